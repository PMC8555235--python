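# Methods

This note documents the model implemented in `transoral_cua`: its structure,
assumptions, parameters, calibration, numerical conventions, and limitations.

## Two-stage structure

**Stage 1 — short-term decision tree.** For each strategy (TORS, TLM) the
cohort is split at a chance node into *surgery alone*, *surgery + adjuvant
RT*, and *surgery + adjuvant CRT*:

    P(none) = p_alone
    P(CRT)  = (1 − p_alone) · p_CRT
    P(RT)   = (1 − p_alone) · (1 − p_CRT)

where `p_CRT` is the probability of chemoradiotherapy *conditional on*
receiving adjuvant therapy (the packaged table's pCRT_*/pRT_* pairs sum to
one). Complications are modelled as independent Bernoulli events attached to
either the surgical level (all patients) or the adjuvant level (RT/CRT arms
only); with no decision nodes below the arm level, expected-value
aggregation over this registry is exactly the tree rollback. The stage
produces, per strategy:

* the **expected upfront cost**: surgery cost (multiplied by
  `krepeatTLM ≥ 1` for TLM, the expected number of resections needed for
  negative margins), adjuvant delivery (course cost + expected planned
  admissions: 1.25 per CRT patient, 0.25 per RT patient + prophylactic
  feeding-tube placement: 70% of CRT, 20% of RT patients), and expected
  complication costs `Σ p·c`;
* the **utility toll** in QALMs: treatment-phase decrements
  `(1 − uSURG)·3 months` (surgery, one cycle) and `(1 − uRT|uCRT)·6 months`
  (adjuvant phases, two cycles), plus complication decrements
  `p·(1 − u)·duration`. Tolls are additive decrements, not multiplicative
  utility chains; the alternative would interact complications and is
  isolated in one function should anyone want to swap it;
* the **adjuvant mix**, which weights the utility of the initial remission
  state in stage 2.

Event durations: acute events (hemorrhage, pharyngocutaneous fistula,
hospital readmission) one cycle; short-term gastrostomy and esophageal
stenosis two cycles (6 months); long-term gastrostomy, tracheostomy, and
osteoradionecrosis four cycles (1 year). The short-/long-term annotations in
the parameter descriptions fix the gastrostomy/tracheostomy durations; the
others are defaults, configurable through the event registry (the
attachment of events to arms is data, not code — see `config.py`).

**Stage 2 — lifetime Markov cohort.** Nine states: remission stratified by
time since treatment (0–2 y, 2–5 y, >5 y), local recurrence salvaged
surgically or by chemoradiation (50/50 by default), regional recurrence,
distant metastasis, palliative care, dead. Cycle length 3 months, horizon to
age 110 (220 cycles from the starting age of 55). The cohort starts 100% in
remission 0–2 y.

* **Time-dependent recurrence.** The per-cycle probabilities `plr`, `prr`,
  `pdr` apply during the first 8 cycles. Between cycles 8 and 20 the
  per-cycle probability q2 solves `1−(1−q2)^12 = 0.25·(1−(1−q1)^8)`, so the
  late period carries 20% of all recurrences against 80% early (the 0.25 is
  the late/early odds 0.20/0.80). No recurrences after year 5. The
  recurrence clock runs on *model time*, not time since salvage: patients
  returning to remission re-enter the time-appropriate remission state.
* **Background mortality** from the annual life table applies first in every
  alive state, converted per cycle as `1−(1−q_x)^{1/4}` (constant hazard
  within the year). Conditional on surviving it, cancer-specific transitions
  apply. A transition row whose outflow exceeds 1 raises an error — it is
  never silently renormalised.
* **Salvage pathway.** Local and regional recurrences are one-cycle tunnel
  states: the entire occupancy exits after one cycle to remission,
  palliative care, or death, which books the large salvage episode costs
  (cLR_s, cLR_chemorad, cRR) exactly once per entry. Distant metastasis
  converts to palliative care with probability 0.5 per cycle (mean dwell
  2 cycles, cDM per cycle); palliative patients die with probability 0.1877
  per cycle (median survival ≈ 10 months, cPC per cycle).
* **Rewards.** Remission 0–2 y costs cREM per cycle plus a panendoscopy
  (cPanendo) every cycle; remission 2–5 y costs c2REM plus a panendoscopy
  every second cycle; remission beyond 5 y is cost-free. The utility of
  remission 0–2 y is the adjuvant-mix-weighted
  `P(adj)·urem + P(none)·uremonlysurg`; later remission uses `urem` for
  everyone. Costs and QALMs are discounted at 3%/year as `1.03^(−t/4)`;
  life months are reported undiscounted. Rewards accrue at cycle start with
  **no half-cycle correction** (the convention of the modelling tool the
  analysis standard follows; a `half_cycle_correction` switch exists).
  The stage-1 expected cost enters undiscounted at cycle 0 and the stage-1
  utility toll is subtracted from the discounted QALM total.

## Parameters

All 56 model inputs live in `data/parameters.csv` (name, description, mean,
dispersion, family, shape1, shape2, role). Probabilities and utilities are
beta(α, β); costs are gamma(shape, rate) in CHF (mean = shape/rate,
SD = √shape/rate). The dispersion column mixes semantics — variance for
event-probability rows, SD for cost and utility rows — so it is stored
verbatim for reporting only; **the shape parameters are authoritative** for
sampling and analytics. `validate_moments()` reports per row which
interpretation of the dispersion column is consistent. In two utility row
pairs (remission after adjuvant vs after surgery alone; distant recurrence
vs palliative care) the reported mean/SD annotations are transposed relative
to the shape parameters; the packaged table stores the moments implied by
the shapes, which are also the clinically coherent assignment (remission
after chemoradiation worse than after surgery alone, palliative care worse
than distant metastasis).

Run-level scalars (not sampled, no distributions): discount rate 0.03/year,
willingness-to-pay 4000 CHF/QALM, cycle 3 months, starting age 55 y, horizon
age 110 y, `krepeatTLM = 1` (base case), CRT admission expectation 1.25,
RT 0.25, PEG rates 0.70 (CRT) and 0.20 (RT).

## Synthetic life table

National period life tables are not bundled; `lifetable.py` integrates a
Gompertz–Makeham hazard `μ(x) = c + a·e^{bx}` over one-year steps and closes
the table with q(110) = 1. The level `a` is calibrated by bisection so life
expectancy at birth (half-interval convention) is **81.9 years**. The frozen
shape defaults are `b = 0.13`, `c = 0.001`, giving a remaining life
expectancy at age 55 of ≈ 30.4 years. What the synthetic table emulates is
the *level and old-age concentration* of mortality in a population with
that e0; it does not reproduce real cohort effects, sex-specific schedules,
infant mortality structure, or period-vs-cohort distinctions, so passing
tests certify internal consistency with the stated e0, not demographic
fidelity.

## Calibration of the frozen defaults

The salvage transition probabilities are not published for this analysis, so
they are **calibration defaults**: chosen once, jointly with (b, c) above,
so that the base-case evaluation at the table means lands within a few
percent of the reference lifetime totals, then frozen in the repository.
Frozen values: local recurrence → remission 0.80 / palliative 0.12 /
death 0.08; regional recurrence → 0.90 / 0.06 / 0.04; the remaining salvage
knobs stay at their a-priori defaults (split 50/50, DM→palliative 0.5,
palliative death 0.1877). These values are claims of internal calibration,
not of clinical evidence.

## Numerical conventions and tie-breaks

* ICUR is reported as a quotient only when ΔC and ΔE share a sign; opposite
  signs yield a dominance marker, 0/0 yields `equivalent`.
* Dominance on the CE plane is weak dominance (at least as good on both
  axes, strictly better on one); exact NMB ties classify as `equivalent`.
* Threshold finding uses Brent's method on the objective difference
  (tolerance 1e-4); same-sign endpoints return an explicit no-threshold
  result. Effectiveness thresholds use expected discounted QALMs as the
  objective, cost-effectiveness thresholds the NMB difference — both are
  exposed because both framings are standard.
* PSA sampling: beta/gamma by row family; complement pairs are sampled on
  the designated free member (pCRT_*) with the partner set to 1 − draw,
  because their shape parameters are exact mirror images (727/652 vs
  652/727), implying one underlying binomial. One root seed spawns per-draw
  substreams (`numpy` SeedSequence); runs are bit-reproducible given the
  seed on one platform, but cross-platform agreement of summary fractions
  to better than ~1e-10 is not promised.
* The 95% confidence ellipse scales the sample covariance of
  (ΔE, ΔC) by the χ²(2 df) quantile 5.991; degenerate clouds produce a
  reduced-rank warning and a line-segment ellipse.
* The cohort trace enforces occupancy conservation to 1e-9 and is verified
  against a 50,000-trajectory first-order microsimulation oracle (within
  3 standard errors) in the test suite; the microsimulation is a test
  oracle only, never the engine.

## Known limitations

* Two inputs of the original analysis are not published: the national life
  table and the inter-state salvage transitions. Both are synthesised or
  calibrated here; incremental results that depend on them only weakly
  (thresholds on adjuvant probability, base-case dominance) reproduce well,
  whereas quantities driven by the absolute incremental cost (the TLM
  retreat-multiplier threshold, the TORS cost-reduction flip point, the PSA
  quadrant fractions) inherit a gap that cannot be closed from printed
  inputs alone — the reference analysis also reports a small survival
  difference between strategies that its stated equal-survival assumption
  does not generate in this implementation.
* Complications are independent Bernoulli events; no patient-level
  heterogeneity, margin-status simulation, or operating-time modelling.
* The model compares exactly two strategies; no efficiency frontiers or
  extended dominance, and no value-of-information analysis.
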