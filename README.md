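# transoral-cua

A decision-analytic **cost-utility model** comparing two minimally invasive
surgical strategies for operable oropharyngeal squamous cell carcinoma:
**transoral robotic surgery (TORS)** versus **transoral laser microsurgery
(TLM)**, from a hospital perspective with a lifetime horizon.

The package is aimed at health-economics researchers and modellers who want a
fully reproducible, scriptable implementation of the analysis: the base-case
evaluation, deterministic one-way/two-way/threshold sensitivity analyses, and
a second-order Monte Carlo probabilistic sensitivity analysis (PSA), with no
external data dependency.

## The model

The model has two stages:

1. **Short-term decision tree.** Each strategy's cohort splits at a chance
   node into surgery alone, surgery + adjuvant radiotherapy (RT), and surgery
   + adjuvant chemoradiotherapy (CRT), with probabilities
   `P(none) = p_alone`, `P(CRT) = (1 − p_alone)·p_CRT`,
   `P(RT) = (1 − p_alone)·(1 − p_CRT)`. Independent complications (hemorrhage,
   fistula, readmission, gastrostomy, tracheostomy, esophageal stenosis,
   osteoradionecrosis) accrue expected costs `Σ p·c` and utility tolls
   `Σ p·(1 − u)·duration`. TLM re-resections for inadequate margins enter as
   a cost multiplier `krepeatTLM ≥ 1` on the TLM surgery cost.
2. **Lifetime Markov cohort.** A nine-state model (remission stratified by
   time since treatment, local/regional/distant recurrence, palliative care,
   dead) run in 3-month cycles to age 110. Recurrence probabilities are
   time-dependent (80% of recurrences in years 0–2, 20% in years 2–5, none
   later); background mortality follows an annual life table converted per
   cycle under a constant hazard. Costs and quality-adjusted life months
   (QALMs) are discounted at 3% per year.

Parameter uncertainty follows the standard convention: **beta** distributions
for probabilities and utility coefficients, **gamma** distributions for costs.
Strategies are compared by incremental cost ΔC and incremental utility ΔE
(TORS − TLM), the incremental cost-utility ratio `ICUR = ΔC/ΔE`, and net
monetary benefit `NMB = λ·E − C` at a willingness-to-pay of
**λ = 4000 CHF per QALM**.

Because the national life table behind the original analysis is not deposited,
the package synthesises one from a Gompertz–Makeham hazard
`μ(x) = c + a·e^{bx}` calibrated so that life expectancy at birth is 81.9
years; the salvage-pathway transition probabilities, likewise unpublished, are
frozen calibration defaults (see `docs/methods.md`).

## Worked example

```python
from transoral_cua import CostUtilityModel

model = CostUtilityModel()          # packaged parameters, frozen defaults
print(model.evaluate().summary())
```

```
Base case cost-utility analysis: TORS vs TLM
====================================================
                TORS       TLM
Months        348.00    348.00
QALMs         212.69    212.74
Cost (CHF) 56,466.98 53,935.91
----------------------------------------------------
Incremental cost (TORS - TLM):    +2,531.07 CHF
Incremental utility (TORS - TLM): -0.0467 QALM
ICUR:                             TLM_dominates
NMB at 4,000 CHF/QALM:          TORS 794,288.19 / TLM 797,006.10 CHF
Classification:                   TLM_dominates
```

Both strategies yield the same expected survival (348 life months from age
55, by the equal-survival assumption), but TORS costs ~2,531 CHF more and
loses ~0.05 QALMs to its higher adjuvant-therapy rate, so **TLM dominates**:
it is both cheaper and more effective.

Threshold analysis shows when that verdict flips:

```python
thr = model.find_threshold("pTorsAlone", 0.0, 1.0, objective="qalm")
print(f"TORS optimal when P(adjuvant) < {thr.complement:.3f}")
# TORS optimal when P(adjuvant) < 0.602
```

i.e. TORS becomes the better strategy on expected utility once fewer than
~60% of TORS patients require adjuvant treatment. The probabilistic analysis
propagates all parameter uncertainty:

```python
psa = model.psa(n=1000, seed=1)
print(psa.summary())
```

```
Probabilistic sensitivity analysis (1000 draws, WTP 4,000 CHF/QALM, seed 1)
============================================================
  TORS_dominates            4.6 %
  TLM_dominates            56.4 %
  TORS_cost_effective       6.6 %
  TLM_cost_effective       32.4 %
  equivalent                0.0 %
  mean incremental cost       +2411.3 CHF (sd 1,819.9)
  mean incremental utility    -0.0422 QALM (sd 0.2349)
```

TLM is the preferred strategy (dominant or higher NMB) in ~89% of draws.
`psa.plot_ce_plane()` draws the cost-effectiveness plane with the 95%
confidence ellipse and the willingness-to-pay line.

The same analyses are available from the shell:

```bash
transoral-cua base-case --out results/
transoral-cua threshold --param krepeatTLM --lo 1 --hi 3 --objective nmb --out results/
transoral-cua psa --n 1000 --seed 1 --plot --out results/
```

Every command writes its outputs (CSV/JSON) plus a `manifest.json` with the
configuration hash, seed, and package version needed to reproduce the run.
Custom scenarios go in a YAML config (`--config`); see
`transoral_cua/config.py` for the schema.

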