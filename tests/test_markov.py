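"""Markov engine: time-dependent transitions, cohort propagation, rewards."""

import numpy as np
import pytest

from transoral_cua import (
    SalvageConfig,
    State,
    TLM,
    evaluate_short_term,
    life_expectancy,
    recurrence_cycle_prob,
    run_cohort,
    total_outcomes,
)
from transoral_cua.exceptions import ModelSpecificationError
from transoral_cua.lifetable import LifeTable, default_life_table
from transoral_cua.markov import (
    CYCLES_2Y,
    CYCLES_5Y,
    N_STATES,
    build_transition_matrix,
    propagate_cohort,
)


def test_recurrence_prob_early_period():
    assert recurrence_cycle_prob(0, 0.0064) == 0.0064
    assert recurrence_cycle_prob(CYCLES_2Y - 1, 0.0064) == 0.0064


def test_recurrence_prob_late_period_closed_form():
    """q2 solves 1-(1-q2)^12 = 0.25 * (1-(1-q1)^8): 20% of recurrences late."""
    q2 = recurrence_cycle_prob(10, 0.0064)
    assert q2 == pytest.approx(0.001049, abs=2e-6)
    cum_late = 1.0 - (1.0 - q2) ** (CYCLES_5Y - CYCLES_2Y)
    cum_early = 1.0 - (1.0 - 0.0064) ** CYCLES_2Y
    assert cum_late == pytest.approx(0.25 * cum_early, rel=1e-9)


def test_recurrence_prob_cured_after_five_years():
    assert recurrence_cycle_prob(CYCLES_5Y, 0.5) == 0.0
    assert recurrence_cycle_prob(25, 0.0064) == 0.0


def test_transition_rows_stochastic(params):
    P = build_transition_matrix(0, 55.0, params, default_life_table(), SalvageConfig())
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(P >= 0)


def test_certain_background_death(params):
    table = LifeTable(ages=np.arange(111), qx=np.ones(111))
    P = build_transition_matrix(0, 55.0, params, table, SalvageConfig())
    np.testing.assert_allclose(P[:, State.DEAD], 1.0, atol=1e-12)


def test_no_transitions_only_scheduled_advancement(params):
    """With all recurrence and death probabilities zeroed, remission just
    advances at the 2- and 5-year boundaries."""
    p = params.copy()
    for name in ("plr", "prr", "pdr"):
        p.values[name] = 0.0
    table = LifeTable(ages=np.arange(111), qx=np.r_[np.zeros(110), 1.0])
    P = build_transition_matrix(0, 55.0, p, table, SalvageConfig())
    assert P[State.REMISSION_0_2, State.REMISSION_0_2] == 1.0
    P = build_transition_matrix(CYCLES_2Y - 1, 56.75, p, table, SalvageConfig())
    assert P[State.REMISSION_0_2, State.REMISSION_2_5] == 1.0
    P = build_transition_matrix(CYCLES_5Y - 1, 59.75, p, table, SalvageConfig())
    assert P[State.REMISSION_2_5, State.REMISSION_POST5] == 1.0


def test_inconsistent_salvage_rejected(params):
    bad = SalvageConfig(local_to_remission=0.9, local_to_palliative=0.3, local_to_dead=0.1)
    with pytest.raises(ModelSpecificationError):
        build_transition_matrix(0, 55.0, params, default_life_table(), bad)


def test_occupancy_conserved_and_dead_monotone(params):
    occ = propagate_cohort(params, default_life_table(), SalvageConfig())
    np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(occ >= -1e-15)
    assert np.all(np.diff(occ[:, State.DEAD]) >= -1e-12)


def test_cohort_extinct_at_horizon(params):
    occ = propagate_cohort(params, default_life_table(), SalvageConfig())
    assert occ[-1, State.DEAD] > 0.999


def _immortal_utopia(params):
    """No cancer transitions, utility 1 everywhere: QALM == life months."""
    p = params.copy()
    for name in ("plr", "prr", "pdr"):
        p.values[name] = 0.0
    for name, spec in p.specs.items():
        if spec.role == "utility":
            p.values[name] = 1.0
    p.scalars.discount_rate_annual = 0.0
    return p


def test_zero_discount_full_utility_qalm_equals_months(params):
    p = _immortal_utopia(params)
    st = evaluate_short_term(TLM, p)
    trace = run_cohort(st, p, default_life_table(), SalvageConfig())
    assert trace.discounted_qalm == pytest.approx(trace.life_months, rel=1e-12)


def test_cancer_free_model_matches_life_table(params):
    """With cancer switched off, model survival reproduces the life table's
    remaining life expectancy at 55 within half a cycle."""
    p = _immortal_utopia(params)
    table = default_life_table()
    st = evaluate_short_term(TLM, p)
    trace = run_cohort(st, p, table, SalvageConfig())
    e55_months = life_expectancy(table, 55) * 12.0
    assert trace.life_months == pytest.approx(e55_months, abs=1.5)


def test_discounting_reduces_totals(params):
    st = evaluate_short_term(TLM, params)
    table = default_life_table()
    t_disc = run_cohort(st, params, table, SalvageConfig())
    assert t_disc.discounted_qalm < t_disc.qalm_undiscounted
    t_zero = run_cohort(st, params, table, SalvageConfig(), discount_annual=0.0)
    t_five = run_cohort(st, params, table, SalvageConfig(), discount_annual=0.05)
    assert t_five.discounted_cost < t_disc.discounted_cost < t_zero.discounted_cost
    assert t_five.discounted_qalm < t_disc.discounted_qalm < t_zero.discounted_qalm


def test_half_cycle_correction_shrinks_life_months(params):
    st = evaluate_short_term(TLM, params)
    table = default_life_table()
    plain = run_cohort(st, params, table, SalvageConfig())
    hcc = run_cohort(st, params, table, SalvageConfig(), half_cycle_correction=True)
    assert hcc.life_months < plain.life_months


def test_total_outcomes_additive(params, base_results):
    st = base_results.short_term["TLM"]
    tr = base_results.traces["TLM"]
    cost, qalm, lm = total_outcomes(tr, st)
    assert cost == pytest.approx(st.expected_cost + tr.discounted_cost)
    assert qalm == pytest.approx(tr.discounted_qalm - st.utility_toll)
    assert lm == pytest.approx(tr.life_months)


def test_trace_export_shape(params, base_results):
    df = base_results.traces["TORS"].to_frame()
    assert {"cycle", "age"} | {s.name for s in State} <= set(df.columns)
    assert df["age"].iloc[0] == 55.0


# ---------------------------------------------------------------------------
# first-order microsimulation oracle


def _microsimulate(params, table, salvage, n_patients, horizon, rng):
    """Independent oracle: simulate individual trajectories through the same
    per-cycle transition matrices and average their discounted rewards."""
    from transoral_cua.markov import _state_cost_vector, _state_utility_vector

    sc = params.scalars
    state = np.zeros(n_patients, dtype=np.int64)
    cost = np.zeros(n_patients)
    qalm = np.zeros(n_patients)
    mix = {"none": 0.0, "RT": 0.5, "CRT": 0.5}  # any fixed mix; matched below
    uvec = _state_utility_vector(params, mix)
    for t in range(horizon):
        age = sc.start_age + t * sc.cycle_months / 12.0
        P = build_transition_matrix(t, age, params, table, salvage)
        df = (1.0 + sc.discount_rate_annual) ** (-(t / (12.0 / sc.cycle_months)))
        cvec = _state_cost_vector(t, params, salvage)
        cost += df * cvec[state]
        qalm += df * uvec[state] * sc.cycle_months
        cum = P.cumsum(axis=1)[state]
        u = rng.random(n_patients)
        state = (u[:, None] > cum).sum(axis=1)
    return cost, qalm, mix


def test_cohort_matches_microsimulation(params):
    """50,000 simulated patients reproduce the cohort expectations (3 SE)."""
    table = default_life_table()
    salvage = SalvageConfig()
    horizon = 220
    rng = np.random.default_rng(20260919)
    cost_i, qalm_i, mix = _microsimulate(params, table, salvage, 50_000, horizon, rng)

    st = evaluate_short_term(TLM, params)
    st = type(st)(strategy=st.strategy, adjuvant_mix=mix, expected_cost=st.expected_cost,
                  utility_toll=st.utility_toll)
    trace = run_cohort(st, params, table, salvage, horizon_cycles=horizon)

    for sample, cohort in ((cost_i, trace.discounted_cost), (qalm_i, trace.discounted_qalm)):
        se = sample.std(ddof=1) / np.sqrt(len(sample))
        assert abs(sample.mean() - cohort) < 3.0 * se
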