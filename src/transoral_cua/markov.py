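"""Stage 2: lifetime Markov cohort model.

The cohort enters remission after initial treatment and transitions between
nine health states in 3-month cycles until death:

* ``REMISSION_0_2`` / ``REMISSION_2_5`` / ``REMISSION_POST5`` — remission,
  stratified by time since treatment (recurrence risk is time-dependent:
  80% of recurrences occur in the first 2 years, the remaining 20% between
  years 2 and 5, none after year 5);
* ``LOCAL_REC_SURGERY`` / ``LOCAL_REC_CRT`` — local recurrence salvaged
  surgically or with chemoradiation (one-cycle tunnel states: the large
  salvage cost is booked once on entry);
* ``REGIONAL_REC`` — regional recurrence (one-cycle tunnel);
* ``DISTANT_MET`` — distant metastasis, transitioning to palliative care;
* ``PALLIATIVE`` — palliative care until death;
* ``DEAD`` — absorbing, zero reward.

Background (non-cancer) mortality from the annual life table applies to every
alive state, converted to a per-cycle probability under a constant hazard.
Cancer-specific death occurs through the salvage pathway.  Rewards (state
costs, utility-weighted months) accrue at cycle start with no half-cycle
correction (switchable), discounted at an equal annual rate for costs and
effects.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, ModelSpecificationError
from .lifetable import LifeTable, annual_to_cycle_prob
from .parameters import ParameterSet
from .tree import ShortTermResult

__all__ = [
    "State",
    "SalvageConfig",
    "CohortTrace",
    "recurrence_cycle_prob",
    "build_transition_matrix",
    "propagate_cohort",
    "run_cohort",
    "total_outcomes",
    "CYCLES_2Y",
    "CYCLES_5Y",
]

CYCLES_2Y = 8  # cycles in the first 2 years
CYCLES_5Y = 20  # cycles in the first 5 years
LATE_FRACTION = 0.20 / 0.80  # late (2-5 y) vs early (0-2 y) cumulative recurrence odds


class State(enum.IntEnum):
    REMISSION_0_2 = 0
    REMISSION_2_5 = 1
    REMISSION_POST5 = 2
    LOCAL_REC_SURGERY = 3
    LOCAL_REC_CRT = 4
    REGIONAL_REC = 5
    DISTANT_MET = 6
    PALLIATIVE = 7
    DEAD = 8


N_STATES = len(State)
_ALIVE = np.arange(N_STATES) != State.DEAD


@dataclass
class SalvageConfig:
    """Inter-state transition probabilities of the salvage pathway and the
    panendoscopy surveillance schedule.

    The salvage values are calibration defaults: the source model they stand
    in for is not published, so they were chosen once (clinically plausible,
    frozen thereafter).  Local and regional recurrences are one-cycle tunnel
    states whose outflow (remission / palliative / cancer death) must sum
    to 1; distant metastasis converts to palliative care with a per-cycle
    probability (expected dwell 1/p cycles); palliative patients die with a
    per-cycle probability giving a ~10-month median survival.
    """

    local_split_surgery: float = 0.5  # share of local recurrences salvaged surgically
    local_to_remission: float = 0.80
    local_to_palliative: float = 0.12
    local_to_dead: float = 0.08
    regional_to_remission: float = 0.90
    regional_to_palliative: float = 0.06
    regional_to_dead: float = 0.04
    dm_to_palliative: float = 0.50  # per cycle -> mean 2 cycles in DISTANT_MET
    dm_to_dead: float = 0.0
    palliative_death: float = 0.1877  # per cycle; median survival ~10 months
    # panendoscopy surveillance: every cycle in years 0-2, every 2nd cycle in
    # years 2-5, none afterwards
    panendo_every_cycle_until: int = CYCLES_2Y
    panendo_every_other_until: int = CYCLES_5Y

    def validate(self) -> None:
        if not 0.0 <= self.local_split_surgery <= 1.0:
            raise InvalidParameterError("local_split_surgery must lie in [0,1]")
        for prefix in ("local", "regional"):
            probs = [getattr(self, f"{prefix}_to_{dest}") for dest in ("remission", "palliative", "dead")]
            if min(probs) < 0:
                raise InvalidParameterError(f"{prefix} salvage probabilities must be non-negative")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ModelSpecificationError(
                    f"{prefix} recurrence is a one-cycle tunnel: outflow must sum to 1, got {sum(probs)}"
                )
        if not 0.0 <= self.dm_to_palliative + self.dm_to_dead <= 1.0:
            raise ModelSpecificationError("distant-metastasis outflow exceeds 1")
        if not 0.0 <= self.palliative_death <= 1.0:
            raise InvalidParameterError("palliative_death must lie in [0,1]")

    def panendo_due(self, t: int) -> bool:
        if t < self.panendo_every_cycle_until:
            return True
        if t < self.panendo_every_other_until:
            return (t - self.panendo_every_cycle_until) % 2 == 0
        return False


def recurrence_cycle_prob(t: int, q1: float) -> float:
    """Per-cycle recurrence probability at cycle ``t``.

    ``q1`` is the per-cycle probability during the first 2 years.  Between
    years 2 and 5 the per-cycle probability q2 solves
    1-(1-q2)^12 = 0.25 * (1-(1-q1)^8), so the late period contributes 20% of
    all recurrences against 80% in the early period.  No recurrences after
    year 5.
    """
    if not 0.0 <= q1 < 1.0:
        raise InvalidParameterError(f"per-cycle recurrence probability {q1} outside [0,1)")
    if t < CYCLES_2Y:
        return q1
    if t < CYCLES_5Y:
        cum_early = 1.0 - (1.0 - q1) ** CYCLES_2Y
        cum_late = LATE_FRACTION * cum_early
        return 1.0 - (1.0 - cum_late) ** (1.0 / (CYCLES_5Y - CYCLES_2Y))
    return 0.0


def _remission_state_at(t: int) -> State:
    if t < CYCLES_2Y:
        return State.REMISSION_0_2
    if t < CYCLES_5Y:
        return State.REMISSION_2_5
    return State.REMISSION_POST5


def build_transition_matrix(
    t: int,
    age: float,
    params: ParameterSet,
    life_table: LifeTable,
    salvage: SalvageConfig,
) -> np.ndarray:
    """Row-stochastic transition matrix for cycle ``t`` at cohort age ``age``.

    Background mortality acts first on every alive state; conditional on
    surviving it, the cancer-specific transitions apply.  A row whose
    cancer-specific outflow exceeds 1 raises
    :class:`ModelSpecificationError` — it is never silently renormalised.
    """
    salvage.validate()
    cycle_fraction = params.scalars.cycle_months / 12.0
    q_bg = annual_to_cycle_prob(life_table.annual_q(age), cycle_fraction)
    P = np.zeros((N_STATES, N_STATES))

    rem_next = _remission_state_at(t + 1)
    p_loc = recurrence_cycle_prob(t, params["plr"])
    p_reg = recurrence_cycle_prob(t, params["prr"])
    p_dist = recurrence_cycle_prob(t, params["pdr"])
    exits = p_loc + p_reg + p_dist
    if exits > 1.0:
        raise ModelSpecificationError(f"remission outflow {exits} exceeds 1 at cycle {t}")
    for rem in (State.REMISSION_0_2, State.REMISSION_2_5, State.REMISSION_POST5):
        row = np.zeros(N_STATES)
        row[State.LOCAL_REC_SURGERY] = p_loc * salvage.local_split_surgery
        row[State.LOCAL_REC_CRT] = p_loc * (1.0 - salvage.local_split_surgery)
        row[State.REGIONAL_REC] = p_reg
        row[State.DISTANT_MET] = p_dist
        row[rem_next] += 1.0 - exits
        P[rem] = row

    for rec, prefix in (
        (State.LOCAL_REC_SURGERY, "local"),
        (State.LOCAL_REC_CRT, "local"),
        (State.REGIONAL_REC, "regional"),
    ):
        row = np.zeros(N_STATES)
        row[rem_next] += getattr(salvage, f"{prefix}_to_remission")
        row[State.PALLIATIVE] += getattr(salvage, f"{prefix}_to_palliative")
        row[State.DEAD] += getattr(salvage, f"{prefix}_to_dead")
        P[rec] = row

    row = np.zeros(N_STATES)
    row[State.PALLIATIVE] = salvage.dm_to_palliative
    row[State.DEAD] = salvage.dm_to_dead
    row[State.DISTANT_MET] = 1.0 - salvage.dm_to_palliative - salvage.dm_to_dead
    P[State.DISTANT_MET] = row

    P[State.PALLIATIVE, State.DEAD] = salvage.palliative_death
    P[State.PALLIATIVE, State.PALLIATIVE] = 1.0 - salvage.palliative_death

    # background mortality competes first in every alive state
    P[_ALIVE] *= 1.0 - q_bg
    P[_ALIVE, State.DEAD] += q_bg
    P[State.DEAD, State.DEAD] = 1.0
    return P


@dataclass
class CohortTrace:
    """Per-cycle state occupancy with accumulated (discounted) rewards."""

    occupancy: np.ndarray  # [cycle, state], cycle 0 .. horizon
    discounted_cost: float  # CHF (stage-2 only)
    discounted_qalm: float
    life_months: float  # undiscounted
    qalm_undiscounted: float
    start_age: float
    cycle_months: float
    cost_increments: np.ndarray = field(repr=False, default=None)
    qalm_increments: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        n = self.occupancy.shape[0]
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in State])
        df.insert(0, "cycle", np.arange(n))
        df.insert(1, "age", self.start_age + np.arange(n) * self.cycle_months / 12.0)
        if self.cost_increments is not None:
            inc_c = np.append(self.cost_increments, np.nan)
            inc_q = np.append(self.qalm_increments, np.nan)
            df["disc_cost_increment"] = inc_c[:n]
            df["disc_qalm_increment"] = inc_q[:n]
        return df


def propagate_cohort(
    params: ParameterSet,
    life_table: LifeTable,
    salvage: SalvageConfig,
    horizon_cycles: int | None = None,
) -> np.ndarray:
    """State occupancy [cycle, state]; strategy-independent (equal survival
    is assumed across strategies, so both share one trace)."""
    sc = params.scalars
    if horizon_cycles is None:
        horizon_cycles = int(np.ceil((sc.horizon_age - sc.start_age) * 12.0 / sc.cycle_months))
    occ = np.zeros((horizon_cycles + 1, N_STATES))
    occ[0, State.REMISSION_0_2] = 1.0
    for t in range(horizon_cycles):
        age = sc.start_age + t * sc.cycle_months / 12.0
        P = build_transition_matrix(t, age, params, life_table, salvage)
        occ[t + 1] = occ[t] @ P
    return occ


def _state_cost_vector(t: int, params: ParameterSet, salvage: SalvageConfig) -> np.ndarray:
    c = np.zeros(N_STATES)
    panendo = params["cPanendo"] if salvage.panendo_due(t) else 0.0
    c[State.REMISSION_0_2] = params["cREM"] + panendo
    c[State.REMISSION_2_5] = params["c2REM"] + panendo
    c[State.REMISSION_POST5] = 0.0
    c[State.LOCAL_REC_SURGERY] = params["cLR_s"]  # one-cycle tunnel: entry cost
    c[State.LOCAL_REC_CRT] = params["cLR_chemorad"]
    c[State.REGIONAL_REC] = params["cRR"]
    c[State.DISTANT_MET] = params["cDM"]
    c[State.PALLIATIVE] = params["cPC"]
    return c


def _state_utility_vector(params: ParameterSet, adjuvant_mix: dict) -> np.ndarray:
    u = np.zeros(N_STATES)
    p_adj = adjuvant_mix["RT"] + adjuvant_mix["CRT"]
    u[State.REMISSION_0_2] = p_adj * params["urem"] + adjuvant_mix["none"] * params["uremonlysurg"]
    u[State.REMISSION_2_5] = params["urem"]
    u[State.REMISSION_POST5] = params["urem"]
    u[State.LOCAL_REC_SURGERY] = params["uloc"]
    u[State.LOCAL_REC_CRT] = params["ulocxrt"]
    u[State.REGIONAL_REC] = params["ureg"]
    u[State.DISTANT_MET] = params["udist"]
    u[State.PALLIATIVE] = params["upall"]
    return u


def run_cohort(
    initial: ShortTermResult,
    params: ParameterSet,
    life_table: LifeTable,
    salvage: SalvageConfig,
    horizon_cycles: int | None = None,
    discount_annual: float | None = None,
    half_cycle_correction: bool = False,
    occupancy: np.ndarray | None = None,
) -> CohortTrace:
    """Run the lifetime cohort model for one strategy.

    ``occupancy`` may be supplied to reuse a precomputed trace (transitions
    do not depend on the strategy); otherwise it is propagated here.
    Rewards accrue at cycle start unless ``half_cycle_correction`` is set,
    in which case the within-cycle average occupancy is used.
    """
    sc = params.scalars
    if discount_annual is None:
        discount_annual = sc.discount_rate_annual
    if occupancy is None:
        occupancy = propagate_cohort(params, life_table, salvage, horizon_cycles)
    n_cycles = occupancy.shape[0] - 1
    cycles_per_year = 12.0 / sc.cycle_months

    uvec = _state_utility_vector(params, initial.adjuvant_mix)
    t_idx = np.arange(n_cycles)
    df = (1.0 + discount_annual) ** (-(t_idx / cycles_per_year))
    if half_cycle_correction:
        occ_r = 0.5 * (occupancy[:-1] + occupancy[1:])
    else:
        occ_r = occupancy[:-1]

    cost_mat = np.stack([_state_cost_vector(t, params, salvage) for t in t_idx])
    cost_inc = df * np.einsum("ts,ts->t", occ_r, cost_mat)
    qalm_per_cycle = (occ_r @ uvec) * sc.cycle_months
    qalm_inc = df * qalm_per_cycle
    alive_months = occ_r[:, _ALIVE].sum(axis=1) * sc.cycle_months

    return CohortTrace(
        occupancy=occupancy,
        discounted_cost=float(cost_inc.sum()),
        discounted_qalm=float(qalm_inc.sum()),
        life_months=float(alive_months.sum()),
        qalm_undiscounted=float(qalm_per_cycle.sum()),
        start_age=sc.start_age,
        cycle_months=sc.cycle_months,
        cost_increments=cost_inc,
        qalm_increments=qalm_inc,
    )


def total_outcomes(trace: CohortTrace, short_term: ShortTermResult) -> tuple[float, float, float]:
    """Combined stage-1 + stage-2 totals: (cost CHF, QALM discounted, life months).

    The stage-1 expected cost is booked undiscounted at cycle 0 and the
    stage-1 utility toll is subtracted from the discounted QALM total; life
    months are undiscounted.
    """
    cost = short_term.expected_cost + trace.discounted_cost
    qalm = trace.discounted_qalm - short_term.utility_toll
    return cost, qalm, trace.life_months
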