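"""Stage 1: short-term outcomes decision tree.

Each surgical strategy (TORS or TLM) leads to a chance node splitting the
cohort into surgery alone, surgery + adjuvant radiotherapy (RT), and surgery
+ adjuvant chemoradiotherapy (CRT).  Complications of surgery and, where
applicable, of the adjuvant therapy then accrue costs and utility decrements.
Because there are no decision nodes below the arm level and complications
are modelled as independent events, expected-value aggregation over the
event registry is exactly equivalent to full tree rollback.

The tree produces three quantities carried into the lifetime Markov model:
the adjuvant mix (initial-state utility weighting), the expected upfront
cost (booked undiscounted at cycle 0), and the utility toll — expected
quality-adjusted life months lost to the treatment phase and complications,
computed as additive decrements p * (1 - u) * duration_months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import InvalidParameterError, SchemaError
from .parameters import ParameterSet

__all__ = [
    "Strategy",
    "ComplicationEvent",
    "ShortTermResult",
    "TORS",
    "TLM",
    "default_event_registry",
    "arm_distribution",
    "expected_adjuvant_delivery_cost",
    "expected_complication_cost",
    "utility_toll",
    "evaluate_short_term",
    "ARMS",
]

ARMS = ("none", "RT", "CRT")


@dataclass(frozen=True)
class Strategy:
    """A surgical strategy and the parameter names that drive its arm split."""

    name: str
    surgery_cost_param: str
    p_alone_param: str
    p_crt_param: str  # probability of CRT *conditional on* receiving adjuvant
    retreat_multiplier_param: str | None = None  # scalar name, e.g. krepeatTLM

    def retreat_multiplier(self, params: ParameterSet) -> float:
        if self.retreat_multiplier_param is None:
            return 1.0
        k = params[self.retreat_multiplier_param]
        if k < 1.0:
            raise InvalidParameterError(f"retreat multiplier {k} must be >= 1")
        return k


TORS = Strategy("TORS", "cTORS", "pTorsAlone", "pCRT_tors")
TLM = Strategy("TLM", "cTLM", "pTLMAlone", "pCRT_TLM", retreat_multiplier_param="krepeatTLM")


@dataclass(frozen=True)
class ComplicationEvent:
    """An independent complication with probability, cost, disutility, duration."""

    name: str
    probability_param: str
    cost_param: str
    utility_param: str
    duration_cycles: int  # cycles over which the disutility applies
    applies_to: frozenset[str]  # subset of {"surgery", "RT", "CRT"}

    def __post_init__(self) -> None:
        if self.duration_cycles < 0:
            raise SchemaError(f"{self.name}: negative duration")
        if not self.applies_to or not self.applies_to <= {"surgery", "RT", "CRT"}:
            raise SchemaError(f"{self.name}: applies_to must be a non-empty subset of surgery/RT/CRT")


def default_event_registry() -> list[ComplicationEvent]:
    """Default complication -> arm attachment.

    Surgery-level events hit every patient; adjuvant-level events hit only
    the RT/CRT arms.  Durations follow the short-term (6 months) / long-term
    (1 year) annotations of the parameter table where stated; acute events
    (hemorrhage, fistula, readmission) last one 3-month cycle.
    """
    S = frozenset({"surgery"})
    A = frozenset({"RT", "CRT"})
    return [
        # surgical complications (all arms)
        ComplicationEvent("hemorrhage", "phem", "cPH", "uPH", 1, S),
        ComplicationEvent("pharyngocutaneous_fistula", "ppf", "cPF", "uPF", 1, S),
        ComplicationEvent("readmission_surgical", "pho_s", "cHR_s", "uHR", 1, S),
        ComplicationEvent("gastrostomy_short_term", "psg", "cGAST", "ug", 2, S),
        ComplicationEvent("tracheostomy_long_term", "plt", "cTRACH", "ult", 4, S),
        # adjuvant complications (RT and CRT arms)
        ComplicationEvent("readmission_adjuvant", "pho_adj", "cHR_adj", "uHR", 1, A),
        ComplicationEvent("gastrostomy_adjuvant", "psg_adj", "cGAST", "ug", 2, A),
        ComplicationEvent("gastrostomy_long_term", "plg", "cGAST", "ug", 4, A),
        ComplicationEvent("esophageal_stenosis", "pes", "cES", "ues", 2, A),
        ComplicationEvent("osteoradionecrosis", "por", "cORN", "uORN", 4, A),
    ]


@dataclass(frozen=True)
class ShortTermResult:
    """Stage-1 outputs carried forward into the Markov model."""

    strategy: str
    adjuvant_mix: dict  # {"none": p, "RT": p, "CRT": p}
    expected_cost: float  # CHF, undiscounted
    utility_toll: float  # QALMs lost to treatment phase + complications
    trach_fraction: float = 0.0  # expected long-term tracheostomy carriers
    gast_fraction: float = 0.0  # expected long-term gastrostomy carriers

    def __post_init__(self) -> None:
        total = sum(self.adjuvant_mix.values())
        if abs(total - 1.0) > 1e-9 or min(self.adjuvant_mix.values()) < -1e-12:
            raise InvalidParameterError(f"adjuvant mix {self.adjuvant_mix} is not a probability vector")
        if self.expected_cost < 0 or self.utility_toll < 0:
            raise InvalidParameterError("expected cost and utility toll must be non-negative")

    @property
    def p_adjuvant(self) -> float:
        return self.adjuvant_mix["RT"] + self.adjuvant_mix["CRT"]


def arm_distribution(strategy: Strategy, params: ParameterSet) -> dict:
    """P(surgery alone), P(adjuvant RT), P(adjuvant CRT) for a strategy."""
    p_alone = params[strategy.p_alone_param]
    p_crt = params[strategy.p_crt_param]
    for label, p in (("p_alone", p_alone), ("p_crt", p_crt)):
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError(f"{strategy.name}: {label} = {p} outside [0,1]")
    return {
        "none": p_alone,
        "RT": (1.0 - p_alone) * (1.0 - p_crt),
        "CRT": (1.0 - p_alone) * p_crt,
    }


def expected_adjuvant_delivery_cost(arm: str, params: ParameterSet) -> float:
    """Expected delivery cost of an adjuvant arm: base course + planned
    hospital admissions + prophylactic feeding tube (PEG) placement."""
    s = params.scalars
    if arm == "CRT":
        return params["cCRT"] + s.crt_admissions * params["cHR_adj"] + s.peg_rate_crt * params["cGAST"]
    if arm == "RT":
        return params["cRT"] + s.rt_admissions * params["cHR_adj"] + s.peg_rate_rt * params["cGAST"]
    raise InvalidParameterError(f"not an adjuvant arm: {arm!r}")


def _applicable(event: ComplicationEvent, arm: str) -> bool:
    if "surgery" in event.applies_to:
        return True
    return arm in event.applies_to


def expected_complication_cost(
    arm: str, params: ParameterSet, registry: list[ComplicationEvent]
) -> float:
    """Sum of p_event * c_event over events applicable in the given arm."""
    total = 0.0
    for ev in registry:
        if not _applicable(ev, arm):
            continue
        try:
            total += params[ev.probability_param] * params[ev.cost_param]
        except KeyError as exc:
            raise SchemaError(f"event {ev.name} references unknown parameter {exc}") from exc
    return total


#: Disutility durations of the treatment phases, in 3-month cycles.
PHASE_DURATION_CYCLES = {"surgery": 1, "RT": 2, "CRT": 2}


def utility_toll(arm: str, params: ParameterSet, registry: list[ComplicationEvent]) -> float:
    """Expected QALMs lost in one arm: treatment-phase decrements plus
    complication decrements, each (1-u) * duration in months."""
    cm = params.scalars.cycle_months
    toll = (1.0 - _checked_u(params, "uSURG")) * PHASE_DURATION_CYCLES["surgery"] * cm
    if arm == "RT":
        toll += (1.0 - _checked_u(params, "uRT")) * PHASE_DURATION_CYCLES["RT"] * cm
    elif arm == "CRT":
        toll += (1.0 - _checked_u(params, "uCRT")) * PHASE_DURATION_CYCLES["CRT"] * cm
    for ev in registry:
        if not _applicable(ev, arm):
            continue
        p = params[ev.probability_param]
        u = _checked_u(params, ev.utility_param)
        toll += p * (1.0 - u) * ev.duration_cycles * cm
    return toll


def _checked_u(params: ParameterSet, name: str) -> float:
    u = params[name]
    if not 0.0 <= u <= 1.0:
        raise InvalidParameterError(f"utility {name} = {u} outside [0,1]")
    return u


def evaluate_short_term(
    strategy: Strategy,
    params: ParameterSet,
    registry: list[ComplicationEvent] | None = None,
) -> ShortTermResult:
    """Roll back the stage-1 tree for one strategy."""
    if registry is None:
        registry = default_event_registry()
    mix = arm_distribution(strategy, params)
    cost = strategy.retreat_multiplier(params) * params[strategy.surgery_cost_param]
    toll = 0.0
    for arm, p_arm in mix.items():
        if p_arm == 0.0:
            continue
        arm_cost = expected_complication_cost(arm, params, registry)
        if arm in ("RT", "CRT"):
            arm_cost += expected_adjuvant_delivery_cost(arm, params)
        cost += p_arm * arm_cost
        toll += p_arm * utility_toll(arm, params, registry)
    return ShortTermResult(
        strategy=strategy.name,
        adjuvant_mix=mix,
        expected_cost=cost,
        utility_toll=toll,
        trach_fraction=params["plt"],
        gast_fraction=(mix["RT"] + mix["CRT"]) * params["plg"],
    )
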