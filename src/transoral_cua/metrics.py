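"""Cost-utility arithmetic: ICUR, net monetary benefit, dominance.

Incremental quantities are oriented TORS minus TLM throughout.  The
incremental cost-utility ratio (ICUR) is only a meaningful trade-off when
the incremental cost and effect have the same sign; otherwise one strategy
dominates and a marker is reported instead of a ratio.  Net monetary
benefit is NMB = wtp * effect - cost with the willingness-to-pay expressed
in CHF per quality-adjusted life month.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

__all__ = ["icur", "nmb", "classify", "CEResult", "LABELS"]

LABELS = ("TORS_dominates", "TLM_dominates", "TORS_cost_effective", "TLM_cost_effective", "equivalent")

_EPS = 1e-12


def icur(delta_cost: float, delta_qalm: float) -> float | str:
    """ICUR in CHF/QALM, or a dominance marker when the ratio is meaningless.

    Returns the quotient when both increments share a sign (a genuine
    trade-off), ``"TORS_dominates"`` / ``"TLM_dominates"`` when one strategy
    is better on both axes, and ``"equivalent"`` for 0/0.
    """
    zc, ze = abs(delta_cost) <= _EPS, abs(delta_qalm) <= _EPS
    if zc and ze:
        return "equivalent"
    if ze:
        return "TLM_dominates" if delta_cost > 0 else "TORS_dominates"
    if delta_cost > 0 and delta_qalm < 0:
        return "TLM_dominates"
    if delta_cost < 0 and delta_qalm > 0:
        return "TORS_dominates"
    return delta_cost / delta_qalm


def nmb(cost: float, qalm: float, wtp: float = 4000.0) -> float:
    """Net monetary benefit wtp*qalm - cost (CHF)."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * qalm - cost


def classify(delta_cost: float, delta_qalm: float, wtp: float = 4000.0) -> str:
    """Position of TORS vs TLM on the cost-effectiveness plane.

    Dominance requires being at least as good on both axes and strictly
    better on one; otherwise the higher NMB at ``wtp`` wins, with exact NMB
    ties classified ``equivalent``.
    """
    better_cost, worse_cost = delta_cost < -_EPS, delta_cost > _EPS
    better_eff, worse_eff = delta_qalm > _EPS, delta_qalm < -_EPS
    if (better_cost and not worse_eff) or (better_eff and not worse_cost):
        return "TORS_dominates"
    if (worse_cost and not better_eff) or (worse_eff and not better_cost):
        return "TLM_dominates"
    dnmb = wtp * delta_qalm - delta_cost
    if abs(dnmb) <= _EPS:
        return "equivalent"
    return "TORS_cost_effective" if dnmb > 0 else "TLM_cost_effective"


@dataclass(frozen=True)
class CEResult:
    """Base-case comparison of the two strategies."""

    cost_tors: float
    qalm_tors: float
    lm_tors: float
    cost_tlm: float
    qalm_tlm: float
    lm_tlm: float
    wtp: float = 4000.0

    @property
    def delta_cost(self) -> float:
        return self.cost_tors - self.cost_tlm

    @property
    def delta_qalm(self) -> float:
        return self.qalm_tors - self.qalm_tlm

    @property
    def icur(self) -> float | str:
        return icur(self.delta_cost, self.delta_qalm)

    @property
    def nmb_tors(self) -> float:
        return nmb(self.cost_tors, self.qalm_tors, self.wtp)

    @property
    def nmb_tlm(self) -> float:
        return nmb(self.cost_tlm, self.qalm_tlm, self.wtp)

    @property
    def label(self) -> str:
        return classify(self.delta_cost, self.delta_qalm, self.wtp)

    @property
    def winner(self) -> str:
        lab = self.label
        if lab.startswith("TORS"):
            return "TORS"
        if lab.startswith("TLM"):
            return "TLM"
        return "equivalent"

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            delta_cost=self.delta_cost,
            delta_qalm=self.delta_qalm,
            icur=self.icur if isinstance(self.icur, str) else float(self.icur),
            nmb_tors=self.nmb_tors,
            nmb_tlm=self.nmb_tlm,
            label=self.label,
            winner=self.winner,
            units={"cost": "CHF", "qalm": "quality-adjusted life months",
                   "lm": "life months", "wtp": "CHF per QALM"},
        )
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)
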