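"""Model object tying the two stages together.

:class:`CostUtilityModel` holds the parameter set, life table, salvage
configuration and complication registry; :meth:`~CostUtilityModel.evaluate`
rolls back the stage-1 tree and runs the stage-2 cohort for both strategies
and returns a :class:`CEResults` object with per-strategy totals, the
incremental comparison and a formatted summary table.  Sensitivity analyses
and the probabilistic analysis hang off the same object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sensitivity as _sens
from .lifetable import LifeTable, default_life_table
from .markov import CohortTrace, SalvageConfig, propagate_cohort, run_cohort, total_outcomes
from .metrics import CEResult
from .parameters import ParameterSet, load_default_parameters, load_parameter_table
from .psa import PSAResult, run_psa
from .tree import TLM, TORS, ComplicationEvent, ShortTermResult, default_event_registry, evaluate_short_term

__all__ = ["CostUtilityModel", "CEResults"]


@dataclass
class CEResults:
    """Results of one deterministic evaluation of the two-stage model."""

    ce: CEResult
    short_term: dict  # strategy name -> ShortTermResult
    traces: dict  # strategy name -> CohortTrace

    def to_frame(self) -> pd.DataFrame:
        """Per-strategy table: life months, QALMs, cost (Table-2 layout)."""
        return pd.DataFrame(
            {
                "TORS": [self.ce.lm_tors, self.ce.qalm_tors, self.ce.cost_tors],
                "TLM": [self.ce.lm_tlm, self.ce.qalm_tlm, self.ce.cost_tlm],
            },
            index=["Months", "QALMs", "Cost (CHF)"],
        )

    def summary(self) -> str:
        ce = self.ce
        lines = ["Base case cost-utility analysis: TORS vs TLM", "=" * 52]
        frame = self.to_frame()
        lines.append(frame.to_string(float_format=lambda v: f"{v:,.2f}"))
        lines.append("-" * 52)
        lines.append(f"Incremental cost (TORS - TLM):    {ce.delta_cost:+,.2f} CHF")
        lines.append(f"Incremental utility (TORS - TLM): {ce.delta_qalm:+,.4f} QALM")
        icur = ce.icur
        icur_s = f"{icur:,.2f} CHF/QALM" if isinstance(icur, float) else icur
        lines.append(f"ICUR:                             {icur_s}")
        lines.append(f"NMB at {ce.wtp:,.0f} CHF/QALM:          "
                     f"TORS {ce.nmb_tors:,.2f} / TLM {ce.nmb_tlm:,.2f} CHF")
        lines.append(f"Classification:                   {ce.label}")
        return "\n".join(lines)


class CostUtilityModel:
    """Two-stage cost-utility model comparing TORS and TLM.

    Parameters
    ----------
    params
        Model parameters; defaults to the packaged table at its means.
    life_table
        Annual background-mortality schedule; defaults to the synthetic
        table calibrated to a life expectancy at birth of 81.9 years.
    salvage
        Salvage-pathway transition configuration (frozen defaults).
    registry
        Complication -> arm attachment for the stage-1 tree.
    """

    def __init__(
        self,
        params: ParameterSet | None = None,
        life_table: LifeTable | None = None,
        salvage: SalvageConfig | None = None,
        registry: list[ComplicationEvent] | None = None,
        horizon_cycles: int | None = None,
    ) -> None:
        self.params = params if params is not None else load_default_parameters()
        self.life_table = life_table if life_table is not None else default_life_table()
        self.salvage = salvage if salvage is not None else SalvageConfig()
        self.registry = registry if registry is not None else default_event_registry()
        self.horizon_cycles = horizon_cycles
        self.strategies = {"TORS": TORS, "TLM": TLM}

    @classmethod
    def from_table(cls, path, **kwargs) -> "CostUtilityModel":
        return cls(params=load_parameter_table(path), **kwargs)

    # ------------------------------------------------------------------
    # deterministic evaluation

    def evaluate(self, params: ParameterSet | None = None, wtp: float | None = None) -> CEResults:
        """Evaluate both strategies at the given (default: stored) parameters."""
        p = params if params is not None else self.params
        if wtp is None:
            wtp = p.scalars.wtp_per_qalm
        # survival is strategy-independent: propagate the cohort once
        occupancy = propagate_cohort(p, self.life_table, self.salvage, self.horizon_cycles)
        shorts: dict[str, ShortTermResult] = {}
        traces: dict[str, CohortTrace] = {}
        totals: dict[str, tuple[float, float, float]] = {}
        for name, strat in self.strategies.items():
            st = evaluate_short_term(strat, p, self.registry)
            tr = run_cohort(st, p, self.life_table, self.salvage, occupancy=occupancy)
            shorts[name], traces[name] = st, tr
            totals[name] = total_outcomes(tr, st)
        ce = CEResult(
            cost_tors=totals["TORS"][0], qalm_tors=totals["TORS"][1], lm_tors=totals["TORS"][2],
            cost_tlm=totals["TLM"][0], qalm_tlm=totals["TLM"][1], lm_tlm=totals["TLM"][2],
            wtp=wtp,
        )
        return CEResults(ce=ce, short_term=shorts, traces=traces)

    def evaluate_at(self, overrides: dict, wtp: float | None = None) -> CEResults:
        """Evaluate with named parameter overrides (complements rebalanced)."""
        p = self.params.copy()
        for name, value in overrides.items():
            p.set(name, value)
        return self.evaluate(p, wtp=wtp)

    # ------------------------------------------------------------------
    # deterministic sensitivity analyses (delegating to .sensitivity)

    def one_way(self, param, lo, hi, n_points=21, objective="qalm", wtp=None) -> pd.DataFrame:
        return _sens.one_way(self, param, lo, hi, n_points, objective, wtp)

    def find_threshold(self, param, lo, hi, objective="qalm", wtp=None, tol=1e-4):
        return _sens.find_threshold(self, param, lo, hi, objective, wtp, tol)

    def two_way(self, param_x, range_x, param_y, range_y, shape=(21, 21), wtp=None):
        return _sens.two_way(self, param_x, range_x, param_y, range_y, shape, wtp)

    def tors_cost_reduction_sweep(self, max_fraction=0.5, n_points=26, wtp=None):
        return _sens.tors_cost_reduction_sweep(self, max_fraction, n_points, wtp)

    # ------------------------------------------------------------------
    # probabilistic sensitivity analysis

    def psa(self, n: int = 1000, seed: int | None = None, wtp: float | None = None) -> PSAResult:
        return run_psa(self, n=n, seed=seed, wtp=wtp)
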