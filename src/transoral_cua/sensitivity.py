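"""Deterministic sensitivity analysis.

One-way curves re-evaluate the full two-stage model over a grid of values
for a single parameter (complement pairs rebalanced at each point, all other
parameters at their base-case values).  Threshold finding brackets the
sign change of an objective difference (expected discounted QALM or net
monetary benefit, TORS minus TLM) and refines it by bisection.  Two-way
maps evaluate the winner over a parameter-pair grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import InvalidParameterError
from .metrics import nmb

__all__ = [
    "ThresholdResult",
    "CostReductionResult",
    "one_way",
    "find_threshold",
    "two_way",
    "tors_cost_reduction_sweep",
]

_OBJECTIVES = ("qalm", "nmb")


def _outcomes(model, params, objective: str, wtp: float | None) -> tuple[float, float]:
    """(outcome_TORS, outcome_TLM) under the chosen objective."""
    if objective not in _OBJECTIVES:
        raise InvalidParameterError(f"objective must be one of {_OBJECTIVES}, got {objective!r}")
    res = model.evaluate(params, wtp=wtp).ce
    if objective == "qalm":
        return res.qalm_tors, res.qalm_tlm
    return res.nmb_tors, res.nmb_tlm


def _winner(o_tors: float, o_tlm: float) -> str:
    if o_tors > o_tlm:
        return "TORS"
    if o_tlm > o_tors:
        return "TLM"
    return "equivalent"


def one_way(
    model,
    param: str,
    lo: float,
    hi: float,
    n_points: int = 21,
    objective: str = "qalm",
    wtp: float | None = None,
) -> pd.DataFrame:
    """Tidy one-way curve: value, per-strategy outcome, winner per grid point."""
    if not lo < hi:
        raise InvalidParameterError(f"need lo < hi, got [{lo}, {hi}]")
    if n_points < 2:
        raise InvalidParameterError("n_points must be >= 2")
    rows = []
    for value in np.linspace(lo, hi, n_points):
        p = model.params.with_value(param, float(value))
        o_tors, o_tlm = _outcomes(model, p, objective, wtp)
        rows.append(
            {"parameter": param, "value": float(value),
             f"{objective}_TORS": o_tors, f"{objective}_TLM": o_tlm,
             "winner": _winner(o_tors, o_tlm)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    """A sign change of the TORS-minus-TLM objective along one parameter."""

    parameter: str
    objective: str
    found: bool
    threshold: float | None
    bracket: tuple[float, float]
    winner_below: str | None
    winner_above: str | None

    @property
    def complement(self) -> float | None:
        """1 - threshold; the adjuvant-probability framing for p*Alone thresholds."""
        return None if self.threshold is None else 1.0 - self.threshold


def find_threshold(
    model,
    param: str,
    lo: float,
    hi: float,
    objective: str = "qalm",
    wtp: float | None = None,
    tol: float = 1e-4,
) -> ThresholdResult:
    """Bisection on the objective difference; an explicit no-threshold result
    (not an exception) when the endpoints share a sign."""

    def diff(x: float) -> float:
        o_tors, o_tlm = _outcomes(model, model.params.with_value(param, x), objective, wtp)
        return o_tors - o_tlm

    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo == 0.0 or f_hi == 0.0:
        x0 = lo if f_lo == 0.0 else hi
        return ThresholdResult(param, objective, True, x0, (lo, hi),
                               "equivalent", "equivalent")
    if np.sign(f_lo) == np.sign(f_hi):
        side = "TORS" if f_lo > 0 else "TLM"
        return ThresholdResult(param, objective, False, None, (lo, hi), side, side)
    x0 = float(brentq(diff, lo, hi, xtol=tol))
    return ThresholdResult(
        param, objective, True, x0, (lo, hi),
        winner_below="TORS" if f_lo > 0 else "TLM",
        winner_above="TORS" if f_hi > 0 else "TLM",
    )


def two_way(
    model,
    param_x: str,
    range_x: tuple[float, float],
    param_y: str,
    range_y: tuple[float, float],
    shape: tuple[int, int] = (21, 21),
    wtp: float | None = None,
) -> pd.DataFrame:
    """Winner map over a parameter-pair grid.

    Returns a DataFrame of cost-effectiveness-plane labels with the x grid
    as columns and the y grid as index.  Complement constraints are honored
    jointly (each point re-balances both parameters' complements).
    """
    xs = np.linspace(*range_x, shape[0])
    ys = np.linspace(*range_y, shape[1])
    labels = np.empty((shape[1], shape[0]), dtype=object)
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            p = model.params.with_value(param_x, float(x)).with_value(param_y, float(y))
            labels[j, i] = model.evaluate(p, wtp=wtp).ce.label
    out = pd.DataFrame(labels, index=ys, columns=xs)
    out.index.name = param_y
    out.columns.name = param_x
    return out


@dataclass(frozen=True)
class CostReductionResult:
    """Sweep of proportional TORS cost reductions."""

    curve: pd.DataFrame
    flip_fraction: float | None  # smallest reduction at which TORS wins on NMB


def tors_cost_reduction_sweep(
    model,
    max_fraction: float = 0.5,
    n_points: int = 26,
    wtp: float | None = None,
) -> CostReductionResult:
    """Scale cTORS by (1 - fraction) over a grid and find where the winner flips.

    The winner uses the net-monetary-benefit framing; the flip point is
    refined by bisection on the NMB difference when a flip occurs in range.
    """
    if not 0.0 <= max_fraction < 1.0:
        raise InvalidParameterError("max_fraction must lie in [0,1)")
    base_ctors = model.params["cTORS"]

    def diff(fraction: float) -> float:
        p = model.params.with_value("cTORS", base_ctors * (1.0 - fraction))
        o_tors, o_tlm = _outcomes(model, p, "nmb", wtp)
        return o_tors - o_tlm

    rows = []
    for fraction in np.linspace(0.0, max_fraction, n_points):
        rows.append({"fraction": float(fraction), "nmb_diff": diff(float(fraction))})
    curve = pd.DataFrame(rows)
    curve["winner"] = np.where(curve["nmb_diff"] > 0, "TORS",
                               np.where(curve["nmb_diff"] < 0, "TLM", "equivalent"))
    flip = None
    d0, d1 = curve["nmb_diff"].iloc[0], curve["nmb_diff"].iloc[-1]
    if d0 < 0 < d1:
        flip = float(brentq(diff, 0.0, max_fraction, xtol=1e-6))
    elif d0 > 0:
        flip = 0.0
    return CostReductionResult(curve=curve, flip_fraction=flip)
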