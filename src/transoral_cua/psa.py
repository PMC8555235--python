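"""Second-order Monte Carlo probabilistic sensitivity analysis.

Each draw samples every uncertain parameter from its distribution (beta for
probabilities and utilities, gamma for costs), re-runs the full two-stage
model for both strategies, and records the incremental cost and effect.
Complement pairs are sampled as a single underlying quantity: the designated
free member (pCRT_*) is drawn and its complement set to one minus the draw,
which keeps every draw internally consistent.  Fixed scalars (admission
schedule, PEG rates, the TLM retreat multiplier) are not sampled.

Reproducibility: one root seed spawns independent per-draw substreams, so
results are deterministic given the seed on one platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .exceptions import InvalidParameterError
from .metrics import LABELS, classify
from .parameters import ParameterSet

__all__ = [
    "PSAResult",
    "Ellipse",
    "sample_parameters",
    "run_psa",
    "confidence_ellipse",
    "acceptability_curve",
]


def sample_parameters(base: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One random parameter set drawn from the distributions in ``base``.

    Beta rows are drawn as beta(shape1, shape2), gamma rows as
    gamma(shape1, rate=shape2); ``fixed`` rows keep their point value.
    Derived complement members are set to 1 minus their free partner's draw.
    """
    derived = {d for _, d in base.complement_groups}
    values = {}
    for name, spec in base.specs.items():
        if name in derived:
            continue
        if spec.family == "beta":
            values[name] = float(rng.beta(spec.shape1, spec.shape2))
        elif spec.family == "gamma":
            values[name] = float(rng.gamma(spec.shape1, 1.0 / spec.shape2))
        else:
            values[name] = base.values[name]
    for free, dep in base.complement_groups:
        values[dep] = 1.0 - values[free]
    return ParameterSet(base.specs, values, base.scalars, base.complement_groups)


@dataclass(frozen=True)
class Ellipse:
    """Confidence ellipse of a 2-d point cloud (normal approximation)."""

    center: np.ndarray  # (2,)
    covariance: np.ndarray  # (2,2)
    coverage: float
    radii: np.ndarray  # semi-axis lengths, descending
    angle_deg: float  # orientation of the major axis, counter-clockwise

    @property
    def degenerate(self) -> bool:
        return bool(np.min(self.radii) <= 0.0)


def confidence_ellipse(points: np.ndarray, coverage: float = 0.95) -> Ellipse:
    """Ellipse covering ``coverage`` of a bivariate normal fitted to ``points``.

    The sample covariance is scaled by the chi-square(2) quantile of the
    coverage level (5.991 for 95%).  A rank-deficient cloud yields a
    degenerate (line-segment) ellipse with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidParameterError("need an (n, 2) array with n >= 3")
    if not 0.0 < coverage < 1.0:
        raise InvalidParameterError("coverage must lie in (0,1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    if np.min(evals) <= 1e-300 * max(1.0, np.max(evals)):
        warnings.warn("degenerate point cloud: reduced-rank confidence ellipse", stacklevel=2)
    q = chi2.ppf(coverage, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    radii = np.sqrt(evals * q)
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return Ellipse(center=center, covariance=cov, coverage=coverage, radii=radii, angle_deg=angle)


def acceptability_curve(draws: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    """P(TORS has the higher net monetary benefit) as a function of WTP."""
    if len(draws) == 0:
        raise InvalidParameterError("no draws")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dq = draws["delta_qalm"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    frac = [(wtp * dq - dc > 0).mean() for wtp in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "p_tors_cost_effective": frac})


@dataclass
class PSAResult:
    """Draw cloud and cost-effectiveness-plane summary of a PSA run."""

    draws: pd.DataFrame  # per draw: costs, qalms, deltas, label
    fractions: dict  # label -> fraction of draws
    ellipse: Ellipse  # on (delta_qalm, delta_cost)
    seed: int | None
    n: int
    wtp: float

    def acceptability_curve(self, wtp_grid) -> pd.DataFrame:
        return acceptability_curve(self.draws, wtp_grid)

    def summary(self) -> str:
        lines = [f"Probabilistic sensitivity analysis ({self.n} draws, "
                 f"WTP {self.wtp:,.0f} CHF/QALM, seed {self.seed})", "=" * 60]
        for label in LABELS:
            lines.append(f"  {label:<22s} {100 * self.fractions[label]:6.1f} %")
        dc, dq = self.draws["delta_cost"], self.draws["delta_qalm"]
        lines.append(f"  mean incremental cost    {dc.mean():+10.1f} CHF (sd {dc.std():,.1f})")
        lines.append(f"  mean incremental utility {dq.mean():+10.4f} QALM (sd {dq.std():.4f})")
        return "\n".join(lines)

    def plot_ce_plane(self, ax=None):
        """Scatter the draw cloud on the CE plane with the confidence ellipse
        and the willingness-to-pay line."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse as MplEllipse

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(self.draws["delta_qalm"], self.draws["delta_cost"], s=8, alpha=0.4)
        ell = self.ellipse
        ax.add_patch(
            MplEllipse(ell.center, 2 * ell.radii[0], 2 * ell.radii[1], angle=ell.angle_deg,
                       fill=False, color="crimson", lw=1.5,
                       label=f"{100 * ell.coverage:.0f}% confidence ellipse")
        )
        xs = np.array(ax.get_xlim())
        ax.plot(xs, self.wtp * xs, "k--", lw=1, label=f"WTP {self.wtp:,.0f} CHF/QALM")
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel("Incremental effectiveness (QALM, TORS - TLM)")
        ax.set_ylabel("Incremental cost (CHF, TORS - TLM)")
        ax.legend(loc="best", fontsize=8)
        return ax


def run_psa(model, n: int = 1000, seed: int | None = None, wtp: float | None = None) -> PSAResult:
    """Run ``n`` full-model evaluations with parameters drawn per draw."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if wtp is None:
        wtp = model.params.scalars.wtp_per_qalm
    streams = np.random.SeedSequence(seed).spawn(n)
    records = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        try:
            draw = sample_parameters(model.params, rng)
            ce = model.evaluate(draw, wtp=wtp).ce
        except Exception as exc:  # noqa: BLE001 - annotate the failing draw
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        records.append(
            {"draw": i, "cost_TORS": ce.cost_tors, "qalm_TORS": ce.qalm_tors,
             "cost_TLM": ce.cost_tlm, "qalm_TLM": ce.qalm_tlm,
             "delta_cost": ce.delta_cost, "delta_qalm": ce.delta_qalm,
             "label": classify(ce.delta_cost, ce.delta_qalm, wtp)}
        )
    draws = pd.DataFrame(records)
    fractions = {label: float((draws["label"] == label).mean()) for label in LABELS}
    pts = draws[["delta_qalm", "delta_cost"]].to_numpy()
    if n >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ell = confidence_ellipse(pts, 0.95)
    else:
        ell = Ellipse(center=pts.mean(axis=0), covariance=np.zeros((2, 2)),
                      coverage=0.95, radii=np.zeros(2), angle_deg=0.0)
    return PSAResult(draws=draws, fractions=fractions, ellipse=ell, seed=seed, n=n, wtp=wtp)
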