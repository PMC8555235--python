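"""Background (non-cancer) mortality.

The model needs an annual mortality schedule q(x) for ages 0..110.  National
period life tables are not bundled; instead a Gompertz-Makeham hazard

    mu(x) = c + a * exp(b * x)

is integrated over one-year age steps and the Makeham level ``a`` is
calibrated by bisection so that life expectancy at birth matches a target
(default 81.9 years, the male life expectancy of the modelled population).

Life expectancy uses the half-interval convention: deaths within an age
interval contribute half a year, so e(x) = 0.5 when q = 1 everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .exceptions import CalibrationError, InvalidParameterError

__all__ = [
    "LifeTable",
    "make_gompertz_makeham",
    "calibrate_to_life_expectancy",
    "life_expectancy",
    "annual_to_cycle_prob",
    "default_life_table",
    "TERMINAL_AGE",
    "DEFAULT_E0",
    "DEFAULT_GOMPERTZ_B",
    "DEFAULT_MAKEHAM_C",
]

TERMINAL_AGE = 110
DEFAULT_E0 = 81.9  # years, calibration target for the default table

# Frozen defaults for the synthetic table: the Gompertz slope b controls how
# strongly mortality concentrates in old age, the Makeham constant c the
# age-independent background hazard.  Calibrated once (together with the
# salvage defaults in markov.SalvageConfig) so that, with a fitted to
# e0 = 81.9 y, the base-case cohort reproduces the reference lifetime totals;
# the implied remaining life expectancy at the starting age of 55 is ~30.4 y.
DEFAULT_GOMPERTZ_B = 0.13
DEFAULT_MAKEHAM_C = 0.001


@dataclass(frozen=True)
class LifeTable:
    """Annual probabilities of death q(x) for integer ages 0..110."""

    ages: np.ndarray  # integer years
    qx: np.ndarray  # annual death probability at each age

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.shape != qx.shape:
            raise InvalidParameterError("ages and qx must have the same length")
        if np.any((qx < 0) | (qx > 1)):
            raise InvalidParameterError("qx values must lie in [0,1]")
        if qx[-1] != 1.0:
            raise InvalidParameterError("the table must close with qx = 1 at the terminal age")

    def annual_q(self, age: float) -> float:
        """q(x) for the (integer) age containing ``age``; 1 beyond the table."""
        if age < self.ages[0]:
            raise InvalidParameterError(f"age {age} below table start {self.ages[0]}")
        idx = int(np.floor(age)) - int(self.ages[0])
        if idx >= len(self.qx):
            return 1.0
        return float(self.qx[idx])

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.ages, self.qx]),
                   header="age,qx", delimiter=",", comments="", fmt=["%d", "%.10g"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(ages=arr[:, 0].astype(int), qx=arr[:, 1])


def make_gompertz_makeham(a: float, b: float, c: float = 0.0) -> LifeTable:
    """Life table from the hazard mu(x) = c + a*exp(b*x), ages 0..110.

    q(x) = 1 - exp(-integral of mu over [x, x+1]); the terminal age is closed
    with q = 1.  Parameters producing q > 1 before the terminal age are
    clamped with a warning.
    """
    if a < 0 or b <= 0 or c < 0:
        raise InvalidParameterError(f"need a >= 0, b > 0, c >= 0; got ({a}, {b}, {c})")
    ages = np.arange(TERMINAL_AGE + 1)
    x = ages.astype(float)
    cumhaz = c + (a / b) * (np.exp(b * (x + 1.0)) - np.exp(b * x))
    qx = 1.0 - np.exp(-cumhaz)
    if np.any(qx[:-1] >= 1.0 - 1e-15):
        warnings.warn("hazard saturates before the terminal age; clamping qx to 1", stacklevel=2)
        qx = np.minimum(qx, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def life_expectancy(table: LifeTable, age: int = 0) -> float:
    """Remaining life expectancy at ``age`` (half-interval convention)."""
    if age < table.ages[0] or age > table.ages[-1]:
        raise InvalidParameterError(f"age {age} outside table range")
    q = table.qx[int(age) - int(table.ages[0]):]
    surv = np.cumprod(1.0 - q)  # survival to the end of each year
    return 0.5 + float(np.sum(surv[:-1])) + 0.5 * float(surv[-1] if len(surv) else 0.0)
    # surv[-1] is 0 because the table closes with q=1; kept for clarity


def calibrate_to_life_expectancy(
    target_e0: float,
    b: float = DEFAULT_GOMPERTZ_B,
    c: float = DEFAULT_MAKEHAM_C,
    tol: float = 0.01,
) -> LifeTable:
    """Bisection on the Gompertz level ``a`` to hit e(0) = target_e0.

    Raises :class:`CalibrationError` when the target cannot be bracketed
    within a in [1e-12, 1].
    """

    def f(log_a: float) -> float:
        return life_expectancy(make_gompertz_makeham(np.exp(log_a), b, c)) - target_e0

    lo, hi = np.log(1e-12), np.log(1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise CalibrationError(
                f"target life expectancy {target_e0} y not bracketable "
                f"(e0 range [{fhi + target_e0:.2f}, {flo + target_e0:.2f}] y)"
            )
        log_a = brentq(f, lo, hi, xtol=1e-12)
        table = make_gompertz_makeham(np.exp(log_a), b, c)
    if abs(life_expectancy(table) - target_e0) > max(tol, 0.1):
        raise CalibrationError("calibration failed to converge")
    return table


_DEFAULT_TABLE: LifeTable | None = None


def default_life_table() -> LifeTable:
    """The frozen default table: calibrated to e(0) = 81.9 years."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = calibrate_to_life_expectancy(DEFAULT_E0)
    return _DEFAULT_TABLE


def annual_to_cycle_prob(q_annual: float, cycle_fraction: float) -> float:
    """Convert an annual probability to a shorter cycle assuming constant hazard.

    p_cycle = 1 - (1 - q_annual) ** cycle_fraction.
    """
    if not 0.0 <= q_annual <= 1.0:
        raise InvalidParameterError(f"annual probability {q_annual} outside [0,1]")
    if not 0.0 < cycle_fraction <= 1.0:
        raise InvalidParameterError(f"cycle fraction {cycle_fraction} outside (0,1]")
    return 1.0 - (1.0 - q_annual) ** cycle_fraction
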