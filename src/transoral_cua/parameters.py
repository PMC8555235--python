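"""Model parameters: distribution specs, moment matching, loading, validation.

Every input of the cost-utility model is a named parameter with a point value
(its mean) and, where second-order uncertainty is modelled, a beta or gamma
distribution given by two shape parameters.  Conventions:

* beta(shape1=alpha, shape2=beta) for probabilities and utility coefficients;
* gamma(shape1=shape k, shape2=rate lambda) for costs, so mean = k/lambda and
  sd = sqrt(k)/lambda;
* ``fixed`` for scalars stated without a distribution.

The ``dispersion`` column of the source estimates mixes semantics (variance
for event probabilities, SD for costs and utilities).  It is stored verbatim
for reporting, but all sampling and analytic moments use only shape1/shape2,
which are authoritative.  :func:`validate_moments` reports, per row, which
interpretation of the dispersion column is consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import InfeasibleMomentsError, InvalidParameterError, SchemaError

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "Scalars",
    "beta_moments",
    "gamma_moments",
    "fit_beta_from_moments",
    "fit_gamma_from_moments",
    "load_parameter_table",
    "load_default_parameters",
    "validate_moments",
    "TABLE_COLUMNS",
    "COMPLEMENT_GROUPS",
]

TABLE_COLUMNS = ("name", "description", "mean", "dispersion", "family", "shape1", "shape2", "role")

#: Pairs of conditional adjuvant-modality probabilities that must sum to one.
#: The first member is the free parameter; the second is derived as 1 - first.
COMPLEMENT_GROUPS: tuple[tuple[str, str], ...] = (
    ("pCRT_tors", "pRT_tors"),
    ("pCRT_TLM", "pRT_TLM"),
)

_FAMILIES = {"beta", "gamma", "fixed"}
_ROLES = {"probability", "cost", "utility", "multiplier"}


# ---------------------------------------------------------------------------
# moment matching


def beta_moments(alpha: float, beta: float) -> tuple[float, float]:
    """Mean and variance of a beta(alpha, beta) distribution."""
    if alpha <= 0 or beta <= 0:
        raise InvalidParameterError(f"beta shapes must be positive, got ({alpha}, {beta})")
    s = alpha + beta
    mean = alpha / s
    var = alpha * beta / (s * s * (s + 1.0))
    return mean, var


def gamma_moments(shape: float, rate: float) -> tuple[float, float]:
    """Mean and standard deviation of a gamma(shape, rate) distribution."""
    if shape <= 0 or rate <= 0:
        raise InvalidParameterError(f"gamma parameters must be positive, got ({shape}, {rate})")
    return shape / rate, math.sqrt(shape) / rate


def fit_beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters of the beta distribution with the given mean and SD.

    Uses the method of moments: with k = mean(1-mean)/sd^2 - 1,
    alpha = mean*k and beta = (1-mean)*k.  Requires sd^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise InvalidParameterError(f"beta mean must lie in (0,1), got {mean}")
    if sd <= 0:
        raise InvalidParameterError(f"sd must be positive, got {sd}")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"variance {var:.6g} is not representable by a beta with mean {mean:.6g} "
            f"(needs sd^2 < mean*(1-mean) = {mean * (1 - mean):.6g})"
        )
    k = mean * (1.0 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


def fit_gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape and rate of the gamma distribution with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise InvalidParameterError(f"gamma moments must be positive, got ({mean}, {sd})")
    shape = (mean / sd) ** 2
    rate = mean / (sd * sd)
    return shape, rate


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input with its uncertainty distribution."""

    name: str
    description: str
    mean: float
    dispersion: float
    family: str  # beta | gamma | fixed
    shape1: float | None
    shape2: float | None
    role: str  # probability | cost | utility | multiplier

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise SchemaError(f"{self.name}: unknown family {self.family!r}")
        if self.role not in _ROLES:
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        if self.family != "fixed":
            if self.shape1 is None or self.shape2 is None:
                raise SchemaError(f"{self.name}: {self.family} row needs shape1 and shape2")
            if self.shape1 <= 0 or self.shape2 <= 0:
                raise InvalidParameterError(
                    f"{self.name}: non-positive shape parameters ({self.shape1}, {self.shape2})"
                )
        if self.role in ("probability", "utility") and not 0.0 <= self.mean <= 1.0:
            raise InvalidParameterError(f"{self.name}: {self.role} mean {self.mean} outside [0,1]")
        if self.role == "cost" and self.mean < 0:
            raise InvalidParameterError(f"{self.name}: negative cost mean {self.mean}")

    def analytic_moments(self) -> tuple[float, float]:
        """(mean, sd) implied by the shape parameters (== (mean, 0) for fixed)."""
        if self.family == "beta":
            m, v = beta_moments(self.shape1, self.shape2)
            return m, math.sqrt(v)
        if self.family == "gamma":
            return gamma_moments(self.shape1, self.shape2)
        return self.mean, 0.0


@dataclass
class Scalars:
    """Run-level scalars stated without distributions."""

    discount_rate_annual: float = 0.03
    wtp_per_qalm: float = 4000.0  # CHF per quality-adjusted life month
    cycle_months: float = 3.0
    start_age: float = 55.0
    horizon_age: float = 110.0
    krepeatTLM: float = 1.0  # expected number of TLM resections per patient
    # expected hospital admissions during adjuvant delivery
    crt_admissions: float = 0.75 * 1 + 0.25 * 2  # 75% admitted once, 25% twice
    rt_admissions: float = 0.25  # 25% admitted once
    # prophylactic feeding-tube (PEG) placement rates during adjuvant therapy
    peg_rate_crt: float = 0.70
    peg_rate_rt: float = 0.20

    def validate(self) -> None:
        if self.krepeatTLM < 1.0:
            raise InvalidParameterError(f"krepeatTLM must be >= 1, got {self.krepeatTLM}")
        for name in ("peg_rate_crt", "peg_rate_rt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0,1], got {v}")
        if self.discount_rate_annual < 0:
            raise InvalidParameterError("discount rate must be non-negative")


class ParameterSet:
    """Point values + distribution specs for all model inputs.

    ``values`` maps parameter name -> current point value; it is what the
    deterministic model reads.  ``specs`` carries the distributions for the
    probabilistic analysis.  Complement pairs (pCRT_*, pRT_*) are kept
    consistent: setting the free member updates the derived complement.
    """

    def __init__(
        self,
        specs: Mapping[str, ParameterSpec],
        values: Mapping[str, float] | None = None,
        scalars: Scalars | None = None,
        complement_groups: Iterable[tuple[str, str]] = COMPLEMENT_GROUPS,
    ) -> None:
        self.specs = dict(specs)
        self.values = dict(values) if values is not None else {n: s.mean for n, s in self.specs.items()}
        self.scalars = scalars if scalars is not None else Scalars()
        self.complement_groups = [tuple(g) for g in complement_groups]
        self.scalars.validate()
        self._enforce_complements()
        self._validate_values()

    # -- construction helpers

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            self.specs, dict(self.values), replace(self.scalars), list(self.complement_groups)
        )

    def _enforce_complements(self) -> None:
        for free, derived in self.complement_groups:
            if free not in self.values or derived not in self.values:
                raise SchemaError(f"complement group ({free}, {derived}) references missing parameter")
            self.values[derived] = 1.0 - self.values[free]

    def _validate_values(self) -> None:
        for name, v in self.values.items():
            spec = self.specs.get(name)
            if spec is None:
                continue
            if spec.role in ("probability", "utility") and not -1e-12 <= v <= 1.0 + 1e-12:
                raise InvalidParameterError(f"{name}: {spec.role} value {v} outside [0,1]")
            if spec.role == "cost" and v < 0:
                raise InvalidParameterError(f"{name}: negative cost {v}")
        for free, derived in self.complement_groups:
            if abs(self.values[free] + self.values[derived] - 1.0) > 1e-9:
                raise InvalidParameterError(f"complement group ({free}, {derived}) does not sum to 1")

    # -- access

    def __getitem__(self, name: str) -> float:
        if name in self.values:
            return self.values[name]
        if hasattr(self.scalars, name):
            return getattr(self.scalars, name)
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.values or hasattr(self.scalars, name)

    def set(self, name: str, value: float) -> None:
        """Set a parameter (or scalar) value, rebalancing its complement."""
        if name in self.values:
            self.values[name] = float(value)
            for free, derived in self.complement_groups:
                if name == free:
                    self.values[derived] = 1.0 - float(value)
                elif name == derived:
                    self.values[free] = 1.0 - float(value)
            self._validate_values()
        elif hasattr(self.scalars, name):
            setattr(self.scalars, name, float(value))
            self.scalars.validate()
        else:
            raise KeyError(name)

    def with_value(self, name: str, value: float) -> "ParameterSet":
        out = self.copy()
        out.set(name, value)
        return out

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, spec in self.specs.items():
            rows.append(
                {
                    "name": name,
                    "description": spec.description,
                    "value": self.values[name],
                    "family": spec.family,
                    "shape1": spec.shape1,
                    "shape2": spec.shape2,
                    "role": spec.role,
                }
            )
        return pd.DataFrame(rows).set_index("name")


# ---------------------------------------------------------------------------
# loading

#: Names that any complete parameter table must define.
REQUIRED_SYMBOLS: tuple[str, ...] = (
    "pes", "phem", "pho_adj", "pho_s", "plg", "plt", "psg", "psg_adj", "por", "ppf",
    "pTLMAlone", "pTorsAlone", "pCRT_TLM", "pCRT_tors", "pRT_TLM", "pRT_tors",
    "plr", "prr", "pdr",
    "cTORS", "cTLM", "cCRT", "cRT", "cES", "cGAST", "cHR_adj", "cHR_s", "cORN",
    "cPF", "cPH", "cTRACH", "cREM", "c2REM", "cPC", "cRR", "cLR_chemorad",
    "cLR_s", "cDM", "cPanendo",
    "uSURG", "uRT", "uCRT", "uHR", "uPF", "uPH", "ug", "ult", "ues", "uORN",
    "urem", "uremonlysurg", "ureg", "ulocxrt", "uloc", "udist", "upall",
)


def _frame_to_set(df: pd.DataFrame, scalars: Scalars | None) -> ParameterSet:
    missing_cols = set(TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"parameter table missing columns: {sorted(missing_cols)}")
    dupes = df["name"][df["name"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"duplicate parameter names: {dupes}")
    specs: dict[str, ParameterSpec] = {}
    for _, row in df.iterrows():
        try:
            specs[str(row["name"])] = ParameterSpec(
                name=str(row["name"]),
                description=str(row["description"]),
                mean=float(row["mean"]),
                dispersion=float(row["dispersion"]),
                family=str(row["family"]).lower(),
                shape1=None if pd.isna(row["shape1"]) else float(row["shape1"]),
                shape2=None if pd.isna(row["shape2"]) else float(row["shape2"]),
                role=str(row["role"]).lower(),
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"malformed row {row['name']!r}: {exc}") from exc
    missing = [s for s in REQUIRED_SYMBOLS if s not in specs]
    if missing:
        raise SchemaError(f"parameter table missing required symbols: {missing}")
    return ParameterSet(specs, scalars=scalars)


def load_parameter_table(path: str | Path, scalars: Scalars | None = None) -> ParameterSet:
    """Load a parameter table from CSV or JSON (list of row records)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"parameter table not found: {path}")
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path)
    return _frame_to_set(df, scalars)


def load_default_parameters(scalars: Scalars | None = None) -> ParameterSet:
    """Load the packaged default parameter table."""
    with resources.as_file(resources.files("transoral_cua").joinpath("data/parameters.csv")) as p:
        return load_parameter_table(p, scalars)


# ---------------------------------------------------------------------------
# validation report


def validate_moments(pset: ParameterSet) -> pd.DataFrame:
    """Cross-check each row's shape parameters against its mean/dispersion.

    The dispersion column of the source table is ambiguous: for event
    probabilities it holds the variance, for costs and utilities the SD.
    Each row is checked under both interpretations; a row is flagged only if
    it is inconsistent under *both*.  Returns a tidy report frame with one
    row per parameter.
    """
    records = []
    for name, spec in pset.specs.items():
        rec = {
            "name": name,
            "family": spec.family,
            "role": spec.role,
            "mean_printed": spec.mean,
            "dispersion_printed": spec.dispersion,
        }
        if spec.family == "fixed":
            rec.update(mean_analytic=spec.mean, sd_analytic=0.0,
                       mean_ok=True, interpretation="none", consistent=True)
            records.append(rec)
            continue
        mean_a, sd_a = spec.analytic_moments()
        var_a = sd_a * sd_a
        rec["mean_analytic"] = mean_a
        rec["sd_analytic"] = sd_a
        if spec.family == "beta":
            rec["mean_ok"] = abs(mean_a - spec.mean) <= 0.005
        else:
            rec["mean_ok"] = abs(mean_a - spec.mean) <= 0.01 * abs(spec.mean)
        # dispersion printed with ~4 significant decimals; allow rounding slack
        var_ok = abs(var_a - spec.dispersion) <= max(1e-4, 0.05 * var_a)
        sd_ok = abs(sd_a - spec.dispersion) <= max(1e-3, 0.02 * sd_a)
        if sd_ok:
            interpretation = "sd"
        elif var_ok:
            interpretation = "variance"
        else:
            interpretation = "inconsistent"
        rec["interpretation"] = interpretation
        rec["consistent"] = bool(rec["mean_ok"] and interpretation != "inconsistent")
        records.append(rec)
    return pd.DataFrame(records).set_index("name")
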