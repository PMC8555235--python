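"""Run configuration: YAML-backed construction of a fully specified model.

All defaults mirror the base case, so an empty configuration is valid and
``base-case`` runs out of the box.  Recognised keys::

    parameters: path/to/table.csv        # default: packaged table
    scalars:                             # any Scalars field
      discount_rate_annual: 0.03
      wtp_per_qalm: 4000
      start_age: 55
      krepeatTLM: 1.0
    life_table:
      path: table.csv                    # 2-column CSV (age, qx), or
      target_e0: 81.9                    # calibrated Gompertz-Makeham
      b: 0.092
      c: 0.0005
    salvage:                             # any SalvageConfig field
      local_split_surgery: 0.5
    events:                              # replaces the complication registry
      - name: hemorrhage
        probability: phem
        cost: cPH
        utility: uPH
        duration_cycles: 1
        applies_to: [surgery]
    seed: 1
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .exceptions import SchemaError
from .lifetable import (
    DEFAULT_E0,
    DEFAULT_GOMPERTZ_B,
    DEFAULT_MAKEHAM_C,
    LifeTable,
    calibrate_to_life_expectancy,
    default_life_table,
)
from .markov import SalvageConfig
from .model import CostUtilityModel
from .parameters import Scalars, load_default_parameters, load_parameter_table
from .tree import ComplicationEvent, default_event_registry

__all__ = ["RunConfig", "load_config"]


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; ``build_model()`` materialises it."""

    parameters: str | None = None
    scalars: dict = dataclasses.field(default_factory=dict)
    life_table: dict = dataclasses.field(default_factory=dict)
    salvage: dict = dataclasses.field(default_factory=dict)
    events: list | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        scalar_fields = {f.name for f in dataclasses.fields(Scalars)}
        unknown = set(self.scalars) - scalar_fields
        if unknown:
            raise SchemaError(f"scalars: unknown fields {sorted(unknown)}")
        salvage_fields = {f.name for f in dataclasses.fields(SalvageConfig)}
        unknown = set(self.salvage) - salvage_fields
        if unknown:
            raise SchemaError(f"salvage: unknown fields {sorted(unknown)}")
        lt_fields = {"path", "target_e0", "b", "c"}
        unknown = set(self.life_table) - lt_fields
        if unknown:
            raise SchemaError(f"life_table: unknown fields {sorted(unknown)}")

    def build_life_table(self) -> LifeTable:
        if self.life_table.get("path"):
            return LifeTable.from_csv(self.life_table["path"])
        if self.life_table:
            return calibrate_to_life_expectancy(
                self.life_table.get("target_e0", DEFAULT_E0),
                b=self.life_table.get("b", DEFAULT_GOMPERTZ_B),
                c=self.life_table.get("c", DEFAULT_MAKEHAM_C),
            )
        return default_life_table()

    def build_registry(self) -> list[ComplicationEvent]:
        if self.events is None:
            return default_event_registry()
        registry = []
        for i, ev in enumerate(self.events):
            try:
                registry.append(
                    ComplicationEvent(
                        name=ev["name"],
                        probability_param=ev["probability"],
                        cost_param=ev["cost"],
                        utility_param=ev["utility"],
                        duration_cycles=int(ev.get("duration_cycles", 1)),
                        applies_to=frozenset(ev.get("applies_to", ["surgery"])),
                    )
                )
            except KeyError as exc:
                raise SchemaError(f"events[{i}]: missing field {exc}") from exc
        return registry

    def build_model(self) -> CostUtilityModel:
        scalars = Scalars(**self.scalars)
        if self.parameters:
            params = load_parameter_table(self.parameters, scalars=scalars)
        else:
            params = load_default_parameters(scalars=scalars)
        salvage = SalvageConfig(**self.salvage)
        salvage.validate()
        return CostUtilityModel(
            params=params,
            life_table=self.build_life_table(),
            salvage=salvage,
            registry=self.build_registry(),
        )

    def manifest(self) -> dict:
        """Reproducibility record: the config content, its hash, the version."""
        from . import __version__

        content = dataclasses.asdict(self)
        blob = json.dumps(content, sort_keys=True, default=str).encode()
        return {
            "package": "transoral-cua",
            "version": __version__,
            "config": content,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
        }


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration (``None`` -> all defaults)."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
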