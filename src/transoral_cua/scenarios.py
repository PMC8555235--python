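"""Random-but-valid scenario generation for property tests.

A scenario is a full :class:`~transoral_cua.parameters.ParameterSet` whose
point values are drawn from the parameter distributions (so every invariant
holds by construction) and then optionally constrained: clamped into
admissible ranges, forced symmetric across strategies, or costs zeroed.
Reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidParameterError
from .parameters import ParameterSet, load_default_parameters
from .psa import sample_parameters

__all__ = ["generate_scenario"]

#: TLM-side parameter -> TORS-side counterpart, used by the symmetric constraint.
_SYMMETRY_MAP = {"pTLMAlone": "pTorsAlone", "pCRT_TLM": "pCRT_tors", "cTLM": "cTORS"}


def generate_scenario(
    seed: int,
    ranges: dict | None = None,
    symmetric: bool = False,
    zero_costs: bool = False,
    base: ParameterSet | None = None,
) -> ParameterSet:
    """Draw a valid random scenario.

    Parameters
    ----------
    seed
        Seed for the random draw; identical seeds give identical scenarios.
    ranges
        Optional ``{name: (lo, hi)}`` map; drawn values are clamped into the
        range.  An empty range (lo > hi) raises.
    symmetric
        Force the TLM-side tree parameters equal to the TORS side, so the
        two strategies become identical (zero increments downstream).
    zero_costs
        Zero every cost parameter (strategy ranking then rests on QALMs).
    """
    if base is None:
        base = load_default_parameters()
    rng = np.random.default_rng(seed)
    scenario = sample_parameters(base, rng)
    if ranges:
        for name, (lo, hi) in ranges.items():
            if lo > hi:
                raise InvalidParameterError(f"unsatisfiable range for {name}: ({lo}, {hi})")
            scenario.set(name, float(np.clip(scenario[name], lo, hi)))
    if symmetric:
        for tlm_name, tors_name in _SYMMETRY_MAP.items():
            scenario.set(tlm_name, scenario[tors_name])
        scenario.scalars.krepeatTLM = 1.0
    if zero_costs:
        for name, spec in scenario.specs.items():
            if spec.role == "cost":
                scenario.values[name] = 0.0
    return scenario
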