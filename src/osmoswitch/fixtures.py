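"""Registry of packaged per-condition parameter sets.

The six headline (ionic strength, temperature) conditions live in
``data/conditions.yaml``; each loads into a :class:`FixtureConfig` whose
``model_params`` drive the synthetic generators. The YAML file is the
single source of truth for the condition parameters used in tests.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .datatypes import FixtureConfig

__all__ = ["load_conditions", "condition", "hns_dimer_params", "lifetimes_ns"]

_cache = None


def _raw() -> dict:
    global _cache
    if _cache is None:
        with resources.files("osmoswitch.data").joinpath("conditions.yaml").open() as fh:
            _cache = yaml.safe_load(fh)
    return _cache


def load_conditions(seed: int = 0) -> dict:
    """All packaged conditions as label -> FixtureConfig."""
    out = {}
    for label, spec in _raw()["conditions"].items():
        params = {k: v for k, v in spec.items()
                  if k not in ("ionic_strength_mM", "temperature_C")}
        out[label] = FixtureConfig(condition_label=label,
                                   ionic_strength_mM=spec["ionic_strength_mM"],
                                   temperature_C=spec["temperature_C"],
                                   model_params=params, seed=seed)
    return out


def condition(label: str, seed: int = 0) -> FixtureConfig:
    """One packaged condition by label (e.g. ``"IS14.5_T37"``)."""
    conds = load_conditions(seed)
    if label not in conds:
        raise KeyError(f"unknown condition {label!r}; "
                       f"available: {', '.join(sorted(conds))}")
    return conds[label]


def hns_dimer_params() -> dict:
    """Packaged H-NS monomer-dimer parameters (K_D in the 100-150 uM range)."""
    return dict(_raw()["hns_dimer"])


def lifetimes_ns() -> list:
    """The salt-independent long/short lifetime pair used by decay fixtures."""
    return list(_raw()["lifetimes_ns"])
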