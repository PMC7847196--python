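"""YAML configuration: named parameter sets and power-study configs."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .params import GrowthParams

__all__ = ["load_params", "load_power_config", "named_params"]

_PARAM_KEYS = ("mu1", "mu2", "sigma1", "sigma2", "sigma3")


def named_params(name: str) -> GrowthParams:
    """Load one of the shipped parameter sets ('pdx' or 'cdx')."""
    ref = resources.files("xenopower") / "configs" / f"{name.lower()}.yaml"
    if not ref.is_file():
        raise KeyError(f"no shipped parameter set named {name!r}")
    with ref.open() as fh:
        return _params_from_mapping(yaml.safe_load(fh))


def _params_from_mapping(d: dict) -> GrowthParams:
    missing = [k for k in _PARAM_KEYS if k not in d]
    if missing:
        raise ValueError(f"parameter config missing key(s): {', '.join(missing)}")
    return GrowthParams.from_dict(d)


def load_params(source) -> GrowthParams:
    """Parameter set from a shipped name, a YAML path, or a mapping."""
    if isinstance(source, GrowthParams):
        return source
    if isinstance(source, dict):
        return _params_from_mapping(source)
    p = Path(source)
    if p.suffix in (".yaml", ".yml") or p.exists():
        with open(p) as fh:
            return _params_from_mapping(yaml.safe_load(fh))
    return named_params(str(source))


def load_power_config(path) -> dict:
    """Power-study config: parameter source plus grid lists.

    Keys: ``params`` (name, path or mapping), ``tgi_targets``,
    ``n_per_arm``, ``horizons``, ``methods``, ``reps``, ``seed``.
    Missing grid keys fall back to the default design.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = {
        "params": load_params(raw["params"]),
        "tgi_targets": raw.get("tgi_targets", [50.0, 100.0]),
        "n_per_arm": raw.get("n_per_arm", [5, 8, 10, 12, 15]),
        "horizons": raw.get("horizons", [14.0, 21.0, 28.0]),
        "methods": raw.get("methods", ["empirical", "mixed"]),
        "reps": int(raw.get("reps", 1000)),
        "seed": int(raw.get("seed", 0)),
    }
    return cfg
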