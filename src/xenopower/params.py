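"""Population parameters of the linear-radius tumour growth model.

The model assumes a spherical tumour whose radius grows linearly in time
(Mayneord growth): ``R_ij = (a_i + b_i * t_ij) * (1 + e_ij)`` where, per
animal ``i``, the baseline radius ``a_i`` and the radial growth rate ``b_i``
are lognormally distributed across the population and ``e_ij`` is
proportional (heteroscedastic) measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["GrowthParams", "EFFECT_SCALES"]

EFFECT_SCALES = ("log_shift", "natural_shift")


@dataclass(frozen=True)
class GrowthParams:
    """Population parameters of the linear-radius growth model.

    Parameters
    ----------
    mu1 : float
        Mean of log baseline radius, log(mm).
    mu2 : float
        Mean of log radial growth rate, log(mm/day).
    sigma1 : float
        SD of log baseline radius across animals (>= 0).
    sigma2 : float
        SD of log growth rate across animals (>= 0).
    sigma3 : float
        Proportional residual SD, dimensionless (>= 0).
    c : float
        Treatment effect on the growth rate of treated animals;
        0 means no effect.  Its meaning depends on ``effect_scale``.
    effect_scale : {"log_shift", "natural_shift"}
        ``log_shift`` (default): ``c`` shifts the mean of log b, i.e.
        treated rates are multiplied by ``exp(c)`` on average.
        ``natural_shift``: the growth rate is treated as a
        moment-matched Normal on the natural scale whose mean is
        shifted additively by ``c`` (the only scale on which 100%
        growth inhibition is exactly attainable).
    """

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    sigma3: float
    c: float = 0.0
    effect_scale: str = "log_shift"

    def __post_init__(self) -> None:
        for name in ("mu1", "mu2", "sigma1", "sigma2", "sigma3", "c"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        for name in ("sigma1", "sigma2", "sigma3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_scale not in EFFECT_SCALES:
            raise ValueError(
                f"effect_scale must be one of {EFFECT_SCALES}, "
                f"got {self.effect_scale!r}"
            )

    def with_effect(self, c: float, effect_scale: str | None = None) -> "GrowthParams":
        """Return a copy with a new treatment effect (and optionally scale)."""
        kwargs = {"c": c}
        if effect_scale is not None:
            kwargs["effect_scale"] = effect_scale
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "mu1": self.mu1,
            "mu2": self.mu2,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
            "sigma3": self.sigma3,
            "c": self.c,
            "effect_scale": self.effect_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParams":
        known = {k: d[k] for k in
                 ("mu1", "mu2", "sigma1", "sigma2", "sigma3", "c", "effect_scale")
                 if k in d}
        return cls(**known)
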