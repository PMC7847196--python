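"""Monte-Carlo power engine for two-arm xenograft designs.

For each design cell (target %TGI, animals per arm, study length, analysis
method) the engine calibrates the treatment effect to the target TGI,
simulates many replicate studies, applies the chosen analysis, and records
the fraction declared significant at alpha = 0.05 together with its
binomial Monte-Carlo standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .empirical import empirical_test
from .growth import calibrate_c, default_schedule, simulate_study
from .model import lr_treatment_test
from .params import GrowthParams

__all__ = [
    "METHODS",
    "PowerCell",
    "PowerGridResult",
    "SignificanceCurve",
    "run_power_cell",
    "run_power_table",
    "significance_curve",
]

METHODS = ("empirical", "mixed", "pooled")

GRID_COLUMNS = [
    "tgi_target", "n_per_arm", "horizon", "method",
    "reps", "power_percent", "mc_se", "seed",
]


@dataclass
class PowerCell:
    tgi_target: float
    n_per_arm: int
    horizon: float
    method: str
    reps: int
    power_percent: float
    mc_se: float
    seed: int
    n_failed: int = 0

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in GRID_COLUMNS}


@dataclass
class PowerGridResult:
    """Power estimates over a Cartesian design grid."""

    cells: list

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.cells], columns=GRID_COLUMNS)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def power(self, tgi_target, n_per_arm, horizon, method) -> float:
        """Power (percent) of one cell of the grid."""
        for c in self.cells:
            if (
                c.tgi_target == tgi_target
                and c.n_per_arm == n_per_arm
                and c.horizon == horizon
                and c.method == method
            ):
                return c.power_percent
        raise KeyError("no such cell in the grid")


def _apply_method(study, method: str):
    if method == "empirical":
        return empirical_test(study)
    if method in ("mixed", "pooled"):
        return lr_treatment_test(study, approach=method)
    raise ValueError(f"method must be one of {METHODS}, got {method!r}")


def run_power_cell(
    params: GrowthParams,
    tgi_target: float,
    n_per_arm: int,
    horizon: float,
    method: str,
    reps: int = 1000,
    seed=None,
    alpha: float = 0.05,
    schedule=None,
) -> PowerCell:
    """Estimate power for one design cell.

    The effect ``c`` is calibrated so the model-expected TGI at the horizon
    equals ``tgi_target`` (0 means the null); ``reps`` studies are then
    simulated and analysed.  Replicates whose analysis fails outright are
    counted as non-significant and tallied in ``n_failed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    c = calibrate_c(params, tgi_target, horizon)
    sim_params = params.with_effect(c)
    if schedule is None:
        schedule = default_schedule(horizon)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(reps)
    n_sig = 0
    n_failed = 0
    for r in range(reps):
        study = simulate_study(
            sim_params, n_per_arm=n_per_arm, horizon=horizon,
            schedule=schedule, seed=rep_seeds[r], study_id=f"rep{r}",
        )
        try:
            result = _apply_method(study, method)
        except (ValueError, ZeroDivisionError):
            n_failed += 1
            continue
        if result.p_value < alpha:
            n_sig += 1
    p_hat = n_sig / reps
    return PowerCell(
        tgi_target=float(tgi_target),
        n_per_arm=int(n_per_arm),
        horizon=float(horizon),
        method=method,
        reps=int(reps),
        power_percent=100.0 * p_hat,
        mc_se=100.0 * math.sqrt(p_hat * (1.0 - p_hat) / reps),
        seed=-1 if seed is None or isinstance(seed, np.random.SeedSequence)
        else int(seed),
        n_failed=n_failed,
    )


def run_power_table(
    params: GrowthParams,
    tgi_targets=(50.0, 100.0),
    n_per_arm=(5, 8, 10, 12, 15),
    horizons=(14.0, 21.0, 28.0),
    methods=("empirical", "mixed"),
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PowerGridResult:
    """Power over the full Cartesian design grid.

    Deterministic for a given root seed: each cell's seed is derived from
    the root seed and the cell's index in the grid, so cells may be
    recomputed independently or in parallel.
    """
    cells = []
    idx = 0
    for tgi_t in tgi_targets:
        for n in n_per_arm:
            for h in horizons:
                for method in methods:
                    cell_seed = np.random.SeedSequence((int(seed), idx))
                    cells.append(
                        run_power_cell(
                            params, tgi_t, n, h, method,
                            reps=reps, seed=cell_seed, alpha=alpha,
                        )
                    )
                    cells[-1].seed = int(seed)
                    idx += 1
    return PowerGridResult(cells=cells)


@dataclass
class SignificanceCurve:
    """Cumulative significance fraction as a function of observed %TGI.

    At each distinct TGI value x, ``fraction[i]`` is the share of studies
    with TGI <= x that were significant — i.e. how often an effect at most
    that large was detected, probing the smallest detectable TGI.
    """

    tgi: np.ndarray
    fraction: np.ndarray
    alpha: float

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.tgi, self.fraction, where="post", **kwargs)
        ax.set_xlabel("%TGI")
        ax.set_ylabel(f"cumulative fraction of studies with p < {self.alpha:g}")
        ax.set_ylim(-0.02, 1.02)
        return ax


def significance_curve(results, alpha: float = 0.05) -> SignificanceCurve:
    """Build the cumulative significance-vs-TGI curve.

    ``results`` is an iterable of (tgi_percent, p_value) pairs, one per
    study.
    """
    pairs = sorted((float(t), float(p)) for t, p in results)
    if not pairs:
        raise ValueError("results must be non-empty")
    tgis = np.array([t for t, _ in pairs])
    sig = np.array([p < alpha for _, p in pairs], dtype=float)
    cum_sig = np.cumsum(sig)
    counts = np.arange(1, len(pairs) + 1)
    # collapse to distinct TGI values (keep the last entry of each run)
    last = np.r_[tgis[1:] != tgis[:-1], True]
    return SignificanceCurve(
        tgi=tgis[last], fraction=(cum_sig / counts)[last], alpha=alpha
    )
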