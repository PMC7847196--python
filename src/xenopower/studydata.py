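"""I/O and assembly of long-format tumour-volume tables.

The canonical flat schema is CSV with header ``study,arm,animal,day,volume_mm3``
(a configurable column mapping is accepted on ingest).  A database holds many
two-arm studies; each can be truncated to a horizon and assembled into
:class:`~xenopower.growth.StudyTable` objects for analysis.  A generator
produces synthetic multi-study databases with the growth model's statistical
structure, standing in for external PDX screen exports.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .growth import (
    AnimalTrajectory,
    StudyTable,
    calibrate_c,
    default_schedule,
    simulate_study,
)
from .params import GrowthParams

__all__ = [
    "COLUMNS",
    "StudyDatabase",
    "read_database",
    "write_database",
    "truncate",
    "generate_database",
    "batch_analyze",
]

logger = logging.getLogger(__name__)

COLUMNS = ["study", "arm", "animal", "day", "volume_mm3"]

_ARM_ALIASES = {
    "control": "control",
    "treated": "treated",
    "treatment": "treated",
    "vehicle": "control",
}


class StudyDatabase:
    """Validated collection of two-arm tumour-volume records."""

    def __init__(self, df: pd.DataFrame):
        self.df = self._validate(df)

    # -- construction --------------------------------------------------------

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        df = df[COLUMNS].copy()
        df["study"] = df["study"].astype(str)
        df["animal"] = df["animal"].astype(str)
        df["volume_mm3"] = pd.to_numeric(df["volume_mm3"])
        df["day"] = pd.to_numeric(df["day"])
        # arm normalisation
        arm = df["arm"].astype(str).str.strip().str.lower()
        unknown = sorted(set(arm) - set(_ARM_ALIASES))
        if unknown:
            raise ValueError(
                f"unrecognised arm label(s) {unknown}; expected "
                f"{sorted(set(_ARM_ALIASES))}"
            )
        df["arm"] = arm.map(_ARM_ALIASES)
        # non-positive volumes are rejected, with a counted log line
        bad = df["volume_mm3"] <= 0
        if bad.any():
            logger.warning("rejected %d row(s) with non-positive volume", bad.sum())
            df = df[~bad]
        # fractional days are floored
        frac = df["day"] % 1 != 0
        if frac.any():
            logger.warning("floored %d row(s) with fractional day values", frac.sum())
            df["day"] = np.floor(df["day"])
        if df["day"].min() < 0:
            raise ValueError("days must be >= 0 (day 0 = randomisation)")
        dup = df.duplicated(subset=["study", "animal", "day"])
        if dup.any():
            keys = df.loc[dup, ["study", "animal", "day"]].iloc[0].tolist()
            raise ValueError(
                f"duplicate (study, animal, day) record(s), first at {keys}"
            )
        one_armed = [
            s for s, g in df.groupby("study") if set(g["arm"]) != {"control", "treated"}
        ]
        if one_armed:
            raise ValueError(
                f"study(ies) lacking both arms: {', '.join(sorted(one_armed))}"
            )
        return df.sort_values(["study", "arm", "animal", "day"]).reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, column_map: dict | None = None):
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
        return cls(df)

    # -- introspection -------------------------------------------------------

    @property
    def study_ids(self) -> list:
        return sorted(self.df["study"].unique())

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    def __len__(self) -> int:
        return len(self.df)

    # -- transformation ------------------------------------------------------

    def truncate(self, horizon: float) -> "StudyDatabase":
        """Drop records past the horizon day; animals left with fewer than
        two records are dropped (and counted in the log)."""
        if horizon <= 0:
            raise ValueError("horizon must be > 0")
        df = self.df[self.df["day"] <= horizon]
        counts = df.groupby(["study", "animal"])["day"].transform("size")
        short = counts < 2
        n_dropped = df[short].groupby(["study", "animal"]).ngroups
        if n_dropped:
            logger.warning(
                "dropped %d animal(s) with <2 records within day %g",
                n_dropped, horizon,
            )
        return StudyDatabase(df[~short])

    def to_study_tables(self, horizon: float | None = None) -> list:
        """Assemble one StudyTable per study (horizon defaults to each
        study's last measured day)."""
        tables = []
        for sid, g in self.df.groupby("study"):
            h = float(horizon if horizon is not None else g["day"].max())
            animals = [
                AnimalTrajectory(
                    animal_id=aid,
                    arm=ag["arm"].iloc[0],
                    times=ag["day"].to_numpy(dtype=float),
                    volumes=ag["volume_mm3"].to_numpy(dtype=float),
                )
                for (aid, ag) in g.groupby("animal")
            ]
            tables.append(StudyTable(study_id=str(sid), animals=animals, horizon=h))
        return tables


def read_database(path, column_map: dict | None = None) -> StudyDatabase:
    """Read and validate a long-format CSV of tumour volumes.

    ``column_map`` maps canonical names to file column names, e.g.
    ``{"volume_mm3": "Volume"}``.
    """
    df = pd.read_csv(path)
    return StudyDatabase.from_dataframe(df, column_map)


def write_database(db: StudyDatabase, path) -> None:
    """Write a database back to the canonical CSV schema."""
    db.df.to_csv(path, index=False, columns=COLUMNS)


def truncate(db: StudyDatabase, horizon: float) -> StudyDatabase:
    return db.truncate(horizon)


def generate_database(
    params_control: GrowthParams,
    n_studies: int,
    n_per_arm: int = 10,
    horizon: float = 21.0,
    schedule=None,
    effect_distribution=None,
    seed=None,
) -> StudyDatabase:
    """Synthetic multi-study database with the growth model's structure.

    Per study, a treatment effect is drawn from ``effect_distribution`` —
    a callable ``rng -> target %TGI`` (default: uniform on [0, 100)) —
    mapped through :func:`~xenopower.growth.calibrate_c`, and a two-arm
    study is simulated on the measurement schedule.  Deterministic for a
    given seed.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    if schedule is None:
        schedule = default_schedule(horizon)
    ss = np.random.SeedSequence(seed)
    effect_rng = np.random.default_rng(ss.spawn(1)[0])
    study_seeds = ss.spawn(n_studies + 1)[1:]
    frames = []
    for k in range(n_studies):
        if effect_distribution is None:
            target = float(effect_rng.uniform(0.0, 100.0))
        else:
            target = float(effect_distribution(effect_rng))
        c = calibrate_c(params_control, target, horizon)
        study = simulate_study(
            params_control.with_effect(c),
            n_per_arm=n_per_arm,
            horizon=horizon,
            schedule=schedule,
            seed=study_seeds[k],
            study_id=f"S{k + 1:03d}",
        )
        frames.append(study.to_dataframe())
    df = pd.concat(frames, ignore_index=True)
    return StudyDatabase(df)


def batch_analyze(
    db: StudyDatabase,
    horizons=(14, 21, 28),
    methods=("empirical",),
    t_variant: str = "student",
) -> pd.DataFrame:
    """Analyse every study at every horizon with the requested methods.

    Returns one row per (study, horizon, method) with the observed %TGI
    and the method's p-value.  Per-study failures (e.g. no growth, too few
    animals after truncation) are logged and skipped; the batch continues.
    """
    from .empirical import empirical_test, study_tgi
    from .model import lr_treatment_test

    rows = []
    n_failed = 0
    for horizon in horizons:
        try:
            trunc = db.truncate(horizon)
        except ValueError:
            n_failed += len(methods) * db.n_studies
            continue
        for study in trunc.to_study_tables(horizon):
            try:
                observed_tgi = study_tgi(study).tgi_percent
            except (ValueError, ZeroDivisionError) as exc:
                logger.warning(
                    "study %s day %g skipped: %s", study.study_id, horizon, exc
                )
                n_failed += len(methods)
                continue
            for method in methods:
                try:
                    if method == "empirical":
                        tr = empirical_test(study, variant=t_variant)
                    elif method in ("mixed", "pooled"):
                        tr = lr_treatment_test(study, approach=method)
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    rows.append(
                        {
                            "study_id": study.study_id,
                            "horizon": float(horizon),
                            "method": method,
                            "tgi_percent": observed_tgi,
                            "statistic": tr.statistic,
                            "p_value": tr.p_value,
                            "effect": tr.effect,
                        }
                    )
                except ValueError as exc:
                    logger.warning(
                        "study %s day %g method %s failed: %s",
                        study.study_id, horizon, method, exc,
                    )
                    n_failed += 1
    if n_failed:
        logger.warning("batch analysis skipped %d study-method combination(s)", n_failed)
    return pd.DataFrame(
        rows,
        columns=[
            "study_id", "horizon", "method", "tgi_percent",
            "statistic", "p_value", "effect",
        ],
    )
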