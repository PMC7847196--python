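"""Conventional two-arm analysis: %TGI from arm-mean volumes and the
unpaired two-tailed t-test on final-day volumes."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .growth import StudyTable
from .model import TestResult

__all__ = ["TgiSummary", "tgi", "study_tgi", "t_test", "empirical_test"]


@dataclass
class TgiSummary:
    """Observed tumour growth inhibition of one study at its horizon."""

    tgi_percent: float
    mean_control_T: float
    mean_treated_T: float
    mean_control_0: float
    horizon: float
    n_control: int
    n_treated: int

    def __str__(self) -> str:  # one decimal, as commonly tabulated
        return (
            f"TGI {self.tgi_percent:.1f}% at day {self.horizon:g} "
            f"(control n={self.n_control}, treated n={self.n_treated})"
        )


def tgi(mean_control_T: float, mean_treated_T: float, mean_control_0: float) -> float:
    """%TGI = 100 * (Vc_T - Vt_T) / (Vc_T - Vc_0).

    ``Vc_T`` / ``Vt_T`` are arm-mean volumes at the end of the study and
    ``Vc_0`` the control mean at randomisation.  Values above 100 indicate
    tumour regression; negative values a treated arm growing faster than
    control.
    """
    denom = mean_control_T - mean_control_0
    if denom == 0:
        raise ZeroDivisionError(
            "TGI undefined: control mean did not change over the study"
        )
    return 100.0 * (mean_control_T - mean_treated_T) / denom


def _final_volumes(study: StudyTable, arm: str) -> np.ndarray:
    """Each animal's last measurement at or before the horizon."""
    vols = []
    for a in study.arm_animals(arm):
        sel = a.times <= study.horizon
        if not sel.any():
            raise ValueError(
                f"animal {a.animal_id!r} has no measurement at or before "
                f"day {study.horizon:g}"
            )
        vols.append(a.volumes[sel][-1])
    return np.asarray(vols)


def _baseline_volumes(study: StudyTable, arm: str = "control") -> np.ndarray:
    vols = []
    for a in study.arm_animals(arm):
        at0 = a.times == 0
        if not at0.any():
            raise ValueError(
                f"animal {a.animal_id!r} lacks a randomisation (day 0) measurement"
            )
        vols.append(a.volumes[at0][0])
    return np.asarray(vols)


def study_tgi(study: StudyTable) -> TgiSummary:
    """Observed %TGI of a study from final-day and day-0 arm means."""
    vc = _final_volumes(study, "control")
    vt = _final_volumes(study, "treated")
    v0 = _baseline_volumes(study)
    return TgiSummary(
        tgi_percent=tgi(vc.mean(), vt.mean(), v0.mean()),
        mean_control_T=float(vc.mean()),
        mean_treated_T=float(vt.mean()),
        mean_control_0=float(v0.mean()),
        horizon=float(study.horizon),
        n_control=len(vc),
        n_treated=len(vt),
    )


def t_test(
    control_volumes,
    treated_volumes,
    variant: str = "student",
    horizon: float = float("nan"),
    effect: float = float("nan"),
) -> TestResult:
    """Unpaired two-tailed t-test on final-day volumes.

    The statistic is positive when the control mean exceeds the treated
    mean.  ``variant='student'`` pools variances (classical test);
    ``'welch'`` drops the equal-variance assumption.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    x = np.asarray(control_volumes, dtype=float)
    y = np.asarray(treated_volumes, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 volumes per arm")
    if x.std() == 0 and y.std() == 0:
        # degenerate: no within-arm variability at all
        if x.mean() == y.mean():
            stat, p = 0.0, 1.0
        else:
            stat = math.copysign(float("inf"), x.mean() - y.mean())
            p = 0.0
    else:
        res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        method="t_test", statistic=stat, p_value=p, effect=effect, horizon=horizon
    )


def empirical_test(study: StudyTable, variant: str = "student") -> TestResult:
    """Full empirical analysis of one study: final-day t-test, with the
    observed %TGI reported as the effect size."""
    summary = study_tgi(study)
    return t_test(
        _final_volumes(study, "control"),
        _final_volumes(study, "treated"),
        variant=variant,
        horizon=float(study.horizon),
        effect=summary.tgi_percent,
    )
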