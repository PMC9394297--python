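"""Phase windows, trapezoidal AUC and the % antinociception statistic.

The formalin test yields a biphasic flinch time course: an early phase
driven by direct nociceptor activation and a late inflammatory phase.
Analysis is restricted to the late phase. A subject's cumulative
nociception is the trapezoidal area under its count-vs-time curve over
the phase window (counts·min), and the treatment effect is

    %antinociception = (AUC_control_mean - AUC_subject) / AUC_control_mean * 100

i.e. the fractional suppression of nociceptive activity relative to the
vehicle-control group mean. Negative values indicate hyperalgesia.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from math import sqrt

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .study import StudyTable, TimeCourse

Interval = tuple[float, float]


@dataclass(frozen=True)
class PhaseWindows:
    """Closed time intervals (minutes) delimiting the two formalin phases.

    Defaults: phase 1 = [0, 10], phase 2 = [15, 60] — the conventional
    formalin-test windows; both configurable.
    """

    phase1: Interval = (0.0, 10.0)
    phase2: Interval = (15.0, 60.0)

    def __post_init__(self):
        (a1, b1), (a2, b2) = self.phase1, self.phase2
        if not (0 <= a1 <= b1 and a2 <= b2 <= 60):
            raise ValidationError(f"phase windows must lie within [0, 60]: {self}")
        if b1 > a2:
            raise ValidationError(
                f"phase1 must precede phase2 without overlap: {self}"
            )


def trapezoid_auc(tc: TimeCourse, window: Interval) -> float:
    """Trapezoidal AUC of a timecourse over a closed window (counts·min).

    Window endpoints must coincide with observation times; a zero-width
    window has zero area.
    """
    lo, hi = window
    times = np.asarray(tc.times, dtype=float)
    if lo not in times or hi not in times:
        raise ValidationError(
            f"window {window} endpoints must lie on the observation grid "
            f"{tuple(times)} (subject {tc.subject!r})"
        )
    mask = (times >= lo) & (times <= hi)
    t = times[mask]
    c = np.asarray(tc.counts, dtype=float)[mask]
    return float(np.trapezoid(c, t))


def percent_antinociception(auc_control_mean: float, auc_subject: float) -> float:
    """Percent suppression of a subject's AUC relative to the control mean.

    May be negative (hyperalgesia) and is at most 100 for non-negative AUCs.
    """
    if not auc_control_mean > 0:
        raise ComputationError(
            f"control mean AUC must be positive, got {auc_control_mean}"
        )
    return (auc_control_mean - auc_subject) / auc_control_mean * 100.0


@dataclass(frozen=True)
class AUCRecord:
    subject: str
    window: Interval
    auc: float


@dataclass(frozen=True)
class GroupEffect:
    """An arm's mean % antinociception ± SEM over its subjects."""

    arm: str
    mean_effect: float
    sem: float | None  # None (undefined) when n == 1
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("GroupEffect.n must be >= 1")
        if self.sem is not None and self.sem < 0:
            raise ValidationError("SEM must be non-negative")


def control_mean_auc(study: StudyTable, windows: PhaseWindows | None = None) -> float:
    """Mean phase-2 AUC of the vehicle-control group (the Eq-3 denominator)."""
    windows = windows or PhaseWindows()
    control = study.control_arm
    tcs = study.timecourses_for(control.label)
    if len(tcs) < 2:
        raise ValidationError(
            f"control arm {control.label!r} needs >= 2 subjects, has {len(tcs)}"
        )
    return mean(trapezoid_auc(tc, windows.phase2) for tc in tcs)


def subject_effects(
    study: StudyTable, arm: str, windows: PhaseWindows | None = None
) -> list[float]:
    """Per-subject % antinociception for one arm against the control mean AUC."""
    windows = windows or PhaseWindows()
    auc_c = control_mean_auc(study, windows)
    return [
        percent_antinociception(auc_c, trapezoid_auc(tc, windows.phase2))
        for tc in study.timecourses_for(arm)
    ]


def group_effect(
    study: StudyTable, arm: str, windows: PhaseWindows | None = None
) -> GroupEffect:
    """Mean ± SEM % antinociception of an arm.

    The control mean AUC is computed once; each subject's effect is taken
    against it, then averaged. Evaluated on the control arm itself the
    mean is exactly zero by construction.
    """
    effects = subject_effects(study, arm, windows)
    n = len(effects)
    sem = stdev(effects) / sqrt(n) if n > 1 else None
    return GroupEffect(arm=arm, mean_effect=mean(effects), sem=sem, n=n)


def metrics_table(
    study: StudyTable, windows: PhaseWindows | None = None
) -> pd.DataFrame:
    """Per-subject metrics (long): subject, arm, phase, auc, percent_antinociception."""
    windows = windows or PhaseWindows()
    auc_c = control_mean_auc(study, windows)
    rows = []
    for tc in study.timecourses:
        for phase, window in (("phase1", windows.phase1), ("phase2", windows.phase2)):
            try:
                auc = trapezoid_auc(tc, window)
            except ValidationError:
                continue  # phase window off this subject's grid
            rows.append(
                {
                    "subject": tc.subject,
                    "arm": tc.arm,
                    "phase": phase,
                    "auc": auc,
                    "percent_antinociception": percent_antinociception(auc_c, auc)
                    if phase == "phase2"
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def group_summary_table(
    study: StudyTable, windows: PhaseWindows | None = None
) -> pd.DataFrame:
    """Group summary: arm, n, mean, sem (phase-2 % antinociception)."""
    rows = []
    for label in study.arms:
        ge = group_effect(study, label, windows)
        rows.append(
            {"arm": label, "n": ge.n, "mean": ge.mean_effect, "sem": ge.sem}
        )
    return pd.DataFrame(rows)
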