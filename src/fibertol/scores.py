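"""Severity and adaptation scoring of weekly symptom diaries.

Two families of scores quantify how a subject experienced a fiber
supplement and how they adapted to it over six weeks:

* MAX scores compare the highest rating reported during weeks 1-5
  against baseline (severity) or against the week-6 rating (adaptation).
* AUC scores integrate the rating trajectory by the trapezoidal rule.
  ``auc_severity`` defaults to the incremental convention (ratings minus
  baseline over weeks 0-6; a no-change subject scores exactly 0) with a
  ``raw`` alternative that integrates unshifted ratings (null value 24
  for a constant composite rating of 4).  ``auc_adaptation`` divides the
  weeks-1-3 raw-rating area by the weeks-4-6 area and equals 1 for any
  constant trajectory.

Week 6 is deliberately excluded from the MAX maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fibertol.datamodel import (
    COMPOSITE_SYMPTOMS,
    N_WEEKS,
    RATING_MAX,
    RATING_MIN,
    SCORED_SYMPTOMS,
    SymptomDiary,
    ToleranceScores,
    UndefinedScoreError,
    ValidationError,
)

#: Offsets used by the scaled-magnitude display convention: the null
#: (no-change) value of each score type under raw-mode AUCs.
SCALED_OFFSETS = {
    "auc_severity_raw": 24.0,
    "auc_severity_incremental": 0.0,
    "auc_adaptation": 1.0,
    "max_severity": 0.0,
    "max_adaptation": 0.0,
}

#: A subject "reverted to baseline" when severity and adaptation MAX
#: scores differ by at most this many points.
REVERTED_TOLERANCE = 1


def composite_rating(flatulence: int, bloating: int, stomachache: int) -> int:
    """Sum the three component ratings into the weekly composite (0-12)."""
    total = 0
    for name, value in (
        ("flatulence", flatulence),
        ("bloating", bloating),
        ("stomachache", stomachache),
    ):
        if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
            raise ValidationError(f"{name} rating {value!r} is not an integer")
        if not RATING_MIN <= value <= RATING_MAX:
            raise ValidationError(
                f"{name} rating {value} outside [{RATING_MIN}, {RATING_MAX}]"
            )
        total += int(value)
    return total


def composite_trajectory(diary: SymptomDiary) -> list[int | None]:
    """Weekly composite ratings for a diary; None where any component is missing."""
    out: list[int | None] = []
    for week in range(N_WEEKS):
        parts = [diary.ratings[s][week] for s in COMPOSITE_SYMPTOMS]
        if any(p is None for p in parts):
            out.append(None)
        else:
            out.append(composite_rating(*parts))
    return out


def _resolve_missing(
    trajectory: list[int | None] | list[float | None],
    required: list[int],
    policy: str,
    what: str,
) -> np.ndarray:
    """Return a full 7-week float vector honoring the missing-data policy.

    ``strict`` raises when any required week is absent; ``interpolate``
    fills gaps linearly from the nearest observed weeks (edge values are
    held).  At least one observation is always required.
    """
    if policy not in ("strict", "interpolate"):
        raise ValueError(f"unknown missing policy {policy!r}")
    values = np.array(
        [np.nan if v is None else float(v) for v in trajectory], dtype=float
    )
    if len(values) != N_WEEKS:
        raise ValidationError(f"trajectory must have {N_WEEKS} entries")
    missing = [w for w in required if np.isnan(values[w])]
    if missing and policy == "strict":
        raise UndefinedScoreError(
            f"{what}: weeks {missing} missing under strict policy"
        )
    if np.isnan(values).any():
        observed = np.flatnonzero(~np.isnan(values))
        if observed.size == 0:
            raise UndefinedScoreError(f"{what}: all weeks missing")
        gaps = np.flatnonzero(np.isnan(values))
        values[gaps] = np.interp(gaps, observed, values[observed])
    return values


def max_severity(
    trajectory: list[int | None], missing: str = "strict"
) -> int:
    """Highest rating in weeks 1-5 minus baseline; week 6 is not consulted."""
    traj = list(trajectory)
    if all(traj[w] is None for w in range(1, 6)):
        raise UndefinedScoreError("max_severity: all of weeks 1-5 missing")
    if traj[0] is None:
        raise UndefinedScoreError("max_severity: baseline rating missing")
    values = _resolve_missing(traj, list(range(6)), missing, "max_severity")
    return int(round(values[1:6].max() - values[0]))


def max_adaptation(
    trajectory: list[int | None], missing: str = "strict"
) -> int:
    """Highest rating in weeks 1-5 minus the week-6 rating."""
    traj = list(trajectory)
    if traj[6] is None:
        raise UndefinedScoreError("max_adaptation: week 6 rating missing")
    if all(traj[w] is None for w in range(1, 6)):
        raise UndefinedScoreError("max_adaptation: all of weeks 1-5 missing")
    values = _resolve_missing(traj, list(range(1, 7)), missing, "max_adaptation")
    return int(round(values[1:6].max() - values[6]))


def trapezoid_auc(values, week_coords) -> float:
    """Trapezoidal area of ``values`` over unit-spaced ``week_coords``."""
    values = np.asarray(values, dtype=float)
    weeks = np.asarray(week_coords, dtype=float)
    if values.shape != weeks.shape or values.ndim != 1:
        raise ValueError("values and week_coords must be aligned 1-d vectors")
    if len(values) < 2:
        raise ValueError("trapezoid_auc needs at least two points")
    diffs = np.diff(weeks)
    if np.any(diffs <= 0) or np.any(diffs != np.round(diffs)):
        raise ValueError("week_coords must be strictly increasing integers")
    return float(np.trapezoid(values, weeks))


def auc_severity(
    trajectory: list[int | None],
    mode: str = "incremental",
    missing: str = "strict",
) -> float:
    """Trapezoid area of the rating trajectory over weeks 0-6.

    Incremental mode integrates ratings minus baseline (null value 0);
    raw mode integrates unshifted ratings (null 6x the constant rating).
    """
    if mode not in ("incremental", "raw"):
        raise ValueError(f"unknown auc_severity mode {mode!r}")
    values = _resolve_missing(
        list(trajectory), list(range(N_WEEKS)), missing, "auc_severity"
    )
    if mode == "incremental":
        values = values - values[0]
    return trapezoid_auc(values, np.arange(N_WEEKS))


@dataclass
class AdaptationAUC:
    """Segment areas and their ratio, with degenerate-case flags."""

    ratio: float
    auc_w13: float
    auc_w46: float
    flags: tuple[str, ...] = ()


def auc_adaptation(
    trajectory: list[int | None], missing: str = "strict"
) -> AdaptationAUC:
    """Ratio of the weeks-1-3 raw-rating area to the weeks-4-6 area.

    Both segments are two-interval trapezoids over raw ratings; no
    interval straddles the boundary between them.  A trajectory with no
    symptoms in either window returns 1 (flag ``zero_symptoms``); one
    with symptoms early but a zero weeks-4-6 area returns ``inf`` with
    the ``complete_resolution`` flag and is excluded from correlations
    downstream.
    """
    values = _resolve_missing(
        list(trajectory), list(range(1, N_WEEKS)), missing, "auc_adaptation"
    )
    w13 = trapezoid_auc(values[1:4], np.array([1, 2, 3]))
    w46 = trapezoid_auc(values[4:7], np.array([4, 5, 6]))
    if w46 == 0:
        if w13 == 0:
            return AdaptationAUC(1.0, w13, w46, ("zero_symptoms",))
        return AdaptationAUC(math.inf, w13, w46, ("complete_resolution",))
    if w13 == 0:
        # symptoms appeared only late; the ratio degenerates to 0
        return AdaptationAUC(0.0, w13, w46, ("late_onset",))
    return AdaptationAUC(w13 / w46, w13, w46)


def scaled_magnitude(score: float, offset: float, sd: float) -> float:
    """Affine rescale ``(score - offset) / sd`` used for display sizing.

    ``offset`` is the null value of the score type (24 for raw-mode AUC
    severity, 1 for AUC adaptation, 0 for MAX scores); ``sd`` is the
    score's standard deviation across the arm.  Sign is preserved so the
    direction of change stays recoverable.
    """
    if not sd > 0:
        raise ValueError("sd must be positive (degenerate cohort)")
    return (score - offset) / sd


def score_trajectory(
    subject_id: str,
    symptom: str,
    trajectory: list[int | None],
    auc_mode: str = "incremental",
    missing: str = "strict",
) -> ToleranceScores:
    """Compute all six scores for one trajectory."""
    adapt = auc_adaptation(trajectory, missing=missing)
    m_sev = max_severity(trajectory, missing=missing)
    m_adapt = max_adaptation(trajectory, missing=missing)
    return ToleranceScores(
        subject_id=subject_id,
        symptom=symptom,
        max_severity=m_sev,
        auc_severity=auc_severity(trajectory, mode=auc_mode, missing=missing),
        max_adaptation=m_adapt,
        auc_adaptation=adapt.ratio,
        auc_w13=adapt.auc_w13,
        auc_w46=adapt.auc_w46,
        auc_mode=auc_mode,
        reverted=abs(m_sev - m_adapt) <= REVERTED_TOLERANCE,
        flags=adapt.flags,
    )


def score_diary(
    diary: SymptomDiary,
    auc_mode: str = "incremental",
    missing: str = "strict",
) -> list[ToleranceScores]:
    """Score the composite trajectory and each component symptom.

    Composite scores are always computed on the summed weekly
    trajectory, never by summing per-symptom scores.
    """
    out = []
    for symptom in SCORED_SYMPTOMS:
        if symptom == "composite":
            trajectory = composite_trajectory(diary)
        else:
            trajectory = diary.trajectory(symptom)
        out.append(
            score_trajectory(
                diary.subject_id, symptom, trajectory,
                auc_mode=auc_mode, missing=missing,
            )
        )
    return out


def score_cohort(
    diaries: list[SymptomDiary],
    auc_mode: str = "incremental",
    missing: str = "strict",
) -> list[ToleranceScores]:
    scores = []
    for diary in diaries:
        scores.extend(score_diary(diary, auc_mode=auc_mode, missing=missing))
    return scores
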