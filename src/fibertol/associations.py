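"""Assembly of the score-feature association tables.

Implements the windowed mapping between symptom scores and fecal
samples (weeks 1-3 scores against week-1 samples, weeks 4-6 scores
against week-6 samples), the subject-profile correlations (baseline
abundances, week-6-minus-baseline shifts, ex-vivo active ASVs, pH/SCFA
shifts, diet features), and the between/within-arm rank-test tables.

Correlation cells carry a significance tier driven by the feature
class: microbiota-compositional cells (taxon/carg/otu/asv/diversity)
are called significant at p < 0.01 and "approached" at p < 0.05;
pH/SCFA/diet cells use p < 0.05 and p < 0.10.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from fibertol.datamodel import (
    SCORED_SYMPTOMS,
    SYMPTOMS,
    AssociationResult,
    SymptomDiary,
    TAXON_CLASSES,
    ToleranceScores,
)
from fibertol.scores import composite_trajectory
from fibertol.stats import bonferroni, mann_whitney, spearman, wilcoxon_signed_rank

#: (significant, approached) alpha levels per feature-class family.
ALPHA_TAXON = (0.01, 0.05)
ALPHA_OTHER = (0.05, 0.10)

SCORE_TYPES = ("max_severity", "auc_severity", "max_adaptation", "auc_adaptation")

MIN_PAIRS = 4


def alphas_for(feature_class: str) -> tuple[float, float]:
    return ALPHA_TAXON if feature_class in TAXON_CLASSES else ALPHA_OTHER


def assign_tier(p: float, feature_class: str) -> str:
    alpha, approach = alphas_for(feature_class)
    if not math.isfinite(p):
        return "ns"
    if p < alpha:
        return "significant"
    if p < approach:
        return "approached"
    return "ns"


def scores_by_subject(
    scores: list[ToleranceScores], symptom: str, attr: str
) -> pd.Series:
    """Per-subject values of one score, NaN where flagged undefined.

    Subjects whose adaptation AUC hit the complete-resolution sentinel
    are excluded (NaN) from ``auc_adaptation`` correlations.
    """
    data = {}
    for s in scores:
        if s.symptom != symptom:
            continue
        value = getattr(s, attr)
        if attr == "auc_adaptation" and "complete_resolution" in s.flags:
            value = math.nan
        if not math.isfinite(float(value)):
            value = math.nan
        data[s.subject_id] = float(value)
    return pd.Series(data, dtype=float)


def _correlate(
    score_series: pd.Series,
    feature_values: pd.Series,
    feature_id: str,
    feature_class: str,
    symptom: str,
    score_type: str,
    window: str,
    arm: str,
    seed: int | None = None,
    p_method: str = "approx",
) -> AssociationResult:
    """One Spearman cell with pairwise deletion and tier assignment."""
    joined = pd.concat(
        [score_series.rename("score"), feature_values.rename("feature")],
        axis=1, join="inner",
    ).dropna()
    n = len(joined)
    flags: tuple[str, ...] = ()
    if n < MIN_PAIRS:
        rho, p, flags = math.nan, math.nan, ("insufficient_n",)
    else:
        res = spearman(
            joined["score"].to_numpy(), joined["feature"].to_numpy(),
            method=p_method, seed=seed,
        )
        rho, p, flags = res.statistic, res.p, res.flags
    tier = "ns" if flags else assign_tier(p, feature_class)
    return AssociationResult(
        feature_id=feature_id,
        feature_class=feature_class,
        symptom=symptom,
        score_type=score_type,
        window=window,
        arm=arm,
        n=n,
        rho=rho,
        p=p,
        p_adjusted=p,
        tier=tier,
        flags=flags,
    )


def windowed_severity_correlations(
    scores: list[ToleranceScores],
    week1_values: pd.DataFrame,
    week6_values: pd.DataFrame,
    feature_class: str,
    arm: str,
    symptoms: tuple[str, ...] = SCORED_SYMPTOMS,
) -> list[AssociationResult]:
    """Correlate segment severity AUCs with time-matched fecal samples.

    For every feature and symptom, the weeks-1-3 raw-rating AUC is
    correlated against week-1 sample values (window ``w13``) and the
    weeks-4-6 AUC against week-6 values (window ``w46``).  Inputs are
    subject-indexed feature frames restricted to one arm; subjects
    missing the matched sample drop out pairwise.
    """
    results = []
    for symptom in symptoms:
        for window, attr, values in (
            ("w13", "auc_w13", week1_values),
            ("w46", "auc_w46", week6_values),
        ):
            series = scores_by_subject(scores, symptom, attr)
            for feature_id in values.columns:
                results.append(
                    _correlate(
                        series, values[feature_id], str(feature_id),
                        feature_class, symptom, "auc_severity", window, arm,
                    )
                )
    return results


def profile_correlations(
    scores: list[ToleranceScores],
    feature_values: pd.DataFrame,
    feature_class: str,
    window: str,
    arm: str,
    symptoms: tuple[str, ...] = SCORED_SYMPTOMS,
    score_types: tuple[str, ...] = SCORE_TYPES,
) -> list[AssociationResult]:
    """Full cross of per-subject features x score types x symptoms.

    ``feature_values`` holds one value per subject per feature (baseline
    abundance, shift, ex-vivo active abundance, pH/SCFA shift, or diet
    feature); ``window`` labels its provenance.
    """
    results = []
    for symptom in symptoms:
        for score_type in score_types:
            series = scores_by_subject(scores, symptom, score_type)
            for feature_id in feature_values.columns:
                results.append(
                    _correlate(
                        series, feature_values[feature_id], str(feature_id),
                        feature_class, symptom, score_type, window, arm,
                    )
                )
    return results


# ---------------------------------------------------------------------------
# rank-test tables (between-arm weekly comparison and within-arm adaptation)


def _weekly_ratings(diaries: list[SymptomDiary], symptom: str) -> pd.DataFrame:
    rows = {}
    for diary in diaries:
        if symptom == "composite":
            rows[diary.subject_id] = composite_trajectory(diary)
        else:
            rows[diary.subject_id] = diary.trajectory(symptom)
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    frame.columns = [f"week{w}" for w in range(7)]
    return frame


def per_week_arm_comparison(diaries: list[SymptomDiary]) -> pd.DataFrame:
    """Per-week Mann-Whitney comparison of AX vs MCC ratings.

    The in-scope surrogate for longitudinal model fitting: one two-sided
    test per symptom and intervention week, Bonferroni-corrected across
    the six weeks within each symptom.
    """
    ax = [d for d in diaries if d.arm == "AX"]
    mcc = [d for d in diaries if d.arm == "MCC"]
    rows = []
    for symptom in ("composite",) + SYMPTOMS:
        ax_ratings = _weekly_ratings(ax, symptom)
        mcc_ratings = _weekly_ratings(mcc, symptom)
        ps = []
        for week in range(1, 7):
            col = f"week{week}"
            res = mann_whitney(
                ax_ratings[col].dropna().to_numpy(),
                mcc_ratings[col].dropna().to_numpy(),
            )
            ps.append(res.p)
            rows.append(
                {
                    "symptom": symptom,
                    "week": week,
                    "U": res.statistic,
                    "p": res.p,
                }
            )
        adjusted = bonferroni(ps, m=6)
        for offset, p_adj in enumerate(adjusted):
            rows[-6 + offset]["p_bonferroni"] = float(p_adj)
    return pd.DataFrame(rows)


def score_arm_comparison(
    scores: list[ToleranceScores], arm_of: dict[str, str]
) -> pd.DataFrame:
    """Mann-Whitney comparison of MAX/AUC severity scores between arms."""
    frame = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "symptom": s.symptom,
                "max_severity": s.max_severity,
                "auc_severity": s.auc_severity,
            }
            for s in scores
        ]
    )
    rows = []
    frame["arm"] = frame["subject_id"].map(arm_of)
    if set(frame["arm"]) != {"AX", "MCC"}:
        raise ValueError("score_arm_comparison needs scores from both arms")
    for symptom in SCORED_SYMPTOMS:
        sub = frame[frame["symptom"] == symptom]
        for score_type in ("max_severity", "auc_severity"):
            res = mann_whitney(
                sub.loc[sub["arm"] == "AX", score_type].to_numpy(dtype=float),
                sub.loc[sub["arm"] == "MCC", score_type].to_numpy(dtype=float),
            )
            rows.append(
                {
                    "symptom": symptom,
                    "score_type": score_type,
                    "U": res.statistic,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)


def within_arm_adaptation_tests(diaries: list[SymptomDiary]) -> pd.DataFrame:
    """Paired Wilcoxon tests of adaptation within one arm.

    Compares the highest weeks-1-5 rating against the week-6 rating, and
    the weeks-1-3 segment AUC against the weeks-4-6 AUC, per symptom,
    Bonferroni-corrected across symptoms within each contrast family.
    """
    from fibertol.scores import auc_adaptation

    rows = []
    for contrast in ("max_vs_week6", "auc_w13_vs_w46"):
        ps = []
        for symptom in SCORED_SYMPTOMS:
            a, b = [], []
            for diary in diaries:
                traj = (
                    composite_trajectory(diary)
                    if symptom == "composite"
                    else diary.trajectory(symptom)
                )
                if any(v is None for v in traj):
                    continue
                if contrast == "max_vs_week6":
                    a.append(max(traj[1:6]))
                    b.append(traj[6])
                else:
                    seg = auc_adaptation(traj)
                    a.append(seg.auc_w13)
                    b.append(seg.auc_w46)
            res = wilcoxon_signed_rank(np.array(a), np.array(b))
            ps.append(res.p)
            rows.append(
                {
                    "contrast": contrast,
                    "symptom": symptom,
                    "W": res.statistic,
                    "p": res.p,
                    "n": len(a),
                }
            )
        adjusted = bonferroni(ps, m=len(SCORED_SYMPTOMS))
        for offset, p_adj in enumerate(adjusted):
            rows[-len(SCORED_SYMPTOMS) + offset]["p_bonferroni"] = float(p_adj)
    return pd.DataFrame(rows)
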