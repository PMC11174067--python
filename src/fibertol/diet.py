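"""Calorie adjustment of diet-history intakes and animal:plant ratios."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fibertol.datamodel import DietProfile

logger = logging.getLogger(__name__)

#: Ratio features of animal- vs plant-based intakes: name -> (numerator
#: item, denominator item).
DEFAULT_RATIOS = {
    "meat:wgrain": ("meat_alternatives_servings", "whole_grains_servings"),
    "chole:DF": ("cholesterol_mg", "dietary_fiber_g"),
}


@dataclass
class DietFeatureVector:
    """Calorie-adjusted intakes and derived ratios for one subject."""

    subject_id: str
    adjusted: dict[str, float]
    ratios: dict[str, float] = field(default_factory=dict)
    method: str = "density"


def calorie_adjust(
    profiles: list[DietProfile], method: str = "density"
) -> list[DietFeatureVector]:
    """Adjust every intake item for total caloric intake.

    ``density`` expresses each item per 1000 kcal.  ``residual`` fits a
    least-squares regression of each item on energy across the cohort
    and keeps the residual plus the cohort mean intake (so the cohort
    mean is unchanged); with no energy variation it degenerates to the
    raw intakes.
    """
    if method not in ("density", "residual"):
        raise ValueError(f"unknown adjustment method {method!r}")
    if not profiles:
        return []
    items = sorted({k for p in profiles for k in p.intakes})

    if method == "density":
        return [
            DietFeatureVector(
                subject_id=p.subject_id,
                adjusted={
                    item: p.intakes.get(item, 0.0) * 1000.0 / p.energy_kcal
                    for item in items
                },
                method=method,
            )
            for p in profiles
        ]

    energy = np.array([p.energy_kcal for p in profiles], dtype=float)
    adjusted_by_subject: list[dict[str, float]] = [{} for _ in profiles]
    for item in items:
        intake = np.array([p.intakes.get(item, 0.0) for p in profiles])
        if np.ptp(energy) == 0:
            fitted = np.full_like(intake, intake.mean())
        else:
            slope, intercept = np.polyfit(energy, intake, 1)
            fitted = slope * energy + intercept
        adjusted = intake - fitted + intake.mean()
        for i, value in enumerate(adjusted):
            adjusted_by_subject[i][item] = float(value)
    return [
        DietFeatureVector(p.subject_id, adjusted_by_subject[i], method=method)
        for i, p in enumerate(profiles)
    ]


def diet_ratio(
    numerator_item: str, denominator_item: str, vector: DietFeatureVector
) -> float | None:
    """Ratio of two calorie-adjusted intakes; None when undefined.

    Subjects with a zero denominator are excluded from that ratio's
    correlations (logged), not errored.
    """
    num = vector.adjusted[numerator_item]
    den = vector.adjusted[denominator_item]
    if den == 0:
        logger.info(
            "subject %s excluded from %s/%s ratio: zero denominator",
            vector.subject_id, numerator_item, denominator_item,
        )
        return None
    return num / den


def diet_feature_table(
    profiles: list[DietProfile],
    method: str = "density",
    ratios: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Subjects x diet-features table of adjusted intakes plus ratios."""
    if ratios is None:
        ratios = DEFAULT_RATIOS
    vectors = calorie_adjust(profiles, method=method)
    rows = {}
    for vec in vectors:
        row = dict(vec.adjusted)
        for name, (num, den) in ratios.items():
            value = diet_ratio(num, den, vec)
            vec.ratios[name] = np.nan if value is None else value
            row[name] = vec.ratios[name]
        rows[vec.subject_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "subject_id"
    return frame.sort_index()
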