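"""Microbiota feature engineering: aggregation, filtering, diversity, shifts.

The pipeline always aggregates OTU tables to the target taxonomic level
first and filters on mean relative abundance afterwards, per level.
Lineage strings use rank prefixes (``p__``, ``f__``, ``g__``) separated
by semicolons; features without the requested rank fall into an
``unclassified`` bucket so per-sample totals are conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fibertol.datamodel import AbundanceTable, ValidationError

logger = logging.getLogger(__name__)

_RANK_PREFIX = {"phylum": "p__", "family": "f__", "genus": "g__"}

UNCLASSIFIED = "unclassified"

#: Mean-abundance screens used by the published analysis: 0.15% for
#: fecal taxa/CARGs, 1.0% for ex-vivo active ASVs.
TAXON_FILTER_THRESHOLD = 0.0015
ACTIVE_ASV_FILTER_THRESHOLD = 0.010


def _lineage_rank(lineage: str, level: str) -> str | None:
    prefix = _RANK_PREFIX[level]
    for part in lineage.split(";"):
        part = part.strip()
        if part.startswith(prefix):
            name = part[len(prefix):].strip()
            return name or None
    return None


def aggregate(table: AbundanceTable, target_level: str) -> AbundanceTable:
    """Sum feature columns into taxa (or CARGs) at ``target_level``.

    Unassigned abundance is reported under ``unclassified`` so that each
    sample's total is conserved exactly.
    """
    if target_level == "carg":
        if not table.carg_map:
            raise ValidationError("no CARG membership map attached to table")
        assignment = {
            fid: table.carg_map.get(fid, UNCLASSIFIED)
            for fid in table.feature_ids
        }
    elif target_level in _RANK_PREFIX:
        assignment = {}
        any_assigned = False
        for fid in table.feature_ids:
            name = _lineage_rank(table.taxonomy.get(fid, ""), target_level)
            if name is not None:
                any_assigned = True
            assignment[fid] = name if name is not None else UNCLASSIFIED
        if not any_assigned:
            raise ValidationError(
                f"taxonomy strings carry no {target_level!r} rank"
            )
    else:
        raise ValidationError(f"cannot aggregate to level {target_level!r}")

    groups: dict[str, list[int]] = {}
    for j, fid in enumerate(table.feature_ids):
        groups.setdefault(assignment[fid], []).append(j)
    # deterministic order: named groups sorted, unclassified last
    names = sorted(g for g in groups if g != UNCLASSIFIED)
    if UNCLASSIFIED in groups:
        names.append(UNCLASSIFIED)
    values = np.column_stack(
        [table.values[:, groups[name]].sum(axis=1) for name in names]
    )
    return AbundanceTable(
        sample_ids=list(table.sample_ids),
        subject_ids=list(table.subject_ids),
        timepoints=list(table.timepoints),
        feature_ids=names,
        values=values,
        level=target_level,
        taxonomy={},
        carg_map=None,
    )


@dataclass
class FeatureSet:
    """Features retained by a screen, with per-sample values.

    ``provenance`` records how the set was chosen: a mean-abundance
    filter (``all_filtered``/``active_asvs``), an external whitelist
    (``significant_otus``), or CARG aggregation (``cargs``).
    """

    level: str
    feature_ids: list[str]
    sample_ids: list[str]
    subject_ids: list[str]
    timepoints: list[str]
    values: np.ndarray
    provenance: str = "all_filtered"
    filter_threshold: float = 0.0
    mean_abundance: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_ids)
        frame.insert(0, "timepoint", self.timepoints)
        frame.insert(0, "subject_id", self.subject_ids)
        frame.insert(0, "sample_id", self.sample_ids)
        return frame

    def subject_values(self, timepoint: str) -> pd.DataFrame:
        """Feature values at one timepoint, indexed by subject id."""
        keep = [i for i, tp in enumerate(self.timepoints) if tp == timepoint]
        return pd.DataFrame(
            self.values[keep, :],
            index=[self.subject_ids[i] for i in keep],
            columns=self.feature_ids,
        )


def filter_mean_abundance(
    table: AbundanceTable,
    threshold: float,
    provenance: str = "all_filtered",
) -> FeatureSet:
    """Retain features whose mean abundance across all samples is > threshold.

    The mean pools every sample in the table (both arms, every
    timepoint).  Retention is strict ``>``; retained features are sorted
    by descending mean abundance.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    means = table.values.mean(axis=0)
    order = np.argsort(-means, kind="stable")
    keep = [int(j) for j in order if means[j] > threshold]
    feature_ids = [table.feature_ids[j] for j in keep]
    return FeatureSet(
        level=table.level,
        feature_ids=feature_ids,
        sample_ids=list(table.sample_ids),
        subject_ids=list(table.subject_ids),
        timepoints=list(table.timepoints),
        values=table.values[:, keep],
        provenance=provenance,
        filter_threshold=threshold,
        mean_abundance={fid: float(means[j]) for fid, j in zip(feature_ids, keep)},
    )


def select_features(table: AbundanceTable, whitelist: list[str]) -> FeatureSet:
    """Restrict a table to an externally supplied feature whitelist."""
    missing = [fid for fid in whitelist if fid not in table.feature_ids]
    if missing:
        raise ValidationError(f"whitelist features absent from table: {missing}")
    idx = [table.feature_index(fid) for fid in whitelist]
    return FeatureSet(
        level=table.level,
        feature_ids=list(whitelist),
        sample_ids=list(table.sample_ids),
        subject_ids=list(table.subject_ids),
        timepoints=list(table.timepoints),
        values=table.values[:, idx],
        provenance="significant_otus",
    )


def shannon_index(sample_values) -> float:
    """Shannon entropy (nats) of a relative-abundance vector."""
    values = np.asarray(sample_values, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative abundance")
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no defined diversity")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(sample_values) -> int:
    """Number of features observed at any nonzero abundance."""
    values = np.asarray(sample_values, dtype=float)
    return int((values > 0).sum())


def diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon index and richness."""
    rows = []
    for i, sample_id in enumerate(table.sample_ids):
        rows.append(
            {
                "sample_id": sample_id,
                "subject_id": table.subject_ids[i],
                "timepoint": table.timepoints[i],
                "shannon": shannon_index(table.values[i]),
                "richness": richness(table.values[i]),
            }
        )
    return pd.DataFrame(rows)


def shift(table: AbundanceTable, subject_id: str, feature_id: str) -> float:
    """Week-6 minus baseline value of one feature for one subject."""
    j = table.feature_index(feature_id)
    i6 = table.sample_index(subject_id, "week6")
    i0 = table.sample_index(subject_id, "baseline")
    if i6 is None or i0 is None:
        raise KeyError(
            f"subject {subject_id!r} lacks baseline or week6 sample"
        )
    return float(table.values[i6, j] - table.values[i0, j])


def shift_table(table: AbundanceTable, feature_ids: list[str]) -> pd.DataFrame:
    """Week-6-minus-baseline shifts, subjects x features.

    Subjects missing either timepoint are excluded with a logged note.
    """
    subjects = sorted(set(table.subject_ids))
    rows, kept = [], []
    for subject in subjects:
        i6 = table.sample_index(subject, "week6")
        i0 = table.sample_index(subject, "baseline")
        if i6 is None or i0 is None:
            logger.info(
                "subject %s excluded from shift features: missing %s sample",
                subject, "week6" if i6 is None else "baseline",
            )
            continue
        idx = [table.feature_index(fid) for fid in feature_ids]
        rows.append(table.values[i6, idx] - table.values[i0, idx])
        kept.append(subject)
    return pd.DataFrame(rows, index=kept, columns=feature_ids)
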