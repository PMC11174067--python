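"""Delimited-text readers and writers for every table in the pipeline.

All files are UTF-8 CSV or TSV (auto-detected on read, comma on write)
with a decimal point.  Abundance matrices given as percentages (row sums
near 100) are renormalized to fractions on read.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from fibertol.datamodel import (
    ARMS,
    DOSE_BY_SEX,
    N_WEEKS,
    SYMPTOMS,
    AbundanceTable,
    AssociationResult,
    DietProfile,
    MetabolitePanel,
    SymptomDiary,
    ToleranceScores,
    ValidationError,
)

FLOAT_FORMAT = "%.12g"

#: Default long-format diary column names; override via ``schema``.
DIARY_SCHEMA = {
    "subject": "subject",
    "arm": "arm",
    "sex": "sex",
    "week": "week",
    "symptom": "symptom",
    "rating": "rating",
}

_ABUNDANCE_META_COLS = ("sample_id", "subject_id", "timepoint")


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table, auto-detecting comma vs tab."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def _write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# symptom diaries


def read_symptom_diaries(
    path: str | Path, schema: dict[str, str] | None = None
) -> list[SymptomDiary]:
    """Read a long-format diary table into one :class:`SymptomDiary` per subject.

    The table needs columns subject/arm/sex/week/symptom/rating (names
    remappable via ``schema``).  Weeks run 0 (baseline) to 6; absent
    (subject, week, symptom) cells become declared-missing ``None``
    entries, never imputed values.
    """
    cols = dict(DIARY_SCHEMA)
    if schema:
        cols.update(schema)
    frame = _read_table(path)
    missing_cols = [c for c in cols.values() if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"diary file missing columns {missing_cols}")

    dup_mask = frame.duplicated(
        subset=[cols["subject"], cols["week"], cols["symptom"]], keep=False
    )
    if dup_mask.any():
        row = frame[dup_mask].iloc[0]
        raise ValidationError(
            f"duplicate diary cell for subject {row[cols['subject']]!r}, "
            f"week {row[cols['week']]}, symptom {row[cols['symptom']]!r}"
        )

    diaries: list[SymptomDiary] = []
    for subject, group in frame.groupby(cols["subject"], sort=True):
        arms = set(group[cols["arm"]])
        sexes = set(group[cols["sex"]])
        if len(arms) != 1 or len(sexes) != 1:
            raise ValidationError(
                f"subject {subject!r}: inconsistent arm/sex labels"
            )
        arm, sex = arms.pop(), sexes.pop()
        if arm not in ARMS:
            raise ValidationError(f"subject {subject!r}: unknown arm label {arm!r}")
        ratings: dict[str, list[int | None]] = {
            s: [None] * N_WEEKS for s in SYMPTOMS
        }
        for _, row in group.iterrows():
            week = int(row[cols["week"]])
            symptom = str(row[cols["symptom"]])
            if symptom not in SYMPTOMS:
                raise ValidationError(
                    f"subject {subject!r}: unknown symptom {symptom!r}"
                )
            if not 0 <= week < N_WEEKS:
                raise ValidationError(
                    f"subject {subject!r}: week {week} outside 0..{N_WEEKS - 1}"
                )
            raw = row[cols["rating"]]
            if pd.isna(raw):
                continue
            value = float(raw)
            if value != int(value):
                raise ValidationError(
                    f"subject {subject!r}, week {week}, symptom {symptom}: "
                    f"non-integer rating {raw!r}"
                )
            ratings[symptom][week] = int(value)
        diaries.append(
            SymptomDiary(
                subject_id=str(subject),
                arm=arm,
                sex=sex,
                dose_g_per_day=DOSE_BY_SEX.get(sex, -1),
                ratings=ratings,
            )
        )
    return diaries


def write_symptom_diaries(diaries: list[SymptomDiary], path: str | Path) -> None:
    rows = []
    for diary in diaries:
        for symptom in SYMPTOMS:
            for week, value in enumerate(diary.ratings[symptom]):
                if value is None:
                    continue
                rows.append(
                    {
                        "subject": diary.subject_id,
                        "arm": diary.arm,
                        "sex": diary.sex,
                        "week": week,
                        "symptom": symptom,
                        "rating": value,
                    }
                )
    _write_table(pd.DataFrame(rows, columns=list(DIARY_SCHEMA.values())), path)


# ---------------------------------------------------------------------------
# abundance tables


def read_abundance_table(
    path: str | Path,
    taxonomy_path: str | Path | None = None,
    carg_path: str | Path | None = None,
    level: str = "otu",
) -> AbundanceTable:
    """Read a wide samples-x-features abundance matrix.

    Rows whose sums look like percentages (mean row sum > 50) are
    rescaled to fractions.  Optional sidecar files attach taxonomy
    lineages and the CARG membership partition.
    """
    frame = _read_table(path)
    for col in _ABUNDANCE_META_COLS:
        if col not in frame.columns:
            raise ValidationError(f"abundance table missing column {col!r}")
    feature_ids = [c for c in frame.columns if c not in _ABUNDANCE_META_COLS]
    values = frame[feature_ids].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError("abundance table contains negative values")
    row_sums = values.sum(axis=1)
    if row_sums.size and row_sums.mean() > 50:  # percent encoding
        values = values / 100.0

    taxonomy: dict[str, str] = {}
    if taxonomy_path is not None:
        tax = _read_table(taxonomy_path)
        taxonomy = dict(zip(tax["feature_id"].astype(str), tax["lineage"].astype(str)))

    carg_map: dict[str, str] | None = None
    if carg_path is not None:
        carg = _read_table(carg_path)
        if carg["feature_id"].duplicated().any():
            dupe = carg.loc[carg["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise ValidationError(
                f"feature {dupe!r} listed in more than one CARG; membership "
                "must be a partition"
            )
        carg_map = {}
        for fid, cid in zip(carg["feature_id"].astype(str), carg["carg_id"].astype(str)):
            if fid not in feature_ids:
                warnings.warn(
                    f"CARG member {fid!r} absent from abundance table; dropped",
                    stacklevel=2,
                )
                continue
            carg_map[fid] = cid

    return AbundanceTable(
        sample_ids=[str(s) for s in frame["sample_id"]],
        subject_ids=[str(s) for s in frame["subject_id"]],
        timepoints=[str(t) for t in frame["timepoint"]],
        feature_ids=feature_ids,
        values=values,
        level=level,
        taxonomy=taxonomy,
        carg_map=carg_map,
    )


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    frame = pd.DataFrame(table.values, columns=table.feature_ids)
    frame.insert(0, "timepoint", table.timepoints)
    frame.insert(0, "subject_id", table.subject_ids)
    frame.insert(0, "sample_id", table.sample_ids)
    _write_table(frame, path)


def write_taxonomy(taxonomy: dict[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"feature_id": list(taxonomy), "lineage": list(taxonomy.values())}
    )
    _write_table(frame, path)


def write_carg_map(carg_map: dict[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"feature_id": list(carg_map), "carg_id": list(carg_map.values())}
    )
    _write_table(frame, path)


# ---------------------------------------------------------------------------
# metabolite panels


def read_metabolite_panels(path: str | Path) -> list[MetabolitePanel]:
    frame = _read_table(path)
    scfa_cols = [
        c for c in frame.columns if c not in ("subject_id", "timepoint", "ph")
    ]
    panels = []
    for _, row in frame.iterrows():
        panels.append(
            MetabolitePanel(
                subject_id=str(row["subject_id"]),
                timepoint=str(row["timepoint"]),
                ph=float(row["ph"]),
                scfa={c: float(row[c]) for c in scfa_cols},
            )
        )
    return panels


def write_metabolite_panels(panels: list[MetabolitePanel], path: str | Path) -> None:
    scfa_cols = sorted({k for p in panels for k in p.scfa})
    rows = []
    for p in panels:
        row = {"subject_id": p.subject_id, "timepoint": p.timepoint, "ph": p.ph}
        row.update({c: p.scfa.get(c, np.nan) for c in scfa_cols})
        rows.append(row)
    _write_table(pd.DataFrame(rows), path)


# ---------------------------------------------------------------------------
# diet profiles


def read_diet_profiles(path: str | Path) -> list[DietProfile]:
    frame = _read_table(path)
    item_cols = [c for c in frame.columns if c not in ("subject_id", "energy_kcal")]
    return [
        DietProfile(
            subject_id=str(row["subject_id"]),
            energy_kcal=float(row["energy_kcal"]),
            intakes={c: float(row[c]) for c in item_cols},
        )
        for _, row in frame.iterrows()
    ]


def write_diet_profiles(profiles: list[DietProfile], path: str | Path) -> None:
    item_cols = sorted({k for p in profiles for k in p.intakes})
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id, "energy_kcal": p.energy_kcal}
        row.update({c: p.intakes.get(c, np.nan) for c in item_cols})
        rows.append(row)
    _write_table(pd.DataFrame(rows), path)


# ---------------------------------------------------------------------------
# results


RESULT_COLUMNS = [
    "feature_id",
    "feature_class",
    "symptom",
    "score_type",
    "window",
    "arm",
    "n",
    "rho",
    "p",
    "p_adjusted",
    "tier",
    "flags",
]

SCORE_COLUMNS = [
    "subject_id",
    "symptom",
    "max_severity",
    "auc_severity",
    "max_adaptation",
    "auc_adaptation",
    "auc_w13",
    "auc_w46",
    "auc_mode",
    "reverted",
    "flags",
]


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dataclasses.asdict(r)
        row["flags"] = ";".join(r.flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def scores_to_frame(scores: list[ToleranceScores]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = dataclasses.asdict(s)
        row["flags"] = ";".join(s.flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_results(
    results: list[AssociationResult],
    scores: list[ToleranceScores],
    path: str | Path,
) -> dict[str, Path]:
    """Write association results and tolerance scores under directory ``path``.

    Emits one tidy long file per table plus a heatmap-shaped matrix of
    rho values (rows: features; columns: arm|symptom|score|window).
    Column order is deterministic and the tidy files round-trip
    losslessly through :func:`read_results`.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    tidy = results_to_frame(results)
    scores_frame = scores_to_frame(scores)
    written = {
        "associations": outdir / "associations.csv",
        "scores": outdir / "scores.csv",
        "matrix": outdir / "associations_matrix.csv",
    }
    _write_table(tidy, written["associations"])
    _write_table(scores_frame, written["scores"])

    if len(tidy):
        matrix_src = tidy.copy()
        matrix_src["cell"] = (
            matrix_src["arm"]
            + "|"
            + matrix_src["symptom"]
            + "|"
            + matrix_src["score_type"]
            + "|"
            + matrix_src["window"]
        )
        matrix = matrix_src.pivot_table(
            index="feature_id", columns="cell", values="rho", aggfunc="first",
            sort=True,
        )
        matrix = matrix.sort_index()
        _write_table(matrix, written["matrix"], index=True)
    else:
        _write_table(pd.DataFrame(columns=["feature_id"]), written["matrix"])
    return written


def read_results(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the tidy files written by :func:`write_results`."""
    outdir = Path(path)
    tidy = pd.read_csv(outdir / "associations.csv")
    scores = pd.read_csv(outdir / "scores.csv")
    return tidy, scores
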