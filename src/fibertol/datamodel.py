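"""Shared domain types and their validation rules.

Every stage of the pipeline exchanges instances of the dataclasses
defined here.  Validation happens at construction time so that malformed
records are rejected as close to the input boundary as possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Symptom names recorded in the weekly diary, in canonical order.
SYMPTOMS = ("overall", "flatulence", "bloating", "stomachache")

#: The three symptoms summed into the weekly composite rating.
COMPOSITE_SYMPTOMS = ("flatulence", "bloating", "stomachache")

#: Symptoms carried through the association analyses (composite first).
SCORED_SYMPTOMS = ("composite", "flatulence", "bloating", "stomachache")

#: Week indices: 0 is baseline, 1..6 are intervention weeks.
WEEKS = tuple(range(7))
N_WEEKS = 7

ARMS = ("AX", "MCC")
SEXES = ("F", "M")
DOSE_BY_SEX = {"F": 25, "M": 35}

TIMEPOINTS = ("baseline", "week1", "week6", "exvivo")
TAXONOMIC_LEVELS = ("phylum", "family", "genus", "otu", "asv", "carg")

RATING_MIN = 0
RATING_MAX = 4


class ValidationError(ValueError):
    """Raised when an input record violates a data-model invariant."""


class UndefinedScoreError(ValueError):
    """Raised when a tolerance score cannot be computed from a diary."""


@dataclass
class SymptomDiary:
    """Weekly ordinal symptom ratings for one subject.

    ``ratings`` maps each symptom to a 7-vector indexed by week 0
    (baseline) through week 6; a cell may be ``None`` to declare a
    missing diary entry.  Missing values are never imputed here --
    downstream scoring decides the policy.
    """

    subject_id: str
    arm: str
    sex: str
    dose_g_per_day: int
    ratings: dict[str, list[int | None]]

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(
                f"subject {self.subject_id}: unknown arm {self.arm!r} "
                f"(expected one of {ARMS})"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"subject {self.subject_id}: unknown sex {self.sex!r}"
            )
        expected_dose = DOSE_BY_SEX[self.sex]
        if self.dose_g_per_day != expected_dose:
            raise ValidationError(
                f"subject {self.subject_id}: dose {self.dose_g_per_day} g/day "
                f"inconsistent with sex {self.sex} (expected {expected_dose})"
            )
        for symptom in SYMPTOMS:
            if symptom not in self.ratings:
                raise ValidationError(
                    f"subject {self.subject_id}: missing symptom {symptom!r}"
                )
        for symptom, vector in self.ratings.items():
            if symptom not in SYMPTOMS:
                raise ValidationError(
                    f"subject {self.subject_id}: unknown symptom {symptom!r}"
                )
            if len(vector) != N_WEEKS:
                raise ValidationError(
                    f"subject {self.subject_id}, symptom {symptom}: expected "
                    f"{N_WEEKS} weekly entries, got {len(vector)}"
                )
            for week, value in enumerate(vector):
                if value is None:
                    continue
                if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                    raise ValidationError(
                        f"subject {self.subject_id}, symptom {symptom}, week "
                        f"{week}: rating {value!r} is not an integer"
                    )
                if not RATING_MIN <= value <= RATING_MAX:
                    raise ValidationError(
                        f"subject {self.subject_id}, symptom {symptom}, week "
                        f"{week}: rating {value} outside "
                        f"[{RATING_MIN}, {RATING_MAX}]"
                    )

    def trajectory(self, symptom: str) -> list[int | None]:
        """Return the 7-week rating vector for one symptom."""
        if symptom not in SYMPTOMS:
            raise ValidationError(f"unknown symptom {symptom!r}")
        return list(self.ratings[symptom])


@dataclass
class AbundanceTable:
    """Samples x features relative-abundance matrix with metadata.

    Values are fractions.  ``taxonomy`` maps feature ids to lineage
    strings of the form ``"p__X; f__Y; g__Z"``; ``carg_map`` optionally
    maps feature ids to co-abundance group ids and must be a partition.
    """

    sample_ids: list[str]
    subject_ids: list[str]
    timepoints: list[str]
    feature_ids: list[str]
    values: np.ndarray
    level: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    carg_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_samples, n_features = self.values.shape
        if not (len(self.sample_ids) == len(self.subject_ids)
                == len(self.timepoints) == n_samples):
            raise ValidationError("sample metadata lists misaligned with values")
        if len(self.feature_ids) != n_features:
            raise ValidationError("feature_ids misaligned with values")
        if self.level not in TAXONOMIC_LEVELS:
            raise ValidationError(f"unknown level {self.level!r}")
        for tp in self.timepoints:
            if tp not in TIMEPOINTS:
                raise ValidationError(f"unknown timepoint {tp!r}")
        if np.any(self.values < 0):
            raise ValidationError("negative relative abundance")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("duplicate sample ids")
        pairs = list(zip(self.subject_ids, self.timepoints))
        if len(set(pairs)) != n_samples:
            raise ValidationError("duplicate (subject, timepoint) pair")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def sample_index(self, subject_id: str, timepoint: str) -> int | None:
        for i, (subj, tp) in enumerate(zip(self.subject_ids, self.timepoints)):
            if subj == subject_id and tp == timepoint:
                return i
        return None

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None

    def subset_timepoint(self, timepoint: str) -> "AbundanceTable":
        """Return a new table restricted to one timepoint."""
        keep = [i for i, tp in enumerate(self.timepoints) if tp == timepoint]
        return AbundanceTable(
            sample_ids=[self.sample_ids[i] for i in keep],
            subject_ids=[self.subject_ids[i] for i in keep],
            timepoints=[self.timepoints[i] for i in keep],
            feature_ids=list(self.feature_ids),
            values=self.values[keep, :],
            level=self.level,
            taxonomy=dict(self.taxonomy),
            carg_map=None if self.carg_map is None else dict(self.carg_map),
        )


@dataclass
class MetabolitePanel:
    """Fecal pH and SCFA concentrations for one subject at one timepoint."""

    subject_id: str
    timepoint: str
    ph: float
    scfa: dict[str, float]

    def __post_init__(self) -> None:
        if self.timepoint not in ("baseline", "week6"):
            raise ValidationError(
                f"subject {self.subject_id}: metabolite timepoint must be "
                f"baseline or week6, got {self.timepoint!r}"
            )
        if not 0 < self.ph < 14:
            raise ValidationError(
                f"subject {self.subject_id}: pH {self.ph} outside (0, 14)"
            )
        for name, conc in self.scfa.items():
            if conc < 0:
                raise ValidationError(
                    f"subject {self.subject_id}: negative {name} concentration"
                )
        total = self.scfa.get("total")
        if total is not None:
            for name, conc in self.scfa.items():
                if name != "total" and conc > total + 1e-9:
                    raise ValidationError(
                        f"subject {self.subject_id}: {name} exceeds total SCFA"
                    )


@dataclass
class DietProfile:
    """One-month diet-history intakes for one subject."""

    subject_id: str
    energy_kcal: float
    intakes: dict[str, float]

    def __post_init__(self) -> None:
        if not self.energy_kcal > 0:
            raise ValidationError(
                f"subject {self.subject_id}: energy {self.energy_kcal} kcal "
                "must be positive"
            )
        for item, amount in self.intakes.items():
            if amount < 0:
                raise ValidationError(
                    f"subject {self.subject_id}: negative intake of {item}"
                )


@dataclass
class ToleranceScores:
    """Severity and adaptation scores for one subject and one symptom.

    ``auc_w13`` / ``auc_w46`` are the raw-rating trapezoid areas over
    weeks 1-3 and 4-6; ``auc_adaptation`` is their ratio (1 for any
    constant trajectory).  ``flags`` records degenerate situations such
    as complete symptom resolution (weeks 4-6 area of zero).
    """

    subject_id: str
    symptom: str
    max_severity: int
    auc_severity: float
    max_adaptation: int
    auc_adaptation: float
    auc_w13: float
    auc_w46: float
    auc_mode: str = "incremental"
    reverted: bool | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.symptom not in SCORED_SYMPTOMS + SYMPTOMS:
            raise ValidationError(f"unknown symptom {self.symptom!r}")
        if self.auc_mode not in ("incremental", "raw"):
            raise ValidationError(f"unknown auc_mode {self.auc_mode!r}")
        bound = 12 if self.symptom == "composite" else 4
        if not -bound <= self.max_severity <= bound:
            raise ValidationError(
                f"max_severity {self.max_severity} outside [-{bound}, {bound}]"
            )
        if (
            math.isfinite(self.auc_adaptation)
            and self.auc_adaptation <= 0
            and not self.flags
        ):
            raise ValidationError("auc_adaptation must be positive when defined")


#: Feature classes whose correlation cells use the stricter alpha.
TAXON_CLASSES = ("taxon", "carg", "otu", "asv", "diversity")
OTHER_CLASSES = ("ph", "scfa", "diet")
FEATURE_CLASSES = TAXON_CLASSES + OTHER_CLASSES

WINDOWS = ("w13", "w46", "baseline", "shift", "exvivo", "whole")
TIERS = ("significant", "approached", "ns")


@dataclass
class AssociationResult:
    """One correlation/test cell of a heatmap table."""

    feature_id: str
    feature_class: str
    symptom: str
    score_type: str
    window: str
    arm: str
    n: int
    rho: float
    p: float
    p_adjusted: float
    tier: str
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(f"unknown feature_class {self.feature_class!r}")
        if self.window not in WINDOWS:
            raise ValidationError(f"unknown window {self.window!r}")
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}")
        if self.tier not in TIERS:
            raise ValidationError(f"unknown tier {self.tier!r}")
        if math.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValidationError(f"|rho| = {abs(self.rho)} exceeds 1")
        if math.isfinite(self.p) and not 0 < self.p <= 1:
            raise ValidationError(f"p = {self.p} outside (0, 1]")

    @property
    def score_name(self) -> str:
        return f"{self.symptom}:{self.score_type}"
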