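"""Synthetic two-arm fiber-trial cohort generator.

Emits every derived table the pipeline consumes: weekly symptom diaries
with a rise-then-adapt trajectory in the fermentable-fiber (AX) arm,
compositional fecal abundance tables at baseline/week-1/week-6, an
ex-vivo "active consortium" ASV table, pH/SCFA panels, and a baseline
diet-history table.  A designated *B. longum*-like OTU, nested in a
six-member co-abundance group, is wired so that subjects carrying more
of it at baseline experience milder symptoms and adapt faster; acetate,
pH and diet links hang off the same latent tolerance axis.  Setting
``null_mode`` severs every planted link while keeping the marginal data
shapes, which is what the type-I calibration tests rely on.

All randomness flows from one seed through named per-block streams, so
adding a data block never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import norm

from fibertol import io
from fibertol.datamodel import (
    DOSE_BY_SEX,
    AbundanceTable,
    DietProfile,
    MetabolitePanel,
    SymptomDiary,
)

PLANTED_OTU = "B_longum_like"
PLANTED_CARG = "CARG1_like"
PLANTED_ASV = "ASV_Blongum_active"

#: Week-shape template for the latent severity curve (weeks 1..6):
#: rises to a peak early, then the tail is scaled down by the
#: subject-specific adaptation propensity.
_BASE_SHAPE = np.array([0.85, 1.0, 0.9, 0.8, 0.7, 0.65])
_DECAY_RAMP = np.array([0.0, 0.0, 0.0, 0.8, 0.9, 1.0])
#: Adapting subjects also run slightly hotter early (symptoms peak
#: before they fade), which sharpens the early/late contrast.
_EARLY_BOOST = np.array([0.25, 0.25, 0.25, 0.0, 0.0, 0.0])

#: Latent-correlation inflation compensating for ordinal discretization
#: and ratio-score nonlinearity (calibrated against realized Spearman).
_RHO_INFLATION = 1.38

_GENERA = [
    ("Actinobacteria", "Bifidobacteriaceae", "Bifidobacterium"),
    ("Actinobacteria", "Coriobacteriaceae", "Collinsella"),
    ("Bacteroidetes", "Bacteroidaceae", "Bacteroides"),
    ("Bacteroidetes", "Porphyromonadaceae", "Parabacteroides"),
    ("Bacteroidetes", "Porphyromonadaceae", "Odoribacter"),
    ("Bacteroidetes", "Prevotellaceae", "Prevotella"),
    ("Bacteroidetes", "Rikenellaceae", "Alistipes"),
    ("Firmicutes", "Lachnospiraceae", "Blautia"),
    ("Firmicutes", "Lachnospiraceae", "Roseburia"),
    ("Firmicutes", "Lachnospiraceae", "Coprococcus"),
    ("Firmicutes", "Ruminococcaceae", "Faecalibacterium"),
    ("Firmicutes", "Ruminococcaceae", "Subdoligranulum"),
    ("Firmicutes", "Ruminococcaceae", "Ruminococcus"),
    ("Firmicutes", "Oscillospiraceae", "Oscillibacter"),
    ("Firmicutes", "Streptococcaceae", "Streptococcus"),
    ("Firmicutes", "Veillonellaceae", "Dialister"),
    ("Proteobacteria", "Enterobacteriaceae", "Escherichia"),
    ("Proteobacteria", "Sutterellaceae", "Sutterella"),
    ("Verrucomicrobia", "Akkermansiaceae", "Akkermansia"),
]


@dataclass
class CohortConfig:
    """Parameters of one synthetic trial cohort.

    The effect block wires a latent per-subject tolerance axis (the
    standardized baseline log-abundance of the planted OTU) into symptom
    trajectories, metabolite shifts and diet gradients.  ``null_mode``
    forces every link to zero.
    """

    n_ax: int = 15
    n_mcc: int = 16
    ax_females: int = 10
    mcc_females: int = 11
    seed: int = 0
    adapt_peak_week: int = 2
    mean_peak_composite_rise: float = 5.0
    adapt_rate: float = 0.9
    tolerance_effect_rho: float = 0.7
    bifido_baseline_logmean: float = -3.5
    bifido_baseline_logsd: float = 1.0
    acetate_link: float = 6.0
    ph_link: float = -0.3
    diet_gradient: float = 0.5
    null_mode: bool = False
    n_background_taxa: int = 45

    def __post_init__(self) -> None:
        if self.n_ax < 4 or self.n_mcc < 4:
            raise ValueError("need at least 4 subjects per arm")
        if not 0 <= self.ax_females <= self.n_ax:
            raise ValueError("ax_females outside [0, n_ax]")
        if not 0 <= self.mcc_females <= self.n_mcc:
            raise ValueError("mcc_females outside [0, n_mcc]")
        if abs(self.tolerance_effect_rho) >= 1:
            raise ValueError(
                "requested |tolerance_effect_rho| >= 1 is infeasible"
            )
        for name in ("mean_peak_composite_rise", "adapt_rate", "acetate_link",
                     "ph_link", "diet_gradient"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_background_taxa < 40:
            raise ValueError("need at least 40 background taxa")


@dataclass
class CohortBundle:
    """Everything :func:`generate_cohort` produces, in memory."""

    config: CohortConfig
    diaries: list[SymptomDiary]
    fecal_table: AbundanceTable
    exvivo_table: AbundanceTable
    metabolites: list[MetabolitePanel]
    diets: list[DietProfile]
    taxonomy: dict[str, str]
    carg_map: dict[str, str]
    significant_otus: list[str]
    tolerance: dict[str, float] = field(default_factory=dict)

    def arm_of(self) -> dict[str, str]:
        return {d.subject_id: d.arm for d in self.diaries}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every table in the formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "diaries": outdir / "diaries.csv",
            "fecal": outdir / "fecal_abundance.csv",
            "exvivo": outdir / "exvivo_abundance.csv",
            "taxonomy": outdir / "taxonomy.csv",
            "carg_map": outdir / "carg_map.csv",
            "significant_otus": outdir / "significant_otus.csv",
            "metabolites": outdir / "metabolites.csv",
            "diet": outdir / "diet.csv",
        }
        io.write_symptom_diaries(self.diaries, paths["diaries"])
        io.write_abundance_table(self.fecal_table, paths["fecal"])
        io.write_abundance_table(self.exvivo_table, paths["exvivo"])
        io.write_taxonomy(self.taxonomy, paths["taxonomy"])
        io.write_carg_map(self.carg_map, paths["carg_map"])
        with open(paths["significant_otus"], "w", encoding="utf-8") as handle:
            handle.write("feature_id\n")
            for fid in self.significant_otus:
                handle.write(f"{fid}\n")
        io.write_metabolite_panels(self.metabolites, paths["metabolites"])
        io.write_diet_profiles(self.diets, paths["diet"])
        return paths


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _subject_frame(config: CohortConfig) -> list[tuple[str, str, str]]:
    subjects = []
    for arm, n, n_f in (
        ("AX", config.n_ax, config.ax_females),
        ("MCC", config.n_mcc, config.mcc_females),
    ):
        for i in range(n):
            sex = "F" if i < n_f else "M"
            subjects.append((f"{arm}{i + 1:02d}", arm, sex))
    return subjects


def _build_taxa(config: CohortConfig):
    """Fixed taxon catalog: planted OTU + CARG partners + background."""
    taxa: list[str] = [PLANTED_OTU, "Subdoligranulum_like", "Blautia_obeum_like"]
    lineages = {
        PLANTED_OTU: "p__Actinobacteria; f__Bifidobacteriaceae; g__Bifidobacterium",
        "Subdoligranulum_like": "p__Firmicutes; f__Ruminococcaceae; g__Subdoligranulum",
        "Blautia_obeum_like": "p__Firmicutes; f__Lachnospiraceae; g__Blautia",
    }
    for j in range(config.n_background_taxa):
        phylum, family, genus = _GENERA[j % len(_GENERA)]
        otu_id = f"OTU{j + 1:03d}"
        taxa.append(otu_id)
        lineages[otu_id] = f"p__{phylum}; f__{family}; g__{genus}"

    carg_map: dict[str, str] = {}
    carg1_members = taxa[:3] + taxa[3:6]  # 6 inter-correlated members
    for fid in carg1_members:
        carg_map[fid] = PLANTED_CARG
    remaining = taxa[6:30]
    for k, fid in enumerate(remaining):
        carg_map[fid] = f"CARG{2 + k % 6}_like"

    significant = list(carg1_members) + taxa[6:15]  # 15-OTU whitelist
    return taxa, lineages, carg_map, carg1_members, significant


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate one complete synthetic trial dataset.

    Fully reproducible from ``config.seed``; identical configs yield
    byte-identical bundles.
    """
    if config is None:
        config = CohortConfig()
    subjects = _subject_frame(config)
    n_total = len(subjects)
    arms = np.array([arm for _, arm, _ in subjects])
    is_ax = arms == "AX"

    # -- latent tolerance axis -------------------------------------------
    rng_tol = _stream(config.seed, "tolerance")
    z = rng_tol.normal(
        config.bifido_baseline_logmean, config.bifido_baseline_logsd, n_total
    )
    tol = (z - config.bifido_baseline_logmean) / config.bifido_baseline_logsd

    # -- symptom diaries --------------------------------------------------
    rng_sym = _stream(config.seed, "symptoms")
    r_lat = min(0.985, abs(config.tolerance_effect_rho) * _RHO_INFLATION)
    link_on = (~np.full(n_total, config.null_mode)) & is_ax
    noise_u = rng_sym.normal(size=n_total)
    u = np.where(
        link_on,
        r_lat * np.sign(config.tolerance_effect_rho) * tol
        + np.sqrt(max(0.0, 1 - r_lat**2)) * noise_u,
        noise_u,
    )
    adapt_propensity = norm.cdf(u)

    frailty = rng_sym.normal(size=n_total)
    peak_rise = np.where(is_ax, config.mean_peak_composite_rise, 0.8)
    rise = peak_rise * np.exp(0.15 * frailty) * (1.45 - 0.9 * adapt_propensity)

    shape_shift = config.adapt_peak_week - 2  # template peaks at week 2
    base_shape = np.roll(_BASE_SHAPE, shape_shift) if shape_shift else _BASE_SHAPE

    shares_noise = rng_sym.normal(size=(n_total, 3))
    shares = np.array([0.45, 0.33, 0.22]) * np.exp(0.3 * shares_noise)
    shares = shares / shares.sum(axis=1, keepdims=True)

    baseline_probs = np.array([0.80, 0.17, 0.03])
    baselines = rng_sym.choice(3, size=(n_total, 3), p=baseline_probs)
    week_noise = rng_sym.normal(0.0, 0.25, size=(n_total, 3, 6))

    diaries: list[SymptomDiary] = []
    for i, (subject_id, arm, sex) in enumerate(subjects):
        tail_scale = 1.0 - config.adapt_rate * adapt_propensity[i] * _DECAY_RAMP
        shape = base_shape * tail_scale * (
            1.0 + adapt_propensity[i] * _EARLY_BOOST
        )
        ratings: dict[str, list[int | None]] = {}
        component_matrix = np.zeros((3, 7), dtype=int)
        for s, symptom in enumerate(("flatulence", "bloating", "stomachache")):
            latent = (
                baselines[i, s]
                + shares[i, s] * rise[i] * shape
                + week_noise[i, s]
            )
            weekly = np.clip(np.rint(latent), 0, 4).astype(int)
            vector = [int(baselines[i, s])] + [int(v) for v in weekly]
            component_matrix[s] = vector
            ratings[symptom] = vector
        ratings["overall"] = [int(v) for v in component_matrix.max(axis=0)]
        diaries.append(
            SymptomDiary(
                subject_id=subject_id,
                arm=arm,
                sex=sex,
                dose_g_per_day=DOSE_BY_SEX[sex],
                ratings=ratings,
            )
        )

    # -- fecal abundance tables ------------------------------------------
    taxa, lineages, carg_map, carg1_members, significant = _build_taxa(config)
    rng_ab = _stream(config.seed, "abundance")
    n_taxa = len(taxa)
    mu = rng_ab.normal(-4.5, 1.2, n_taxa)
    subject_effect = rng_ab.normal(0.0, 0.7, size=(n_total, n_taxa))
    couple = np.zeros(n_taxa)
    for fid in carg1_members[1:]:
        couple[taxa.index(fid)] = 0.4  # inter-correlation within the guild
    if config.null_mode:
        couple[:] = 0.0

    sample_ids, subject_ids, timepoints, rows = [], [], [], []
    planted_idx = taxa.index(PLANTED_OTU)
    for tp in ("baseline", "week1", "week6"):
        tp_noise = rng_ab.normal(0.0, 0.35, size=(n_total, n_taxa))
        logv = mu[None, :] + subject_effect + tp_noise
        logv += couple[None, :] * tol[:, None]
        logv[:, planted_idx] = z + tp_noise[:, planted_idx]
        if tp != "baseline":
            # fermentable fiber boosts the planted taxon in the AX arm
            logv[is_ax, planted_idx] += 0.5
        values = np.exp(logv)
        values = values / values.sum(axis=1, keepdims=True)
        for i, (subject_id, _, _) in enumerate(subjects):
            sample_ids.append(f"{subject_id}_{tp}")
            subject_ids.append(subject_id)
            timepoints.append(tp)
            rows.append(values[i])
    fecal_table = AbundanceTable(
        sample_ids=sample_ids,
        subject_ids=subject_ids,
        timepoints=timepoints,
        feature_ids=taxa,
        values=np.array(rows),
        level="otu",
        taxonomy=lineages,
        carg_map=carg_map,
    )

    # -- ex-vivo active consortium ---------------------------------------
    rng_ex = _stream(config.seed, "exvivo")
    n_asv = 28
    asv_ids = [PLANTED_ASV] + [f"ASV{j + 1:03d}" for j in range(n_asv - 1)]
    asv_mu = rng_ex.normal(-4.0, 1.1, n_asv)
    degrader_bonus = np.zeros(n_asv)
    degrader_bonus[1:8] = rng_ex.uniform(0.5, 1.5, 7)  # fiber-degrader slots
    asv_noise = rng_ex.normal(0.0, 0.5, size=(n_total, n_asv))
    log_asv = asv_mu[None, :] + degrader_bonus[None, :] + asv_noise
    if config.null_mode:
        log_asv[:, 0] = -3.0 + asv_noise[:, 0]
    else:
        log_asv[:, 0] = z + 1.0 + 0.5 * asv_noise[:, 0]
    asv_values = np.exp(log_asv)
    asv_values = asv_values / asv_values.sum(axis=1, keepdims=True)
    exvivo_table = AbundanceTable(
        sample_ids=[f"{sid}_exvivo" for sid, _, _ in subjects],
        subject_ids=[sid for sid, _, _ in subjects],
        timepoints=["exvivo"] * n_total,
        feature_ids=asv_ids,
        values=asv_values,
        level="asv",
        taxonomy={
            PLANTED_ASV:
                "p__Actinobacteria; f__Bifidobacteriaceae; g__Bifidobacterium"
        },
        carg_map=None,
    )

    # -- metabolites ------------------------------------------------------
    rng_met = _stream(config.seed, "metabolites")
    ph0 = np.clip(rng_met.normal(6.9, 0.25, n_total), 5.5, 8.0)
    ph_shift = rng_met.normal(0.0, 0.15, n_total)
    acet0 = np.clip(rng_met.normal(55.0, 12.0, n_total), 5.0, None)
    acet_shift = rng_met.normal(0.0, 4.0, n_total)
    prop0 = np.clip(rng_met.normal(18.0, 5.0, n_total), 1.0, None)
    but0 = np.clip(rng_met.normal(15.0, 5.0, n_total), 1.0, None)
    prop_shift = rng_met.normal(0.0, 3.0, n_total)
    but_shift = rng_met.normal(0.0, 3.0, n_total)
    ph_shift = np.where(link_on, ph_shift + config.ph_link * tol, ph_shift)
    acet_shift = np.where(
        link_on, acet_shift + config.acetate_link * tol, acet_shift
    )
    metabolites: list[MetabolitePanel] = []
    for i, (subject_id, _, _) in enumerate(subjects):
        for tp, ph, ac, pr, bu in (
            ("baseline", ph0[i], acet0[i], prop0[i], but0[i]),
            (
                "week6",
                float(np.clip(ph0[i] + ph_shift[i], 4.5, 9.0)),
                max(1.0, acet0[i] + acet_shift[i]),
                max(1.0, prop0[i] + prop_shift[i]),
                max(1.0, but0[i] + but_shift[i]),
            ),
        ):
            scfa = {
                "acetate": float(ac),
                "propionate": float(pr),
                "butyrate": float(bu),
            }
            scfa["total"] = float(ac + pr + bu)
            metabolites.append(
                MetabolitePanel(
                    subject_id=subject_id, timepoint=tp, ph=float(ph), scfa=scfa
                )
            )

    # -- diet history -----------------------------------------------------
    rng_diet = _stream(config.seed, "diet")
    energy = np.clip(rng_diet.normal(2150.0, 320.0, n_total), 1400.0, 3200.0)
    wgrain_density = np.exp(rng_diet.normal(np.log(1.3), 0.35, n_total))
    ratio_noise = rng_diet.normal(0.0, 0.5, n_total)
    chol_noise = rng_diet.normal(0.0, 0.2, n_total)
    fiber_noise = rng_diet.normal(0.0, 0.15, n_total)
    rise_std = (rise - rise.mean()) / (rise.std() + 1e-12)
    log_ratio = np.where(
        link_on,
        0.3 + config.diet_gradient * rise_std + ratio_noise,
        0.3 + ratio_noise,
    )
    meat_density = np.exp(log_ratio) * wgrain_density
    diets: list[DietProfile] = []
    for i, (subject_id, _, _) in enumerate(subjects):
        scale = energy[i] / 1000.0
        diets.append(
            DietProfile(
                subject_id=subject_id,
                energy_kcal=float(energy[i]),
                intakes={
                    "meat_alternatives_servings": float(meat_density[i] * scale),
                    "whole_grains_servings": float(wgrain_density[i] * scale),
                    "cholesterol_mg": float(
                        120.0 * meat_density[i] * np.exp(chol_noise[i]) * scale
                    ),
                    "dietary_fiber_g": float(
                        (7.0 + 4.0 * wgrain_density[i])
                        * np.exp(fiber_noise[i]) * scale
                    ),
                },
            )
        )

    return CohortBundle(
        config=config,
        diaries=diaries,
        fecal_table=fecal_table,
        exvivo_table=exvivo_table,
        metabolites=metabolites,
        diets=diets,
        taxonomy=lineages,
        carg_map=carg_map,
        significant_otus=significant,
        tolerance={sid: float(t) for (sid, _, _), t in zip(subjects, tol)},
    )


def ground_truth(config: CohortConfig | None = None) -> list[dict]:
    """Machine-readable descriptors of the planted effects.

    Each entry names a feature, the score and window where its planted
    association should surface, and the expected correlation sign.
    Empty in ``null_mode``.
    """
    if config is None:
        config = CohortConfig()
    if config.null_mode:
        return []
    sign = int(np.sign(config.tolerance_effect_rho)) or 1
    effects = [
        {
            "feature_id": PLANTED_OTU,
            "feature_class": "otu",
            "symptom": "composite",
            "score_type": "auc_adaptation",
            "window": "baseline",
            "sign": sign,
        },
        {
            "feature_id": PLANTED_OTU,
            "feature_class": "otu",
            "symptom": "composite",
            "score_type": "auc_severity",
            "window": "w13",
            "sign": -sign,
        },
        {
            "feature_id": PLANTED_CARG,
            "feature_class": "carg",
            "symptom": "composite",
            "score_type": "auc_adaptation",
            "window": "baseline",
            "sign": sign,
        },
    ]
    if config.acetate_link != 0:
        effects.append(
            {
                "feature_id": "acetate",
                "feature_class": "scfa",
                "symptom": "composite",
                "score_type": "auc_adaptation",
                "window": "shift",
                "sign": sign * int(np.sign(config.acetate_link)),
            }
        )
    if config.ph_link != 0:
        effects.append(
            {
                "feature_id": "ph",
                "feature_class": "ph",
                "symptom": "composite",
                "score_type": "auc_severity",
                "window": "shift",
                "sign": -sign * int(np.sign(config.ph_link)),
            }
        )
    if config.diet_gradient != 0:
        effects.append(
            {
                "feature_id": "meat:wgrain",
                "feature_class": "diet",
                "symptom": "composite",
                "score_type": "auc_severity",
                "window": "baseline",
                "sign": int(np.sign(config.diet_gradient)),
            }
        )
    effects.append(
        {
            "feature_id": PLANTED_ASV,
            "feature_class": "asv",
            "symptom": "composite",
            "score_type": "auc_adaptation",
            "window": "exvivo",
            "sign": sign,
        }
    )
    return effects


def null_config(config: CohortConfig | None = None, **overrides) -> CohortConfig:
    """Convenience: a copy of ``config`` with every planted link severed."""
    if config is None:
        config = CohortConfig()
    return replace(config, null_mode=True, **overrides)
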