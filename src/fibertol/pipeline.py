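"""End-to-end orchestration: simulate -> scores -> features -> associate.

A run consumes either a directory of input tables or a simulation block,
executes every stage with the configured conventions, and writes all
outputs plus a manifest (materialized config, package version, file
hashes) into the run directory.  Outputs are deterministic given the
seed, so re-running a completed directory changes nothing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

import fibertol
from fibertol import associations, community, diet, io, scores as scoring
from fibertol.community import (
    ACTIVE_ASV_FILTER_THRESHOLD,
    TAXON_FILTER_THRESHOLD,
)
from fibertol.datamodel import ARMS
from fibertol.simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

#: Every configurable decision and its default, materialized into the
#: run manifest so nothing is hidden.
DEFAULT_RUN_CONFIG = {
    "seed": 0,
    "auc_mode": "incremental",
    "missing_policy": "strict",
    "p_value_mode": "approx",
    "taxon_filter_threshold": TAXON_FILTER_THRESHOLD,
    "active_asv_filter_threshold": ACTIVE_ASV_FILTER_THRESHOLD,
    "alpha_taxon": list(associations.ALPHA_TAXON),
    "alpha_other": list(associations.ALPHA_OTHER),
    "simulate": {},
    "inputs": None,
}


def load_run_config(path: str | Path | None = None, **overrides) -> dict:
    """Merge YAML config (if given) and overrides onto the defaults."""
    config = json.loads(json.dumps(DEFAULT_RUN_CONFIG))
    if path is not None:
        with open(path, encoding="utf-8") as handle:
            loaded = yaml.safe_load(handle) or {}
        unknown = set(loaded) - set(config)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(loaded)
    config.update({k: v for k, v in overrides.items() if v is not None})
    return config


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _load_inputs(config: dict, outdir: Path):
    """Either read the configured input tables or simulate a cohort."""
    if config["inputs"]:
        paths = {k: Path(v) for k, v in config["inputs"].items()}
        diaries = io.read_symptom_diaries(paths["diaries"])
        fecal = io.read_abundance_table(
            paths["fecal"], paths.get("taxonomy"), paths.get("carg_map"),
            level="otu",
        )
        exvivo = io.read_abundance_table(paths["exvivo"], level="asv")
        metabolites = io.read_metabolite_panels(paths["metabolites"])
        diets = io.read_diet_profiles(paths["diet"])
        whitelist = list(
            pd.read_csv(paths["significant_otus"])["feature_id"].astype(str)
        )
        return diaries, fecal, exvivo, metabolites, diets, whitelist

    sim_config = CohortConfig(seed=config["seed"], **config["simulate"])
    bundle = generate_cohort(sim_config)
    bundle.write(outdir / "inputs")
    return (
        bundle.diaries,
        bundle.fecal_table,
        bundle.exvivo_table,
        bundle.metabolites,
        bundle.diets,
        bundle.significant_otus,
    )


def _metabolite_shifts(metabolites) -> pd.DataFrame:
    by_subject: dict[str, dict[str, dict[str, float]]] = {}
    for panel in metabolites:
        entry = by_subject.setdefault(panel.subject_id, {})
        entry[panel.timepoint] = {"ph": panel.ph, **panel.scfa}
    rows, index = [], []
    for subject, entry in sorted(by_subject.items()):
        if "baseline" not in entry or "week6" not in entry:
            logger.info(
                "subject %s excluded from metabolite shifts: missing timepoint",
                subject,
            )
            continue
        base, week6 = entry["baseline"], entry["week6"]
        rows.append({k: week6[k] - base[k] for k in base if k in week6})
        index.append(subject)
    return pd.DataFrame(rows, index=index)


def run(config: dict, outdir: str | Path) -> Path:
    """Execute the full pipeline into ``outdir`` and return the path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fibertol")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_stages(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: dict, outdir: Path) -> Path:
    diaries, fecal, exvivo, metabolites, diets, whitelist = _load_inputs(
        config, outdir
    )
    arm_of = {d.subject_id: d.arm for d in diaries}
    subjects_by_arm = {
        arm: sorted(s for s, a in arm_of.items() if a == arm) for arm in ARMS
    }

    # -- stage: scores ----------------------------------------------------
    all_scores = scoring.score_cohort(
        diaries, auc_mode=config["auc_mode"], missing=config["missing_policy"]
    )
    scores_frame = io.scores_to_frame(all_scores)
    scores_frame.insert(1, "arm", scores_frame["subject_id"].map(arm_of))
    io._write_table(scores_frame, outdir / "scores.csv")
    adapted = scores_frame[
        ["subject_id", "arm", "symptom", "max_severity", "max_adaptation",
         "reverted"]
    ]
    io._write_table(adapted, outdir / "adapted_flags.csv")

    # -- stage: community features ---------------------------------------
    level_sets = {}
    for level in ("phylum", "family", "genus", "carg"):
        aggregated = community.aggregate(fecal, level)
        feature_set = community.filter_mean_abundance(
            aggregated, config["taxon_filter_threshold"]
        )
        level_sets[level] = feature_set
        io._write_table(
            feature_set.to_frame(), outdir / f"features_{level}.csv"
        )
    significant = community.select_features(fecal, whitelist)
    io._write_table(significant.to_frame(), outdir / "features_otu.csv")
    diversity = community.diversity_table(fecal)
    io._write_table(diversity, outdir / "diversity.csv")
    active = community.filter_mean_abundance(
        exvivo, config["active_asv_filter_threshold"], provenance="active_asvs"
    )
    io._write_table(active.to_frame(), outdir / "features_active_asv.csv")

    # -- stage: diet features --------------------------------------------
    diet_features = diet.diet_feature_table(diets)
    io._write_table(diet_features, outdir / "diet_features.csv", index=True)

    # -- stage: associations ---------------------------------------------
    metabolite_shifts = _metabolite_shifts(metabolites)
    fig3, fig4, fig5, fig6 = [], [], [], []
    for arm in ARMS:
        members = subjects_by_arm[arm]
        arm_scores = [s for s in all_scores if arm_of[s.subject_id] == arm]

        def arm_slice(frame: pd.DataFrame) -> pd.DataFrame:
            return frame.loc[frame.index.intersection(members)]

        for level, feature_class in (
            ("phylum", "taxon"), ("family", "taxon"), ("genus", "taxon"),
            ("carg", "carg"),
        ):
            fset = level_sets[level]
            fig3.extend(
                associations.windowed_severity_correlations(
                    arm_scores,
                    arm_slice(fset.subject_values("week1")),
                    arm_slice(fset.subject_values("week6")),
                    feature_class, arm,
                )
            )
        fig3.extend(
            associations.windowed_severity_correlations(
                arm_scores,
                arm_slice(significant.subject_values("week1")),
                arm_slice(significant.subject_values("week6")),
                "otu", arm,
            )
        )
        div_by_tp = {
            tp: diversity[diversity["timepoint"] == tp]
            .set_index("subject_id")[["shannon", "richness"]]
            for tp in ("week1", "week6")
        }
        fig3.extend(
            associations.windowed_severity_correlations(
                arm_scores,
                arm_slice(div_by_tp["week1"]),
                arm_slice(div_by_tp["week6"]),
                "diversity", arm,
            )
        )

        for fset, feature_class in (
            (significant, "otu"), (level_sets["carg"], "carg"),
        ):
            fig4.extend(
                associations.profile_correlations(
                    arm_scores,
                    arm_slice(fset.subject_values("baseline")),
                    feature_class, "baseline", arm,
                )
            )
            shifts = community.shift_table(
                _featureset_as_table(fset), fset.feature_ids
            )
            fig4.extend(
                associations.profile_correlations(
                    arm_scores, arm_slice(shifts), feature_class, "shift", arm,
                )
            )
        fig4.extend(
            associations.profile_correlations(
                arm_scores,
                arm_slice(active.subject_values("exvivo")),
                "asv", "exvivo", arm,
            )
        )

        fig5.extend(
            associations.profile_correlations(
                arm_scores, arm_slice(metabolite_shifts[["ph"]]), "ph",
                "shift", arm,
            )
        )
        scfa_cols = [c for c in metabolite_shifts.columns if c != "ph"]
        fig5.extend(
            associations.profile_correlations(
                arm_scores, arm_slice(metabolite_shifts[scfa_cols]), "scfa",
                "shift", arm,
            )
        )

        fig6.extend(
            associations.profile_correlations(
                arm_scores, arm_slice(diet_features), "diet", "baseline", arm,
            )
        )

    for name, results in (
        ("fig3_taxa", fig3),
        ("fig4_baseline_shift_exvivo", fig4),
        ("fig5_ph_scfa", fig5),
        ("fig6_diet", fig6),
    ):
        io._write_table(io.results_to_frame(results), outdir / f"{name}.csv")
    io.write_results(fig3 + fig4 + fig5 + fig6, all_scores, outdir / "results")

    io._write_table(
        associations.per_week_arm_comparison(diaries),
        outdir / "fig2_weekly_tests.csv",
    )
    io._write_table(
        associations.score_arm_comparison(all_scores, arm_of),
        outdir / "fig2_score_tests.csv",
    )
    for arm in ARMS:
        arm_diaries = [d for d in diaries if d.arm == arm]
        io._write_table(
            associations.within_arm_adaptation_tests(arm_diaries),
            outdir / f"fig2_adaptation_tests_{arm}.csv",
        )

    # -- manifest ---------------------------------------------------------
    outputs = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    )
    manifest = {
        "config": config,
        "version": fibertol.__version__,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return outdir


def _featureset_as_table(fset):
    """View a FeatureSet as an AbundanceTable for shift computation."""
    from fibertol.datamodel import AbundanceTable

    known = ("phylum", "family", "genus", "otu", "asv", "carg")
    level = fset.level if fset.level in known else "otu"
    return AbundanceTable(
        sample_ids=list(fset.sample_ids),
        subject_ids=list(fset.subject_ids),
        timepoints=list(fset.timepoints),
        feature_ids=list(fset.feature_ids),
        values=fset.values,
        level=level,
    )
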