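import numpy as np
import pandas as pd
import pytest

from fibertol import associations, community
from fibertol.scores import score_cohort
from fibertol.simulate import CohortConfig, generate_cohort, null_config


@pytest.fixture(scope="module")
def bundle():
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="module")
def ax_scores(bundle):
    ax = {d.subject_id for d in bundle.diaries if d.arm == "AX"}
    return [s for s in score_cohort(bundle.diaries) if s.subject_id in ax]


def _ax_subjects(bundle):
    return sorted(d.subject_id for d in bundle.diaries if d.arm == "AX")


class TestTierAssignment:
    @pytest.mark.parametrize(
        "p,feature_class,tier",
        [
            (0.005, "taxon", "significant"),
            (0.03, "taxon", "approached"),
            (0.07, "taxon", "ns"),
            (0.03, "diet", "significant"),
            (0.07, "scfa", "approached"),
            (0.2, "ph", "ns"),
        ],
    )
    def test_dual_alpha_rule(self, p, feature_class, tier):
        assert associations.assign_tier(p, feature_class) == tier


class TestWindowedCorrelations:
    def test_constant_feature_is_flagged_ns(self, bundle, ax_scores):
        subjects = _ax_subjects(bundle)
        constant = pd.DataFrame({"flat": 0.5}, index=subjects)
        results = associations.windowed_severity_correlations(
            ax_scores, constant, constant, "taxon", "AX",
            symptoms=("composite",),
        )
        assert all(r.tier == "ns" for r in results)
        assert all("zero_variance" in r.flags for r in results)

    def test_planted_negative_severity_link_recovered(self, bundle, ax_scores):
        table = bundle.fecal_table
        subjects = _ax_subjects(bundle)
        j = table.feature_index("B_longum_like")
        week1 = pd.DataFrame(
            {
                "B_longum_like": [
                    table.values[table.sample_index(s, "week1"), j]
                    for s in subjects
                ]
            },
            index=subjects,
        )
        week6 = pd.DataFrame(
            {
                "B_longum_like": [
                    table.values[table.sample_index(s, "week6"), j]
                    for s in subjects
                ]
            },
            index=subjects,
        )
        results = associations.windowed_severity_correlations(
            ax_scores, week1, week6, "otu", "AX", symptoms=("composite",)
        )
        by_window = {r.window: r for r in results}
        assert by_window["w13"].rho < 0
        assert by_window["w13"].tier in ("significant", "approached")

    def test_null_arm_mostly_quiet(self):
        # aggregate over several null cohorts: taxon cells rarely significant
        sig = total = 0
        for seed in range(8):
            null_bundle = generate_cohort(null_config(seed=seed))
            ax = sorted(
                d.subject_id for d in null_bundle.diaries if d.arm == "AX"
            )
            genus = community.filter_mean_abundance(
                community.aggregate(null_bundle.fecal_table, "genus"), 0.0015
            )
            scores = [
                s
                for s in score_cohort(null_bundle.diaries)
                if s.subject_id in set(ax)
            ]
            results = associations.windowed_severity_correlations(
                scores,
                genus.subject_values("week1").loc[ax],
                genus.subject_values("week6").loc[ax],
                "taxon",
                "AX",
            )
            for r in results:
                if r.flags:
                    continue
                total += 1
                sig += r.tier == "significant"
        assert sig / total < 0.05

    def test_missing_subject_dropped_pairwise(self, bundle, ax_scores):
        subjects = _ax_subjects(bundle)
        rng = np.random.default_rng(0)
        partial = pd.DataFrame(
            {"f": rng.normal(size=len(subjects) - 3)}, index=subjects[:-3]
        )
        results = associations.windowed_severity_correlations(
            ax_scores, partial, partial, "taxon", "AX", symptoms=("composite",)
        )
        assert all(r.n <= len(subjects) - 3 for r in results)


class TestProfileCorrelations:
    def test_planted_exvivo_adaptation_link(self, bundle, ax_scores):
        subjects = _ax_subjects(bundle)
        active = community.filter_mean_abundance(
            bundle.exvivo_table, 0.01, provenance="active_asvs"
        )
        values = active.subject_values("exvivo").loc[subjects]
        results = associations.profile_correlations(
            ax_scores, values[["ASV_Blongum_active"]], "asv", "exvivo", "AX",
            symptoms=("composite",), score_types=("auc_adaptation",),
        )
        assert len(results) == 1
        assert results[0].rho > 0
        assert results[0].tier in ("significant", "approached")

    def test_planted_diet_severity_link(self, bundle, ax_scores):
        from fibertol.diet import diet_feature_table

        subjects = _ax_subjects(bundle)
        features = diet_feature_table(bundle.diets).loc[subjects]
        results = associations.profile_correlations(
            ax_scores, features[["meat:wgrain"]], "diet", "baseline", "AX",
            symptoms=("composite",), score_types=("auc_severity",),
        )
        assert results[0].rho > 0
        assert results[0].p < 0.05

    def test_shuffling_labels_destroys_planted_tier(self, bundle, ax_scores):
        table = bundle.fecal_table
        subjects = _ax_subjects(bundle)
        j = table.feature_index("B_longum_like")
        baseline = np.array(
            [table.values[table.sample_index(s, "baseline"), j] for s in subjects]
        )
        rng = np.random.default_rng(11)
        surviving = 0
        n_shuffles = 60
        for _ in range(n_shuffles):
            shuffled = pd.DataFrame(
                {"B_longum_like": rng.permutation(baseline)}, index=subjects
            )
            results = associations.profile_correlations(
                ax_scores, shuffled, "otu", "baseline", "AX",
                symptoms=("composite",), score_types=("auc_adaptation",),
            )
            surviving += results[0].tier == "significant"
        assert surviving / n_shuffles <= 0.05

    def test_complete_resolution_subjects_excluded(self, bundle, ax_scores):
        flagged = {
            s.subject_id
            for s in ax_scores
            if s.symptom == "composite" and "complete_resolution" in s.flags
        }
        subjects = _ax_subjects(bundle)
        rng = np.random.default_rng(2)
        values = pd.DataFrame({"f": rng.normal(size=len(subjects))}, index=subjects)
        results = associations.profile_correlations(
            ax_scores, values, "otu", "baseline", "AX",
            symptoms=("composite",), score_types=("auc_adaptation",),
        )
        assert results[0].n == len(subjects) - len(flagged)


class TestRankTestTables:
    def test_per_week_comparison_shape(self, bundle):
        frame = associations.per_week_arm_comparison(bundle.diaries)
        assert set(frame["week"]) == set(range(1, 7))
        assert len(frame) == 5 * 6  # composite + 4 symptoms, 6 weeks
        assert (frame["p_bonferroni"] >= frame["p"] - 1e-12).all()

    def test_ax_arm_symptoms_elevated_early(self, bundle):
        frame = associations.per_week_arm_comparison(bundle.diaries)
        early = frame[(frame.symptom == "composite") & (frame.week <= 3)]
        assert (early["p"] < 0.05).any()

    def test_score_arm_comparison(self, bundle):
        scores = score_cohort(bundle.diaries)
        arm_of = bundle.arm_of()
        frame = associations.score_arm_comparison(scores, arm_of)
        assert len(frame) == 4 * 2
        composite = frame[
            (frame.symptom == "composite") & (frame.score_type == "auc_severity")
        ]
        assert composite["p"].iloc[0] < 0.05  # planted arm contrast

    def test_within_arm_adaptation_tests(self, bundle):
        ax = [d for d in bundle.diaries if d.arm == "AX"]
        frame = associations.within_arm_adaptation_tests(ax)
        assert set(frame["contrast"]) == {"max_vs_week6", "auc_w13_vs_w46"}
        composite = frame[
            (frame.contrast == "auc_w13_vs_w46") & (frame.symptom == "composite")
        ]
        assert composite["p"].iloc[0] < 0.05  # adaptation planted in AX arm
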