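import numpy as np
import pandas as pd
import pytest

from fibertol import io
from fibertol.datamodel import (
    AbundanceTable,
    MetabolitePanel,
    SymptomDiary,
    ValidationError,
)
from fibertol.scores import score_cohort
from tests.conftest import make_diary


class TestSymptomDiaryValidation:
    def test_valid_diary(self):
        diary = make_diary(flatulence=[0, 1, 2, 3, 4, 2, 1])
        assert diary.dose_g_per_day == 25

    def test_dose_follows_sex(self):
        assert make_diary(sex="M").dose_g_per_day == 35
        with pytest.raises(ValidationError, match="dose"):
            SymptomDiary(
                subject_id="S1", arm="AX", sex="F", dose_g_per_day=35,
                ratings=make_diary().ratings,
            )

    def test_rating_bounds(self):
        with pytest.raises(ValidationError, match="outside"):
            make_diary(flatulence=[0, 5, 0, 0, 0, 0, 0])

    def test_unknown_arm(self):
        with pytest.raises(ValidationError, match="arm"):
            make_diary(arm="PLACEBO")

    def test_wrong_length(self):
        with pytest.raises(ValidationError, match="weekly entries"):
            make_diary(flatulence=[0, 1, 2])


class TestDiaryIO:
    def test_round_trip(self, tmp_path):
        diaries = [
            make_diary("S1", flatulence=[0, 1, 2, 3, 4, 2, 1]),
            make_diary("S2", arm="MCC", sex="M", bloating=[1, 1, 2, 1, 1, 1, 1]),
        ]
        path = tmp_path / "diaries.csv"
        io.write_symptom_diaries(diaries, path)
        back = io.read_symptom_diaries(path)
        assert len(back) == 2
        by_id = {d.subject_id: d for d in back}
        for original in diaries:
            assert by_id[original.subject_id].ratings == original.ratings
            assert by_id[original.subject_id].arm == original.arm

    def test_rating_out_of_bounds_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject,arm,sex,week,symptom,rating\n"
            "S1,AX,F,0,flatulence,5\n"
        )
        with pytest.raises(ValidationError, match="S1.*week 0|week 0.*S1"):
            io.read_symptom_diaries(path)

    def test_missing_week_becomes_declared_missing(self, tmp_path):
        diaries = [make_diary("S1", flatulence=[0, 1, 1, 1, 1, 1, 1])]
        path = tmp_path / "diaries.csv"
        io.write_symptom_diaries(diaries, path)
        frame = pd.read_csv(path)
        frame = frame[~((frame.week == 4) & (frame.symptom == "flatulence"))]
        frame.to_csv(path, index=False)
        back = io.read_symptom_diaries(path)
        assert back[0].ratings["flatulence"][4] is None
        assert back[0].ratings["flatulence"][3] == 1

    def test_duplicate_cell_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "subject,arm,sex,week,symptom,rating\n"
            "S1,AX,F,1,flatulence,1\n"
            "S1,AX,F,1,flatulence,2\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            io.read_symptom_diaries(path)

    def test_unknown_arm_label_rejected(self, tmp_path):
        path = tmp_path / "arm.csv"
        path.write_text(
            "subject,arm,sex,week,symptom,rating\nS1,XX,F,1,flatulence,1\n"
        )
        with pytest.raises(ValidationError, match="arm"):
            io.read_symptom_diaries(path)

    def test_tsv_dialect_detected(self, tmp_path):
        path = tmp_path / "diaries.tsv"
        path.write_text(
            "subject\tarm\tsex\tweek\tsymptom\trating\n"
            "S1\tAX\tF\t1\tflatulence\t2\n"
        )
        back = io.read_symptom_diaries(path)
        assert back[0].ratings["flatulence"][1] == 2


class TestAbundanceIO:
    def _write(self, tmp_path, values, features=("A", "B")):
        frame = pd.DataFrame(values, columns=list(features))
        frame.insert(0, "timepoint", ["baseline", "week1"])
        frame.insert(0, "subject_id", ["S1", "S1"])
        frame.insert(0, "sample_id", ["S1_b", "S1_w1"])
        path = tmp_path / "abund.csv"
        frame.to_csv(path, index=False)
        return path

    def test_percent_rows_renormalized(self, tmp_path):
        path = self._write(tmp_path, [[60.0, 40.0], [30.0, 70.0]])
        table = io.read_abundance_table(path)
        assert np.allclose(table.values.sum(axis=1), 1.0)
        assert table.values[0, 0] == pytest.approx(0.6)

    def test_fraction_rows_unchanged(self, tmp_path):
        path = self._write(tmp_path, [[0.6, 0.4], [0.3, 0.7]])
        table = io.read_abundance_table(path)
        assert table.values[0, 0] == pytest.approx(0.6)

    def test_renormalization_idempotent(self, tmp_path):
        path = self._write(tmp_path, [[60.0, 40.0], [30.0, 70.0]])
        table = io.read_abundance_table(path)
        round_trip = tmp_path / "again.csv"
        io.write_abundance_table(table, round_trip)
        again = io.read_abundance_table(round_trip)
        assert np.allclose(table.values, again.values)

    def test_negative_value_rejected(self, tmp_path):
        path = self._write(tmp_path, [[-0.1, 1.1], [0.3, 0.7]])
        with pytest.raises(ValidationError, match="negative"):
            io.read_abundance_table(path)

    def test_carg_partition_enforced(self, tmp_path):
        path = self._write(tmp_path, [[0.6, 0.4], [0.3, 0.7]])
        carg_path = tmp_path / "carg.csv"
        carg_path.write_text("feature_id,carg_id\nA,CARG1\nA,CARG2\n")
        with pytest.raises(ValidationError, match="partition"):
            io.read_abundance_table(path, carg_path=carg_path)

    def test_unknown_carg_member_warned_and_dropped(self, tmp_path):
        path = self._write(tmp_path, [[0.6, 0.4], [0.3, 0.7]])
        carg_path = tmp_path / "carg.csv"
        carg_path.write_text("feature_id,carg_id\nA,CARG1\nZZZ,CARG1\n")
        with pytest.warns(UserWarning, match="ZZZ"):
            table = io.read_abundance_table(path, carg_path=carg_path)
        assert table.carg_map == {"A": "CARG1"}

    def test_duplicate_subject_timepoint_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            AbundanceTable(
                sample_ids=["a", "b"],
                subject_ids=["S1", "S1"],
                timepoints=["baseline", "baseline"],
                feature_ids=["A"],
                values=np.array([[1.0], [1.0]]),
                level="otu",
            )


class TestMetaboliteAndDietIO:
    def test_metabolite_round_trip(self, tmp_path):
        panels = [
            MetabolitePanel(
                "S1", "baseline", 6.8,
                {"acetate": 50.0, "propionate": 20.0, "butyrate": 10.0,
                 "total": 80.0},
            )
        ]
        path = tmp_path / "met.csv"
        io.write_metabolite_panels(panels, path)
        back = io.read_metabolite_panels(path)
        assert back[0].ph == pytest.approx(6.8)
        assert back[0].scfa["total"] == pytest.approx(80.0)

    def test_total_must_dominate_components(self):
        with pytest.raises(ValidationError, match="total"):
            MetabolitePanel("S1", "baseline", 6.8, {"acetate": 90.0, "total": 80.0})

    def test_diet_round_trip(self, tmp_path, default_bundle):
        path = tmp_path / "diet.csv"
        io.write_diet_profiles(default_bundle.diets, path)
        back = io.read_diet_profiles(path)
        assert len(back) == len(default_bundle.diets)
        assert back[0].intakes == pytest.approx(default_bundle.diets[0].intakes)


class TestResultsIO:
    def test_round_trip(self, tmp_path, default_bundle):
        from fibertol import associations, community

        scores = score_cohort(default_bundle.diaries)
        genus = community.filter_mean_abundance(
            community.aggregate(default_bundle.fecal_table, "genus"), 0.0015
        )
        results = associations.windowed_severity_correlations(
            scores,
            genus.subject_values("week1"),
            genus.subject_values("week6"),
            "taxon",
            "AX",
            symptoms=("composite",),
        )
        written = io.write_results(results, scores, tmp_path / "out")
        tidy, scores_frame = io.read_results(tmp_path / "out")
        assert len(tidy) == len(results)
        assert list(tidy.columns) == io.RESULT_COLUMNS
        original = io.results_to_frame(results)
        pd.testing.assert_frame_equal(
            tidy.fillna(""), pd.read_csv(written["associations"]).fillna("")
        )
        assert len(scores_frame) == len(scores)

    def test_empty_results_header_only(self, tmp_path):
        io.write_results([], [], tmp_path / "empty")
        tidy, scores_frame = io.read_results(tmp_path / "empty")
        assert len(tidy) == 0 and list(tidy.columns) == io.RESULT_COLUMNS
        assert len(scores_frame) == 0

    def test_matrix_has_one_column_per_score_window(self, tmp_path, default_bundle):
        from fibertol import associations, community

        scores = score_cohort(default_bundle.diaries)
        genus = community.filter_mean_abundance(
            community.aggregate(default_bundle.fecal_table, "genus"), 0.0015
        )
        results = associations.windowed_severity_correlations(
            scores,
            genus.subject_values("week1"),
            genus.subject_values("week6"),
            "taxon",
            "AX",
            symptoms=("composite", "flatulence"),
        )
        io.write_results(results, scores, tmp_path / "out")
        matrix = pd.read_csv(tmp_path / "out" / "associations_matrix.csv")
        cells = {
            (r.arm, r.symptom, r.score_type, r.window) for r in results
        }
        assert len(matrix.columns) == 1 + len(cells)
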