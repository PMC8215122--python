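"""Study-table parsing, quality checklist, and demographic pooling."""

import numpy as np
import pytest

from dualale.study_io import (
    Direction,
    FocusCoordinate,
    Space,
    StudyRecord,
    aggregate_demographics,
    compare_conditions,
    filter_by_quality,
    parse_study_table,
    score_quality,
    write_study_table,
)


def _write(tmp_path, studies_text, foci_text=None):
    sp = tmp_path / "studies.csv"
    sp.write_text(studies_text)
    fp = None
    if foci_text is not None:
        fp = tmp_path / "foci.csv"
        fp.write_text(foci_text)
    return sp, fp


_HEADER = (
    "study_id,condition,n_patients,n_controls,age_mean,age_sd,ctrl_age_mean,"
    "ctrl_age_sd,duration_mean,duration_sd,duration_is_median,hba1c_mean,"
    "hba1c_sd,q1,q2,q3,q4,q5,q6,q7,q8,q9,q10,q11,q12\n"
)
_ROW_A = "a,T1DM,30,19,14.3,4.0,13,3.2,5.6,3.8,0,8.4,0.9,1,1,1,1,1,1,1,1,1,0.5,0,0\n"
_ROW_B = "b,T2DM,16,16,61.2,7.8,59.6,6.1,13.2,5.6,0,8.4,1.7,1,1,1,1,1,1,1,1,1,1,0,0\n"


class TestParsing:
    def test_fixture_row_values_match_published_table(self, table2_records):
        r = table2_records[0]
        assert r.study_id == "kaufmann"
        assert (r.condition, r.n_patients, r.n_controls) == ("T1DM", 30, 19)
        assert r.duration_mean == pytest.approx(5.6)
        assert r.hba1c_mean == pytest.approx(8.4)
        assert r.quality.total == pytest.approx(9.5)

    def test_study_without_foci_rows_is_a_valid_null_study(self, tmp_path):
        sp, fp = _write(tmp_path, _HEADER + _ROW_A + _ROW_B,
                        "study_id,x,y,z,space,direction\n"
                        "b,10,20,30,MNI,reduction\n")
        records = parse_study_table(sp, fp)
        assert records[0].foci == ()
        assert len(records[1].foci) == 1
        assert records[1].foci[0].space is Space.MNI

    def test_unknown_coordinate_space_is_a_hard_error(self, tmp_path):
        sp, fp = _write(tmp_path, _HEADER + _ROW_A,
                        "study_id,x,y,z,space,direction\n"
                        "a,10,20,30,SPM99,reduction\n")
        with pytest.raises(ValueError, match="unknown coordinate space"):
            parse_study_table(sp, fp)

    def test_focus_referencing_undeclared_study_names_row(self, tmp_path):
        sp, fp = _write(tmp_path, _HEADER + _ROW_A,
                        "study_id,x,y,z,space,direction\n"
                        "ghost,1,2,3,MNI,reduction\n")
        with pytest.raises(ValueError, match="row 2.*undeclared"):
            parse_study_table(sp, fp)

    def test_unknown_condition_label_rejected_when_labels_given(self, tmp_path):
        sp, _ = _write(tmp_path, _HEADER + _ROW_A)
        with pytest.raises(ValueError, match="unknown condition label"):
            parse_study_table(sp, conditions=("T2DM", "GDM"))

    def test_non_numeric_coordinate_is_a_hard_error(self, tmp_path):
        sp, fp = _write(tmp_path, _HEADER + _ROW_A,
                        "study_id,x,y,z,space,direction\n"
                        "a,ten,2,3,MNI,reduction\n")
        with pytest.raises(ValueError, match="row 2"):
            parse_study_table(sp, fp)

    def test_round_trip_preserves_records(self, tmp_path, table2_records):
        sp = tmp_path / "out.csv"
        fp = tmp_path / "foci_out.csv"
        write_study_table(table2_records, sp, fp)
        again = parse_study_table(sp, fp)
        assert again == table2_records

    def test_round_trip_with_foci(self, tmp_path):
        rec = StudyRecord(
            study_id="s1", condition="T1DM", n_patients=10, n_controls=10,
            quality=score_quality([1] * 12),
            foci=(
                FocusCoordinate(1.5, -2.0, 3.0, Space.MNI, Direction.REDUCTION),
                FocusCoordinate(-10.0, 20.0, 30.0, Space.TALAIRACH,
                                Direction.INCREASE),
            ),
        )
        sp = tmp_path / "s.csv"
        fp = tmp_path / "f.csv"
        write_study_table([rec], sp, fp)
        assert parse_study_table(sp, fp) == [rec]


class TestQualityChecklist:
    @pytest.mark.parametrize(
        "items, total, included",
        [
            ([1] * 12, 12.0, True),
            ([1] * 8 + [0] * 4, 8.0, True),
            ([1] * 7 + [0.5] + [0] * 4, 7.5, False),
        ],
    )
    def test_totals_and_inclusion_threshold(self, items, total, included):
        q = score_quality(items)
        assert q.total == total
        assert q.included is included

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValueError, match="12 items"):
            score_quality([1] * 11)

    def test_out_of_set_score_rejected(self):
        with pytest.raises(ValueError, match="not in"):
            score_quality([1] * 11 + [0.3])

    def test_quality_filter_drops_below_threshold(self):
        lo = StudyRecord("lo", "T1DM", 5, 5, quality=score_quality([1] * 7 + [0] * 5))
        hi = StudyRecord("hi", "T1DM", 5, 5, quality=score_quality([1] * 9 + [0] * 3))
        assert filter_by_quality([lo, hi]) == [hi]


class TestAggregation:
    def test_single_study_pools_to_itself(self):
        r = StudyRecord("s", "T1DM", 12, 11, age_mean=30.0, age_sd=5.0,
                        duration_mean=4.0, duration_sd=1.0,
                        hba1c_mean=8.0, hba1c_sd=1.0,
                        quality=score_quality([1] * 12))
        s = aggregate_demographics([r]).per_condition["T1DM"]
        assert s.total_patients == 12 and s.total_controls == 11
        assert s.mean_of_means["age"] == pytest.approx(30.0)
        assert s.mean_of_sds["hba1c"] == pytest.approx(1.0)

    def test_missing_covariates_excluded_not_imputed(self):
        rs = [
            StudyRecord("a", "T1DM", 5, 5, hba1c_mean=8.0,
                        quality=score_quality([1] * 12)),
            StudyRecord("b", "T1DM", 5, 5, hba1c_mean=None,
                        quality=score_quality([1] * 12)),
        ]
        s = aggregate_demographics(rs).per_condition["T1DM"]
        assert s.mean_of_means["hba1c"] == pytest.approx(8.0)
        assert s.n_missing["hba1c"] == 1

    def test_order_invariance_of_aggregation(self, table2_records):
        fwd = aggregate_demographics(table2_records)
        rng = np.random.default_rng(0)
        shuffled = list(table2_records)
        rng.shuffle(shuffled)
        rev = aggregate_demographics(shuffled)
        for cond in ("T1DM", "T2DM"):
            f = fwd.per_condition[cond].mean_of_means
            r = rev.per_condition[cond].mean_of_means
            assert f.keys() == r.keys()
            for k in f:
                assert f[k] == pytest.approx(r[k], abs=1e-12)
        assert fwd.quality_mean == pytest.approx(rev.quality_mean, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_demographics([])

    def test_column_sum_conservation(self, table2_records):
        s = aggregate_demographics(table2_records)
        assert s.total_patients == 1175
        assert s.total_controls == 1013


class TestConditionComparison:
    def test_identical_value_vectors_give_zero_statistic(self):
        mk = lambda sid, cond, age: StudyRecord(
            sid, cond, 5, 5, age_mean=age, duration_mean=5.0, hba1c_mean=8.0,
            quality=score_quality([1] * 12))
        rs = [mk("a1", "X", 20.0), mk("a2", "X", 30.0),
              mk("b1", "Y", 20.0), mk("b2", "Y", 30.0)]
        t = compare_conditions(rs)
        assert t["age"]["statistic"] == pytest.approx(0.0)
        assert t["age"]["p"] == pytest.approx(1.0)

    def test_too_few_usable_studies_rejected(self):
        mk = lambda sid, cond, hb: StudyRecord(
            sid, cond, 5, 5, age_mean=30.0, duration_mean=5.0, hba1c_mean=hb,
            quality=score_quality([1] * 12))
        rs = [mk("a1", "X", 8.0), mk("a2", "X", None),
              mk("b1", "Y", 8.0), mk("b2", "Y", 9.0)]
        with pytest.raises(ValueError, match="hba1c"):
            compare_conditions(rs)

    def test_welch_on_published_ages_significant_durations_not(
        self, table2_records
    ):
        t = compare_conditions(table2_records)
        assert t["age"]["p"] < 0.01
        assert t["duration"]["p"] > 0.05


class TestFocusValidation:
    def test_non_finite_coordinate_rejected(self):
        with pytest.raises(ValueError):
            FocusCoordinate(float("nan"), 0, 0, Space.MNI, Direction.REDUCTION)

    def test_out_of_sanity_bound_rejected(self):
        with pytest.raises(ValueError, match="sanity bound"):
            FocusCoordinate(250.0, 0, 0, Space.MNI, Direction.REDUCTION)

    def test_group_sizes_must_be_positive(self):
        with pytest.raises(ValueError, match=">= 1"):
            StudyRecord("s", "T1DM", 0, 5)
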