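"""Instrument scoring, record screening, wave matching, descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cognet.descriptives import compare_samples, compare_waves, prevalence
from cognet.qc import QCConfig, apply_qc, match_waves
from cognet.records import (
    frame_to_records,
    read_records_csv,
    records_to_frame,
    score_record,
    score_wave,
    write_records_csv,
)
from cognet.scales import (
    CONSTRUCTS,
    DEFAULT_SCALES,
    RRS,
    MissingItemError,
    ScaleDefinition,
    score_bounds,
)

from .conftest import clean_record, paired_from_arrays


class TestScoring:
    def test_minimum_and_simple_sums(self):
        rec = clean_record("x", fill=0)
        scores = score_record(rec)
        assert scores["PHQ"] == 0
        assert scores["GAD"] == 0
        # 1-based scales clip the fill to their minimum
        assert scores["SR"] + scores["BD"] + scores["RP"] == 22
        rec2 = clean_record("y", per_construct={"PHQ": 1})
        assert score_record(rec2)["PHQ"] == 9

    def test_rrs_subscales_partition_the_items(self):
        rec = clean_record("x", fill=4)
        s = score_record(rec)
        # all 22 RRS items at 4 split across the three facets
        assert s["SR"] + s["BD"] + s["RP"] == 88
        assert s["SR"] == 48 and s["BD"] == 20 and s["RP"] == 20

    def test_missing_item_names_scale_and_index(self):
        rec = clean_record("x")
        rec.responses["gad"][2] = None
        with pytest.raises(MissingItemError, match="gad.*item 3"):
            score_record(rec)

    def test_scoring_invariant_to_item_order_given_subscale_map(self):
        """Permuting items together with the subscale map leaves every
        construct total unchanged."""
        rng = np.random.default_rng(4)
        responses = rng.integers(1, 5, size=22).tolist()
        perm = rng.permutation(22)
        permuted = [responses[perm[i]] for i in range(22)]
        inverse = {int(orig) + 1: i + 1 for i, orig in enumerate(perm)}
        rrs_perm = ScaleDefinition(
            "rrs", 22, 1, 4,
            subscales={
                label: tuple(inverse[i] for i in items)
                for label, items in RRS.subscales.items()
            },
        )
        assert RRS.score(responses) == rrs_perm.score(permuted)

    def test_invalid_definitions_rejected(self):
        with pytest.raises(ValueError, match="two subscales"):
            ScaleDefinition("bad", 4, 0, 3,
                            subscales={"a": (1, 2), "b": (2, 3)})
        with pytest.raises(ValueError, match="outside"):
            ScaleDefinition("bad", 4, 0, 3, subscales={"a": (0, 1)})
        with pytest.raises(ValueError, match="response_min"):
            ScaleDefinition("bad", 4, 3, 3)

    def test_score_bounds_cover_scored_records(self):
        rec = clean_record("x", fill=5)
        scores = score_record(rec)
        for c in CONSTRUCTS:
            lo, hi = score_bounds(c)
            assert lo <= scores[c] <= hi


class TestQC:
    def test_five_record_fixture_filters_applied_by_hand(
        self, five_record_fixture
    ):
        retained, report = apply_qc(
            five_record_fixture, QCConfig(outlier_z=1.5)
        )
        assert [r.code for r in retained] == ["E"]
        assert report.n_input == 5
        assert report.n_retained == 1
        assert report.exclusions == {
            "lie": 1, "missing": 1, "fast": 1, "outlier": 1
        }

    def test_all_clean_records_retained(self):
        records = [clean_record(f"r{i}") for i in range(10)]
        retained, report = apply_qc(records)
        assert report.n_retained == report.n_input == 10
        assert report.exclusions == {}

    def test_empty_input(self):
        retained, report = apply_qc([])
        assert retained == []
        assert report.n_input == report.n_retained == 0

    def test_age_filter_and_first_reason_attribution(self):
        # under-age AND too fast: age is checked after speed, so the
        # record is attributed to "fast"
        rec = clean_record("x", age=16.0, response_time_s=100.0)
        _, report = apply_qc([rec, clean_record("y")])
        assert report.exclusions == {"fast": 1}
        rec2 = clean_record("z", age=16.0)
        _, report2 = apply_qc([rec2, clean_record("y")])
        assert report2.exclusions == {"age_grade": 1}

    def test_missing_demographic_excluded(self):
        rec = clean_record("x")
        rec.demographics["sex"] = None
        _, report = apply_qc([rec, clean_record("y")])
        assert report.exclusions == {"demographic": 1}

    @given(st.lists(
        st.tuples(st.booleans(), st.booleans(), st.booleans()),
        min_size=0, max_size=25,
    ))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_report_counts_always_conserve(self, flags):
        """n_input == n_retained + sum of exclusions on arbitrary
        mixes of lie / missing / fast violations."""
        records = []
        for i, (lie, missing, fast) in enumerate(flags):
            rec = clean_record(f"r{i}", lie_ok=not lie)
            if missing:
                rec.responses["anis"][0] = None
            if fast:
                rec.response_time_s = 120.0
            records.append(rec)
        retained, report = apply_qc(records)
        assert report.n_input == len(records)
        assert report.n_retained + sum(
            report.exclusions.values()
        ) == report.n_input
        assert len(retained) == report.n_retained


class TestMatching:
    def test_inner_join_on_codes(self):
        t1 = [clean_record(c, "T1") for c in "abc"]
        t2 = [clean_record(c, "T2") for c in "bcd"]
        paired = match_waves(t1, t2)
        assert list(paired.t1.index) == ["b", "c"]
        assert paired.n_matched == 2
        assert paired.n_t1_only == 1 and paired.n_t2_only == 1

    def test_disjoint_and_full_overlap(self):
        t1 = [clean_record(c, "T1") for c in "abcde"]
        assert match_waves(
            t1, [clean_record(c, "T2") for c in "vwxyz"]
        ).n_matched == 0
        assert match_waves(
            t1, [clean_record(c, "T2") for c in "abcde"]
        ).n_matched == 5

    def test_duplicate_codes_rejected(self):
        t1 = [clean_record("a"), clean_record("a")]
        with pytest.raises(ValueError, match="duplicate.*T1"):
            match_waves(t1, [clean_record("b", "T2")])


class TestDescriptives:
    def test_prevalence_fraction_at_or_above_cutoff(self):
        scores = pd.DataFrame({"PHQ": [4, 5, 6]})
        assert prevalence(scores, "PHQ", 5) == pytest.approx(2 / 3)
        assert prevalence(scores, "PHQ", 100) == 0.0
        assert prevalence(scores, "PHQ", 0) == 1.0

    def test_paired_t_hand_computed(self):
        """diffs (1,-1,2,0,3): mean 1, s_d = sqrt(10/4), so
        t = 1 / (1.5811 / sqrt(5)) = 1.4142."""
        X1 = np.zeros((5, 7))
        X2 = X1.copy()
        X2[:, 0] = [1, -1, 2, 0, 3]
        X2[:, 1] = np.arange(5)  # keep other columns non-degenerate
        X1[:, 1:] = np.random.default_rng(0).normal(size=(5, 6))
        paired = paired_from_arrays(X1, X2, list(CONSTRUCTS))
        res = compare_waves(paired)
        assert res.loc["PHQ", "t"] == pytest.approx(1.41421, abs=1e-4)
        assert res.loc["PHQ", "df"] == 4

    def test_identical_waves_degenerate_flagged(self):
        X = np.random.default_rng(1).normal(size=(6, 7))
        res = compare_waves(paired_from_arrays(X, X, list(CONSTRUCTS)))
        assert res["degenerate"].all()
        assert (res["t"] == 0).all()

    def test_constant_nonzero_diffs_degenerate(self):
        X = np.random.default_rng(2).integers(0, 20, size=(4, 7)).astype(float)
        res = compare_waves(
            paired_from_arrays(X, X + 1.0, list(CONSTRUCTS))
        )
        assert res["degenerate"].all()

    def test_paired_t_matches_one_sample_on_jittered_constant(self):
        """Paired t on (X, X + c + jitter) equals the one-sample t of
        the jittered constant."""
        from scipy import stats

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 7))
        shift = 0.5 + rng.normal(0, 0.1, size=(40, 1))
        res = compare_waves(
            paired_from_arrays(X, X + shift, list(CONSTRUCTS))
        )
        expect = stats.ttest_1samp(shift.ravel(), 0.0)
        for c in CONSTRUCTS:
            assert res.loc[c, "t"] == pytest.approx(
                expect.statistic, rel=1e-9
            )

    def test_welch_independent_samples(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame(rng.normal(0, 1, (30, 2)), columns=["PHQ", "GAD"])
        b = pd.DataFrame(rng.normal(1, 2, (50, 2)), columns=["PHQ", "GAD"])
        res = compare_samples(a, b)
        assert (res["p"] < 0.05).any()
        with pytest.raises(ValueError):
            compare_samples(a.iloc[:1], b)


class TestRecordsIO:
    def test_csv_round_trip(self, tmp_path):
        records = [clean_record(f"r{i}") for i in range(4)]
        records[1].responses["rrs"][5] = None
        records[2].lie_ok = False
        records[3].demographics["sex"] = None
        path = tmp_path / "records.csv"
        write_records_csv(records, path)
        back = read_records_csv(path)
        assert [r.code for r in back] == [r.code for r in records]
        assert back[1].responses["rrs"][5] is None
        assert back[2].lie_ok is False
        assert back[3].demographics["sex"] is None
        assert score_record(back[0]) == score_record(records[0])

    def test_frame_round_trip_preserves_scores(self):
        records = [clean_record(f"r{i}", fill=i % 4) for i in range(6)]
        back = frame_to_records(records_to_frame(records))
        pd.testing.assert_frame_equal(
            score_wave(records), score_wave(back)
        )
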