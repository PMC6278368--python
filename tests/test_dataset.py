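"""Curation, labelling, splitting and filtering of compound datasets."""

import math

import numpy as np
import pandas as pd
import pytest

from mgmtqsar.dataset import (
    CensoredValue,
    CompoundRecord,
    diversity_summary,
    filter_descriptors,
    label_activity,
    parse_ed50,
    split_classification,
    split_qsar_ranked,
    to_ped50,
)


class TestToPed50:
    @pytest.mark.parametrize(
        "ed50, expected",
        [(1.0, 0.0), (1000.0, -3.0), (0.05, 1.301)],
    )
    def test_log_transform(self, ed50, expected):
        assert to_ped50(ed50) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            to_ped50(bad)

    def test_censored_rejected(self):
        with pytest.raises(ValueError):
            to_ped50(CensoredValue(bound=10, direction=">"))


class TestParseEd50:
    def test_round_trip(self):
        v = parse_ed50(">10")
        assert isinstance(v, CensoredValue)
        assert (v.bound, v.direction) == (10.0, ">")
        assert parse_ed50("0.5") == 0.5


class TestLabelActivity:
    def test_potency_above_fold_cutoff_is_positive(self):
        # reference 0.5 uM, compound 10 uM: potency ratio 0.05 > 1/50 -> P
        recs = label_activity([CompoundRecord("a", ed50=10.0)], reference_ed50=0.5)
        assert recs[0].class_label == "P"

    def test_equal_to_reference_is_positive(self):
        recs = label_activity([CompoundRecord("a", ed50=0.5)], reference_ed50=0.5)
        assert recs[0].class_label == "P"

    def test_exactly_at_cutoff_is_negative(self):
        # "more than 1/50 potency" read strictly
        recs = label_activity([CompoundRecord("a", ed50=25.0)], reference_ed50=0.5)
        assert recs[0].class_label == "N"

    def test_censored_weak_compound_is_negative(self):
        recs = label_activity(
            [CompoundRecord("a", ed50=CensoredValue(10, ">"))],
            reference_ed50=CensoredValue(1, "<"),
        )
        assert recs[0].class_label == "N"

    def test_censored_potent_compound_is_positive(self):
        recs = label_activity(
            [CompoundRecord("a", ed50=CensoredValue(1, "<"))],
            reference_ed50=CensoredValue(1, "<"),
        )
        assert recs[0].class_label == "P"

    def test_straddling_bound_left_unlabeled(self):
        recs = label_activity(
            [CompoundRecord("a", ed50=CensoredValue(5, ">"))],
            reference_ed50=0.01,  # cutoff 0.5; ">5" with censor_cutoff 10 is unresolvable
        )
        assert recs[0].class_label == "unlabeled"


class TestSplitQsarRanked:
    @pytest.mark.parametrize("n, n_test, n_train", [(103, 20, 83), (84, 16, 68)])
    def test_every_fifth_counts(self, n, n_test, n_train):
        recs = [CompoundRecord(f"c{i:03d}", ped50=i * 0.1) for i in range(n)]
        split_qsar_ranked(recs)
        assert sum(r.split == "test" for r in recs) == n_test
        assert sum(r.split == "train" for r in recs) == n_train

    def test_degenerate_all_train(self):
        recs = [CompoundRecord(f"c{i}", ped50=float(i)) for i in range(4)]
        split_qsar_ranked(recs)
        assert all(r.split == "train" for r in recs)

    def test_test_compounds_spread_over_activity_ranks(self):
        recs = [CompoundRecord(f"c{i:03d}", ped50=float(i)) for i in range(25)]
        split_qsar_ranked(recs)
        ranked = sorted(recs, key=lambda r: -r.ped50)
        test_positions = [i for i, r in enumerate(ranked) if r.split == "test"]
        assert test_positions == [2, 7, 12, 17, 22]  # middle of each block of 5

    def test_split_partitions_dataset(self):
        recs = [CompoundRecord(f"c{i}", ped50=float(i)) for i in range(37)]
        split_qsar_ranked(recs)
        assert all(r.split in ("train", "test") for r in recs)


class TestSplitClassification:
    def _records(self, n_p=62, n_n=67):
        recs = [CompoundRecord(f"c{i:03d}", ped50=0.0) for i in range(n_p + n_n)]
        for i, r in enumerate(recs):
            r.class_label = "P" if i < n_p else "N"
        return recs

    def test_stratified_four_to_one(self):
        recs = self._records()
        split_classification(recs, seed=0)
        train = [r for r in recs if r.split == "train"]
        test = [r for r in recs if r.split == "test"]
        assert (len(train), len(test)) == (104, 25)
        assert sum(r.class_label == "P" for r in train) == 50
        assert sum(r.class_label == "P" for r in test) == 12

    def test_deterministic_under_seed(self):
        r1, r2 = self._records(), self._records()
        split_classification(r1, seed=42)
        split_classification(r2, seed=42)
        assert [r.split for r in r1] == [r.split for r in r2]

    def test_small_balanced_split(self):
        recs = self._records(5, 5)
        split_classification(recs, seed=1)
        train = [r for r in recs if r.split == "train"]
        assert len(train) == 8
        assert sum(r.class_label == "P" for r in train) == 4

    def test_missing_class_rejected(self):
        recs = self._records(5, 0)
        with pytest.raises(ValueError):
            split_classification(recs)


class TestFilterDescriptors:
    def test_constant_column_dropped(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        out, log = filter_descriptors(m)
        assert list(out.columns) == ["b"]
        assert "near-constant" in log["a"]

    def test_duplicated_column_drops_exactly_one(self):
        m = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0],
             "c": [4.0, 1.0, 3.0, 2.0]}
        )
        out, log = filter_descriptors(m)
        assert list(out.columns) == ["a", "c"]
        assert "inter-correlated" in log["b"]

    def test_correlation_structure_on_hand_fixture(self):
        # columns engineered so r(a,b) > 0.95 but r(a,c), r(b,c) small
        rng = np.random.default_rng(0)
        a = rng.standard_normal(200)
        b = a + 0.05 * rng.standard_normal(200)
        c = rng.standard_normal(200)
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.99
        m = pd.DataFrame({"a": a, "b": b, "c": c})
        out, _ = filter_descriptors(m)
        assert list(out.columns) == ["a", "c"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((50, 4))
        m = pd.DataFrame(
            np.column_stack([base, base[:, 0] * 1.001, np.ones(50)]),
            columns=list("abcdef"),
        )
        once, _ = filter_descriptors(m)
        twice, log2 = filter_descriptors(once)
        pd.testing.assert_frame_equal(once, twice)
        assert not log2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            filter_descriptors(pd.DataFrame())


class TestDiversitySummary:
    def test_identical_fingerprints_distance_zero(self):
        m = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["a", "b"])
        _, d = diversity_summary(m)
        assert d.loc["a", "b"] == 0.0

    def test_complementary_vectors_normalize_to_one(self):
        bits = np.zeros((3, 166), dtype=int)
        bits[1] = 1  # complement of row 0
        bits[2, :5] = 1
        m = pd.DataFrame(bits, index=["a", "b", "c"])
        _, d = diversity_summary(m)
        assert d.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_distance(self):
        m = pd.DataFrame([[1, 0, 1], [1, 1, 0], [0, 0, 0]], index=list("abc"))
        _, d = diversity_summary(m)
        # raw distances: ab = sqrt(2), ac = sqrt(2), bc = sqrt(2); all equal -> 1
        assert d.loc["a", "b"] == pytest.approx(1.0)

    def test_metric_properties_on_random_fixture(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(8, 20)))
        _, d = diversity_summary(m)
        arr = d.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 0)
        # triangle inequality survives min-max scaling (common factor)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert arr[i, j] <= arr[i, k] + arr[k, j] + 1e-12
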