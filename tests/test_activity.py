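import math

import numpy as np
import pytest
import scipy.sparse as sp

from haircut.activity import (
    Correction,
    activity_scores,
    log_normalize,
    pairwise_rank_test,
    position_profile,
    scores_frame,
)
from haircut.repair_matrix import RepairCountMatrix, build_matrix
from haircut.umi_count import PositionCounts


def _matrix(entries, cells):
    return build_matrix(PositionCounts(entries), cells)


class TestLogNormalize:
    def test_stated_formula(self):
        # count 10 of a 1000-count cell at scale 1e4 -> ln(1 + 100)
        m = _matrix({("B1", "s", 45): 10, ("B1", "s", 1): 990}, ["B1"])
        out = log_normalize(m)
        j = m.features.index(("s", 45))
        assert out[0, j] == pytest.approx(math.log(1 + 100), abs=1e-6)
        assert out[0, j] == pytest.approx(4.6151, abs=1e-4)

    def test_zero_count_maps_to_zero(self):
        m = _matrix({("B1", "s", 1): 5}, ["B1", "B2"])
        out = log_normalize(m)
        assert out[1, 0] == 0.0
        assert out.nnz == 1

    def test_single_feature_cell_independent_of_total(self):
        # count == total == t gives ln(1 + scale) for any t
        for t in (1, 7, 500):
            m = _matrix({("B1", "s", 45): t}, ["B1"])
            assert log_normalize(m)[0, 0] == pytest.approx(math.log(1 + 1e4))

    def test_invalid_scale_rejected(self):
        m = _matrix({("B1", "s", 1): 1}, ["B1"])
        with pytest.raises(ValueError):
            log_normalize(m, scale=0)

    def test_monotone_in_count_and_depth_invariant(self):
        m1 = _matrix({("B1", "s", 45): 3, ("B1", "s", 1): 7}, ["B1"])
        m2 = _matrix({("B1", "s", 45): 5, ("B1", "s", 1): 5}, ["B1"])
        j = m1.features.index(("s", 45))
        assert log_normalize(m2)[0, j] > log_normalize(m1)[0, j]
        # duplicating every count leaves normalized values unchanged
        doubled = RepairCountMatrix(
            m1.cell_barcodes, m1.features, m1.counts * 2
        )
        assert np.allclose(
            log_normalize(doubled).toarray(), log_normalize(m1).toarray()
        )


class TestActivityScores:
    def test_raw_count_at_scored_site(self, example_substrates):
        m = _matrix({("B1", "uracilA", 45): 20, ("B1", "uracilA", 1): 80}, ["B1"])
        scores = {s.activity_name: s for s in activity_scores(m, example_substrates)}
        assert scores["uracilA:45"].raw_count == 20
        assert scores["uracilA:45"].score == pytest.approx(
            math.log(1 + 20 / 100 * 1e4)
        )

    def test_intact_only_cell_scores_zero(self, example_substrates):
        m = _matrix({("B1", "uracilA", 1): 50}, ["B1"])
        scores = {s.activity_name: s for s in activity_scores(m, example_substrates)}
        assert scores["uracilA:45"].raw_count == 0
        assert scores["uracilA:45"].score == 0.0

    def test_short_and_long_patch_scored_independently(self, example_substrates):
        m = _matrix(
            {("B1", "abasicG", 45): 6, ("B1", "abasicG", 46): 2,
             ("B1", "abasicG", 1): 12},
            ["B1"],
        )
        scores = {s.activity_name: s for s in activity_scores(m, example_substrates)}
        assert scores["abasicG:45"].raw_count == 6   # short patch
        assert scores["abasicG:46"].raw_count == 2   # long patch

    def test_multi_site_activity_sums_counts(self, example_substrates):
        m = _matrix(
            {("B1", "abasicG", 45): 6, ("B1", "abasicG", 46): 2}, ["B1"]
        )
        scores = activity_scores(
            m, example_substrates,
            activities={"abasic_total": ("abasicG", [45, 46])},
        )
        assert scores[0].raw_count == 8

    def test_score_zero_iff_raw_zero(self, example_substrates):
        m = _matrix(
            {("B1", "uracilA", 45): 1, ("B1", "uracilA", 1): 400,
             ("B2", "uracilA", 1): 5},
            ["B1", "B2"],
        )
        for s in activity_scores(m, example_substrates):
            assert (s.score == 0) == (s.raw_count == 0)


class TestPositionProfile:
    def test_group_mean_includes_zeros(self):
        m = _matrix({("B1", "s", 45): 4}, ["B1", "B2"])
        prof = position_profile(m, {"B1": "g", "B2": "g"})
        assert prof.loc[0, "mean_count"] == 2.0

    def test_single_group_equals_column_means(self):
        m = _matrix(
            {("B1", "s", 1): 2, ("B2", "s", 1): 4, ("B2", "s", 45): 6},
            ["B1", "B2"],
        )
        prof = position_profile(m, {"B1": "g", "B2": "g"})
        means = dict(zip([tuple(f) for f in m.features],
                         np.asarray(m.counts.mean(axis=0)).ravel()))
        for _, row in prof.iterrows():
            assert row["mean_count"] == means[(row["substrate"], row["position"])]

    def test_profile_conserves_matrix_totals(self):
        rng = np.random.default_rng(2)
        entries = {
            (f"B{i}", "s", int(p)): int(c)
            for i, (p, c) in enumerate(zip(rng.integers(1, 50, 30),
                                           rng.integers(1, 20, 30)))
        }
        cells = sorted({k[0] for k in entries})
        m = build_matrix(PositionCounts(entries), cells)
        labels = {cb: ("g1" if i % 2 else "g2") for i, cb in enumerate(cells)}
        prof = position_profile(m, labels)
        total = (prof["mean_count"] * prof["n_cells"]).sum()
        assert total == pytest.approx(m.total())

    def test_unlabeled_cell_rejected(self):
        m = _matrix({("B1", "s", 1): 1}, ["B1", "B2"])
        with pytest.raises(ValueError, match="unlabeled"):
            position_profile(m, {"B1": "g"})


def _scores(values_by_cell, activity="act"):
    from haircut.activity import ActivityScore

    return [
        ActivityScore(cb, activity, 1, float(v)) for cb, v in values_by_cell.items()
    ]


class TestPairwiseRankTest:
    def test_exact_p_for_fully_separated_triples(self):
        """U = 0 for {1,2,3} vs {4,5,6}; exact two-sided p = 2/20 = 0.1."""
        scores = _scores({f"a{i}": v for i, v in enumerate([1, 2, 3])} |
                         {f"b{i}": v for i, v in enumerate([4, 5, 6])})
        labels = {cb: cb[0] for cb in "a0 a1 a2 b0 b1 b2".split()}
        (comp,) = pairwise_rank_test(scores, labels)
        assert comp.statistic == 0.0
        assert comp.p_value == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        scores = _scores({"a0": 1, "a1": 2, "a2": 3, "b0": 1, "b1": 2, "b2": 3})
        labels = {cb: cb[0] for cb in "a0 a1 a2 b0 b1 b2".split()}
        (comp,) = pairwise_rank_test(scores, labels)
        assert comp.p_value == pytest.approx(1.0)

    def test_label_swap_preserves_p(self):
        scores = _scores({"a0": 1, "a1": 5, "a2": 3, "b0": 4, "b1": 2, "b2": 6})
        labels = {cb: cb[0] for cb in "a0 a1 a2 b0 b1 b2".split()}
        swapped = {cb: ("b" if g == "a" else "a") for cb, g in labels.items()}
        (c1,) = pairwise_rank_test(scores, labels)
        (c2,) = pairwise_rank_test(scores, swapped)
        assert c1.p_value == pytest.approx(c2.p_value)
        assert c1.log_fold_change == pytest.approx(-c2.log_fold_change)

    def test_adjusted_p_at_least_p(self):
        rng = np.random.default_rng(4)
        scores = []
        labels = {}
        for grp in "abc":
            for i in range(10):
                cb = f"{grp}{i}"
                scores.extend(_scores({cb: rng.exponential()}))
                labels[cb] = grp
        comps = pairwise_rank_test(scores, labels, Correction.BONFERRONI)
        assert len(comps) == 3
        assert all(c.adjusted_p >= c.p_value for c in comps)
        comps_bh = pairwise_rank_test(scores, labels, Correction.BH)
        assert all(c.adjusted_p >= c.p_value for c in comps_bh)

    def test_degenerate_group_skipped(self):
        scores = _scores({"a0": 1, "a1": 2, "b0": 3})
        labels = {"a0": "a", "a1": "a", "b0": "b"}
        assert pairwise_rank_test(scores, labels) == []
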