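import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from haircut.classify_eval import (
    Genotype,
    call_genotypes,
    centroid_classify,
    confusion,
    downsample_and_classify,
    random_baseline,
)
from haircut.umi_count import UmiEvent


class TestCallGenotypes:
    def test_uracil_only_cell_is_rnaseh2c_ko(self):
        calls = call_genotypes({"B1": 100, "B2": 0}, {"B1": 0, "B2": 100})
        by_cb = {c.cell_barcode: c.label for c in calls}
        assert by_cb["B1"] is Genotype.RNASEH2C_KO
        assert by_cb["B2"] is Genotype.UNG_KO

    def test_both_high_is_doublet(self):
        calls = call_genotypes({"B1": 100, "B2": 100}, {"B1": 100, "B2": 0})
        assert calls[0].label is Genotype.DOUBLET

    def test_both_low_is_unclassified(self):
        calls = call_genotypes({"B1": 100, "B2": 2}, {"B1": 100, "B2": 2})
        by_cb = {c.cell_barcode: c.label for c in calls}
        assert by_cb["B2"] is Genotype.UNCLASSIFIED

    def test_exact_threshold_boundary_falls_low(self):
        # 5 == 0.05 * 100 is not strictly greater: low side
        calls = call_genotypes({"B1": 100, "B2": 5}, {"B1": 0, "B2": 100})
        by_cb = {c.cell_barcode: c.label for c in calls}
        assert by_cb["B2"] is Genotype.UNG_KO  # uracil side counted low

    def test_zero_maximum_is_an_error(self):
        with pytest.raises(ValueError, match="zero maximum"):
            call_genotypes({"B1": 10}, {"B1": 0})

    def test_mismatched_cell_universe_rejected(self):
        with pytest.raises(ValueError):
            call_genotypes({"B1": 1}, {"B2": 1})

    @given(scale=st.integers(1, 1000))
    def test_scaling_counts_preserves_all_labels(self, scale):
        u = {"B1": 100, "B2": 0, "B3": 100, "B4": 2}
        r = {"B1": 0, "B2": 100, "B3": 100, "B4": 2}
        base = [c.label for c in call_genotypes(u, r)]
        scaled = [
            c.label for c in call_genotypes(
                {k: v * scale for k, v in u.items()},
                {k: v * scale for k, v in r.items()},
            )
        ]
        assert base == scaled

    def test_output_is_a_partition(self):
        rng = np.random.default_rng(0)
        cells = [f"B{i}" for i in range(200)]
        u = {cb: int(rng.integers(0, 100)) for cb in cells}
        r = {cb: int(rng.integers(0, 100)) for cb in cells}
        calls = call_genotypes(u, r)
        assert sorted(c.cell_barcode for c in calls) == sorted(cells)
        assert all(0 <= c.uracil_fraction_of_max <= 1 for c in calls)
        assert all(0 <= c.ribo_fraction_of_max <= 1 for c in calls)


class TestConfusion:
    def test_perfect_prediction(self):
        truth = {f"B{i}": ("x" if i < 5 else "y") for i in range(10)}
        evals = confusion(truth, truth)
        for ev in evals.values():
            assert ev.tpr == 1.0 and ev.fpr == 0.0

    def test_tpr_by_definition(self):
        truth = {f"B{i}": "x" for i in range(10)}
        pred = dict(truth)
        pred["B0"] = "other"
        ev = confusion(pred, truth)["x"]
        assert ev.tp == 9 and ev.fn == 1
        assert ev.tpr == 0.9
        assert ev.fpr is None  # no true negatives exist for a single class

    def test_against_brute_force_tally(self):
        rng = np.random.default_rng(7)
        cells = [f"B{i}" for i in range(100)]
        labels = ["x", "y", "z", "doublet"]
        truth = {cb: labels[rng.integers(0, 3)] for cb in cells}
        pred = {cb: labels[rng.integers(0, 4)] for cb in cells}
        evals = confusion(pred, truth)
        for cls, ev in evals.items():
            tp = sum(pred[c] == cls and truth[c] == cls for c in cells)
            fp = sum(pred[c] == cls and truth[c] != cls for c in cells)
            fn = sum(pred[c] != cls and truth[c] == cls for c in cells)
            tn = sum(pred[c] != cls and truth[c] != cls for c in cells)
            assert (ev.tp, ev.fp, ev.tn, ev.fn) == (tp, fp, tn, fn)
            assert ev.tp + ev.fp + ev.tn + ev.fn == len(cells)
            assert ev.tp + ev.fn == sum(v == cls for v in truth.values())


class TestRandomBaseline:
    def test_label_multiset_preserved_and_reproducible(self):
        truth = {f"B{i}": ("x" if i % 3 else "y") for i in range(30)}
        pred = random_baseline(truth, seed=5)
        assert sorted(pred.values()) == sorted(truth.values())
        assert pred == random_baseline(truth, seed=5)

    def test_expected_tpr_equals_class_frequency(self):
        """Permuting labels gives E[TPR] ~= class frequency (for class x at
        frequency 0.3, averaged over many seeds)."""
        truth = {f"B{i}": ("x" if i < 30 else "y") for i in range(100)}
        tprs = []
        for seed in range(500):
            ev = confusion(random_baseline(truth, seed), truth)["x"]
            tprs.append(ev.tpr)
        # analytic expectation for a label permutation: 30/100; MC err ~ 0.004
        assert np.mean(tprs) == pytest.approx(0.30, abs=0.02)


class TestCentroidClassify:
    def test_cell_at_centroid_recovers_class(self):
        train = np.array([[0, 0], [0, 2], [10, 10], [10, 12]], dtype=float)
        labels = ["lo", "lo", "hi", "hi"]
        assert centroid_classify(train, labels, np.array([[0.0, 1.0]])) == ["lo"]
        assert centroid_classify(train, labels, np.array([[10.0, 11.0]])) == ["hi"]

    def test_equidistant_cell_takes_lexicographic_first(self):
        train = np.array([[0.0], [2.0]])
        assert centroid_classify(train, ["b", "a"], np.array([[1.0]])) == ["a"]

    def test_separated_synthetic_populations_classified_accurately(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(200, 4))
        b = rng.normal(2.5, 1, size=(200, 4))
        train = np.vstack([a[:100], b[:100]])
        labels = ["a"] * 100 + ["b"] * 100
        test = np.vstack([a[100:], b[100:]])
        pred = centroid_classify(train, labels, test)
        truth = ["a"] * 100 + ["b"] * 100
        acc = np.mean([p == t for p, t in zip(pred, truth)])
        assert acc > 0.9

    def test_feature_space_mismatch_rejected(self):
        with pytest.raises(ValueError):
            centroid_classify(np.zeros((2, 3)), ["a", "b"], np.zeros((1, 2)))


def _toy_events(rng, cells_labels, reads_per_cell=60):
    """Read-level events: UNG_KO cells emit ribo-site reads, RNASEH2C_KO
    cells uracil-site reads, plus intact reads for both."""
    events = []
    for cb, label in cells_labels.items():
        active = ("riboG", 44) if label == "UNG_KO" else ("uracilA", 45)
        for i in range(reads_per_cell):
            umi = "".join(rng.choice(list("ACGT"), 8))
            if i % 2 == 0:
                events.append(UmiEvent(cb, active[0], active[1], umi))
            else:
                events.append(UmiEvent(cb, "uracilA", 1, umi))
    return events


class TestDownsampleAndClassify:
    def _run(self, targets, seed=9):
        rng = np.random.default_rng(1)
        truth = {
            f"B{i}": ("UNG_KO" if i % 2 else "RNASEH2C_KO") for i in range(40)
        }
        events = _toy_events(rng, truth)
        return downsample_and_classify(
            events, truth, targets, seed, ("uracilA", 45), ("riboG", 44)
        ), truth, events

    def test_target_above_depth_is_a_noop(self):
        table, truth, events = self._run([10_000])
        assert table.loc[0, "reads_used"] == len(events)
        assert table.loc[0, "fraction_correct"] == 1.0

    def test_same_seed_reproduces_table(self):
        t1, _, _ = self._run([5, 20, 10_000], seed=9)
        t2, _, _ = self._run([5, 20, 10_000], seed=9)
        assert t1.equals(t2)

    def test_fraction_correct_trend_with_depth(self):
        """Averaged over seeds, accuracy does not decrease with depth."""
        means = None
        tables = [self._run([2, 8, 10_000], seed=s)[0] for s in range(5)]
        means = np.mean([t["fraction_correct"].to_numpy() for t in tables], axis=0)
        assert all(means[i] <= means[i + 1] + 1e-12 for i in range(len(means) - 1))

    def test_non_positive_target_rejected(self):
        with pytest.raises(ValueError):
            self._run([0])
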