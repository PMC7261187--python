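"""Genotype calling, cell-type prediction and classification evaluation.

In the knockout cell-mixing experiment, a cell's genotype is read directly
from its repair phenotype: counts at the uracil incision site (lesion + 1)
and the ribonucleotide incision site (the lesion position) are compared to
5% of the respective per-activity maximum over all cells. One activity
high and the other low identifies the knockout lacking the *other*
pathway; both high flags a doublet; both low leaves the cell
unclassified. Evaluation uses one-vs-rest confusion counts, TPR/FPR, a
label-permutation baseline, a nearest-centroid classifier standing in for
reference-based label transfer, and read-level downsampling to probe how
much sequencing the classification needs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from haircut.umi_count import GroupMethod, UmiEvent, count_positions
from haircut.repair_matrix import build_matrix

__all__ = [
    "Genotype",
    "GenotypeCall",
    "ClassEval",
    "call_genotypes",
    "confusion",
    "random_baseline",
    "centroid_classify",
    "downsample_and_classify",
]


class Genotype(str, Enum):
    UNG_KO = "UNG_KO"
    RNASEH2C_KO = "RNASEH2C_KO"
    DOUBLET = "doublet"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GenotypeCall:
    cell_barcode: str
    label: Genotype
    uracil_site_count: int
    ribo_site_count: int
    uracil_fraction_of_max: float
    ribo_fraction_of_max: float


@dataclass(frozen=True)
class ClassEval:
    """One-vs-rest confusion counts and rates for a single class."""

    label: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def fpr(self) -> float | None:
        denom = self.fp + self.tn
        return self.fp / denom if denom else None


def call_genotypes(
    uracil_counts: Mapping[str, int],
    ribo_counts: Mapping[str, int],
    threshold: float = 0.05,
) -> list[GenotypeCall]:
    """Threshold raw incision-site counts against 5% of each activity's max.

    Uracil incision requires UNG, so a cell with uracil activity but no
    ribonucleotide activity is RNASEH2C_KO, and vice versa. The
    comparison is strict (> threshold * max is "high", otherwise "low":
    exact equality falls to the low side). Maxima are taken over all
    cells, doublets included. Raw counts are used, so scaling both count
    vectors by any positive constant leaves every label unchanged.
    """
    if set(uracil_counts) != set(ribo_counts):
        raise ValueError("uracil and ribo maps must cover the same cells")
    if not uracil_counts:
        raise ValueError("empty cell universe")
    max_u = max(uracil_counts.values())
    max_r = max(ribo_counts.values())
    if max_u <= 0 or max_r <= 0:
        raise ValueError(
            "degenerate experiment: an activity has zero maximum count"
        )
    calls = []
    for cb in sorted(uracil_counts):
        u, r = uracil_counts[cb], ribo_counts[cb]
        u_hi = u > threshold * max_u
        r_hi = r > threshold * max_r
        if u_hi and r_hi:
            label = Genotype.DOUBLET
        elif u_hi:
            label = Genotype.RNASEH2C_KO  # uracil repair intact, ribo absent
        elif r_hi:
            label = Genotype.UNG_KO
        else:
            label = Genotype.UNCLASSIFIED
        calls.append(GenotypeCall(cb, label, u, r, u / max_u, r / max_r))
    return calls


def confusion(
    pred: Mapping[str, str], truth: Mapping[str, str]
) -> dict[str, ClassEval]:
    """One-vs-rest confusion per true class.

    Predictions of classes outside the truth label set (doublet,
    unclassified, anything else) count as negative predictions for every
    true class.
    """
    if set(pred) != set(truth):
        raise ValueError("pred and truth must cover the same cells")
    classes = sorted(set(truth.values()))
    out: dict[str, ClassEval] = {}
    for cls in classes:
        tp = fp = tn = fn = 0
        for cb in truth:
            is_true = truth[cb] == cls
            is_pred = pred[cb] == cls
            if is_pred and is_true:
                tp += 1
            elif is_pred:
                fp += 1
            elif is_true:
                fn += 1
            else:
                tn += 1
        out[cls] = ClassEval(cls, tp, fp, tn, fn)
    return out


def random_baseline(truth: Mapping[str, str], seed: int) -> dict[str, str]:
    """Uniform random permutation of the existing labels across cells.

    Preserves the label multiset exactly; the expected one-vs-rest TPR of
    a class then equals (roughly, up to the without-replacement
    correction) its frequency.
    """
    if not truth:
        raise ValueError("empty truth mapping")
    rng = np.random.default_rng(seed)
    cells = sorted(truth)
    labels = [truth[cb] for cb in cells]
    perm = rng.permutation(len(labels))
    return {cb: labels[j] for cb, j in zip(cells, perm)}


def centroid_classify(
    train_matrix: np.ndarray,
    train_labels: Sequence[str],
    test_matrix: np.ndarray,
) -> list[str]:
    """Nearest-centroid prediction in a shared feature space.

    Per-class mean vectors are computed on the training matrix
    (normalized scores, typically); each test cell is assigned the class
    of the nearest centroid by Euclidean distance, ties broken by
    lexicographically first class. Classes without training cells are
    excluded. A plumbing stand-in for reference-based label transfer.
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    test_matrix = np.asarray(test_matrix, dtype=float)
    if train_matrix.shape[1] != test_matrix.shape[1]:
        raise ValueError("train and test matrices must share the feature space")
    if train_matrix.shape[0] != len(train_labels):
        raise ValueError("one label per training cell required")
    classes = sorted(set(train_labels))
    label_arr = np.asarray(train_labels)
    centroids = np.vstack([
        train_matrix[label_arr == cls].mean(axis=0) for cls in classes
    ])
    # squared distances; argmin returns the first (lexicographic) minimum
    d2 = ((test_matrix[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return [classes[j] for j in d2.argmin(axis=1)]


GenotypeClassifier = Callable[[Mapping[str, int], Mapping[str, int]], Mapping[str, str]]


def _default_classifier(
    uracil_counts: Mapping[str, int], ribo_counts: Mapping[str, int]
) -> dict[str, str]:
    return {
        c.cell_barcode: c.label.value
        for c in call_genotypes(uracil_counts, ribo_counts)
    }


def downsample_and_classify(
    events: Sequence[UmiEvent],
    truth: Mapping[str, str],
    reads_per_cell_targets: Sequence[int],
    seed: int,
    uracil_site: tuple[str, int],
    ribo_site: tuple[str, int],
    classifier: GenotypeClassifier | None = None,
    method: GroupMethod | str = GroupMethod.DIRECTIONAL,
) -> pd.DataFrame:
    """Read-level downsampling sensitivity of genotype classification.

    ``events`` are pre-deduplication read-level records (one per counted
    read). For each target depth, every cell's reads are sampled without
    replacement down to the target (cells with fewer reads keep them
    all), UMIs are re-deduplicated, site counts are rebuilt and cells are
    reclassified; the reported ``fraction_correct`` is the fraction of
    cells whose predicted label equals the truth. Seeded and
    reproducible; a target at or above the deepest cell reproduces the
    full-depth classification exactly.
    """
    if classifier is None:
        classifier = _default_classifier
    targets = list(reads_per_cell_targets)
    if any(t <= 0 for t in targets):
        raise ValueError("read-depth targets must be positive")
    by_cell: dict[str, list[UmiEvent]] = defaultdict(list)
    for ev in events:
        by_cell[ev.cell_barcode].append(ev)
    cells = sorted(truth)
    rng = np.random.default_rng(seed)
    rows = []
    for target in targets:
        sampled: list[UmiEvent] = []
        for cb in sorted(by_cell):
            evs = by_cell[cb]
            if len(evs) <= target:
                sampled.extend(evs)
            else:
                idx = rng.choice(len(evs), size=target, replace=False)
                sampled.extend(evs[i] for i in idx)
        counts = count_positions(sampled, method)
        matrix = build_matrix(counts, cells)
        u = dict(zip(cells, matrix.feature_counts(*uracil_site).astype(int)))
        r = dict(zip(cells, matrix.feature_counts(*ribo_site).astype(int)))
        pred = classifier(u, r)
        n_correct = sum(pred.get(cb) == truth[cb] for cb in cells)
        rows.append((target, len(sampled), n_correct / len(cells)))
    return pd.DataFrame(
        rows, columns=["reads_per_cell_target", "reads_used", "fraction_correct"]
    )
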