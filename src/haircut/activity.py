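"""Normalization, repair-activity scores and group comparisons.

A cell's repair activity on a substrate is the log-normalized molecule
count at the substrate's scored incision site: counts are divided by the
cell's total repair counts, scaled by 1e4 and transformed with ln(1 + x).
Group differences are assessed with two-sided Wilcoxon rank-sum
(Mann-Whitney U) tests over all pairwise group combinations, with
multiple-testing correction across every reported test.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from haircut.repair_matrix import RepairCountMatrix
from haircut.substrate_model import SubstrateSet

__all__ = [
    "ActivityScore",
    "Correction",
    "GroupComparison",
    "log_normalize",
    "activity_scores",
    "position_profile",
    "pairwise_rank_test",
]

DEFAULT_SCALE = 1e4


@dataclass(frozen=True)
class ActivityScore:
    """Per-cell activity at one scored incision site."""

    cell_barcode: str
    activity_name: str
    raw_count: int
    score: float

    def __post_init__(self) -> None:
        if self.raw_count < 0 or self.score < 0 or not np.isfinite(self.score):
            raise ValueError("raw_count and score must be finite and >= 0")


class Correction(str, Enum):
    BONFERRONI = "bonferroni"
    BH = "bh"


@dataclass(frozen=True)
class GroupComparison:
    """One pairwise rank test of an activity between two cell groups."""

    activity_name: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    adjusted_p: float
    log_fold_change: float


def log_normalize(matrix: RepairCountMatrix, scale: float = DEFAULT_SCALE) -> sp.csr_matrix:
    """ln(1 + count / cell_total * scale), per cell over all repair features.

    Cells with zero total counts keep an all-zero row. Zero counts map to
    zero, so sparsity is preserved.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    counts = matrix.counts.tocsr().astype(np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    inv = np.zeros_like(totals)
    nz = totals > 0
    inv[nz] = scale / totals[nz]
    out = sp.diags(inv) @ counts
    out.data = np.log1p(out.data)
    return sp.csr_matrix(out)


def _activity_map(substrates: SubstrateSet) -> dict[str, tuple[str, tuple[int, ...]]]:
    """Default activity naming: one activity per scored site, named
    "substrate:site". Multi-site activities (e.g. a combined long-patch
    window) can be passed explicitly to :func:`activity_scores`."""
    out: dict[str, tuple[str, tuple[int, ...]]] = {}
    for s in substrates:
        for site in s.scored_sites:
            out[f"{s.name}:{site}"] = (s.name, (site,))
    return out


def activity_scores(
    matrix: RepairCountMatrix,
    substrates: SubstrateSet,
    activities: Mapping[str, tuple[str, Sequence[int]]] | None = None,
    scale: float = DEFAULT_SCALE,
) -> list[ActivityScore]:
    """Per-cell activity scores at every scored site.

    ``activities`` maps an activity name to (substrate, positions); counts
    over the named positions are summed before normalization. Scored sites
    absent from the feature space contribute zero. The score is the
    log-normalized value of the summed raw count against the cell's total
    repair counts.
    """
    if activities is None:
        activities = _activity_map(substrates)
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    scores: list[ActivityScore] = []
    for name, (sub, sites) in activities.items():
        raw = np.zeros(len(matrix.cell_barcodes))
        for site in sites:
            raw += matrix.feature_counts(sub, site)
        with np.errstate(invalid="ignore"):
            norm = np.where(totals > 0, np.log1p(raw / np.maximum(totals, 1) * scale), 0.0)
        for i, cb in enumerate(matrix.cell_barcodes):
            scores.append(ActivityScore(cb, name, int(raw[i]), float(norm[i])))
    return scores


def scores_frame(scores: Sequence[ActivityScore]) -> pd.DataFrame:
    """Tidy DataFrame view of activity scores."""
    return pd.DataFrame(
        [(s.cell_barcode, s.activity_name, s.raw_count, s.score) for s in scores],
        columns=["cell_barcode", "activity_name", "raw_count", "score"],
    )


def position_profile(
    matrix: RepairCountMatrix, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group mean raw count at every (substrate, position).

    Every cell in the matrix must be labeled; zeros are included in the
    means, so for each group: mean * group_size summed over features equals
    the group's total counts. Empty groups cannot arise (labels come from
    the matrix's own cells).
    """
    missing = [cb for cb in matrix.cell_barcodes if cb not in labels]
    if missing:
        raise ValueError(f"{len(missing)} unlabeled cells, e.g. {missing[:3]}")
    rows = []
    groups = sorted({labels[cb] for cb in matrix.cell_barcodes})
    cell_groups = np.array([labels[cb] for cb in matrix.cell_barcodes])
    dense_cols = matrix.counts.tocsc()
    for grp in groups:
        mask = cell_groups == grp
        n = int(mask.sum())
        means = np.asarray(dense_cols[mask].mean(axis=0)).ravel()
        for (sub, pos), m in zip(matrix.features, means):
            rows.append((grp, sub, pos, float(m), n))
    return pd.DataFrame(
        rows, columns=["group", "substrate", "position", "mean_count", "n_cells"]
    )


def pairwise_rank_test(
    scores: Sequence[ActivityScore] | pd.DataFrame,
    labels: Mapping[str, str],
    correction: Correction | str = Correction.BONFERRONI,
    min_group_size: int = 2,
) -> list[GroupComparison]:
    """Two-sided Mann-Whitney U tests for every activity and group pair.

    Small untied samples get an exact p-value; otherwise the normal
    approximation with tie correction is used. The log fold change is the
    difference of group mean scores (scores are already on a log scale).
    Correction (Bonferroni by default, Benjamini-Hochberg optional) is
    applied across all reported tests. Groups below ``min_group_size``
    are skipped.
    """
    correction = Correction(correction)
    df = scores if isinstance(scores, pd.DataFrame) else scores_frame(scores)
    df = df[df["cell_barcode"].map(labels.__contains__)]
    df = df.assign(group=df["cell_barcode"].map(labels))
    results: list[tuple[str, str, str, float, float, float]] = []
    for activity, sub_df in df.groupby("activity_name", sort=True):
        by_group = {g: gdf["score"].to_numpy() for g, gdf in sub_df.groupby("group")}
        groups = sorted(g for g, v in by_group.items() if len(v) >= min_group_size)
        if len(groups) < 2:
            continue
        for ga, gb in combinations(groups, 2):
            a, b = by_group[ga], by_group[gb]
            stat, p = mannwhitneyu(a, b, alternative="two-sided", method="auto")
            lfc = float(np.mean(a) - np.mean(b))
            results.append((activity, ga, gb, float(stat), float(p), lfc))
    if not results:
        return []
    pvals = [r[4] for r in results]
    method = "bonferroni" if correction is Correction.BONFERRONI else "fdr_bh"
    _, adjusted, _, _ = multipletests(pvals, method=method)
    return [
        GroupComparison(act, ga, gb, stat, p, float(adj), lfc)
        for (act, ga, gb, stat, p, lfc), adj in zip(results, adjusted)
    ]
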