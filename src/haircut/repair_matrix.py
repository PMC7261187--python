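"""Sparse cells x (substrate:position) count matrices and empty-drop profiles.

The deduplicated position counts become a sparse matrix restricted to
cell-associated barcodes (the list produced by the mRNA pipeline, or a
rank-based fallback for purely synthetic runs). Barcodes outside that
list are droplets without a cell; their per-position mean signal is the
ambient background profile.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from haircut.umi_count import PositionCounts

__all__ = [
    "RepairCountMatrix",
    "BackgroundProfile",
    "build_matrix",
    "write_mtx",
    "read_mtx",
    "empty_drop_profile",
    "top_n_by_umi",
]


@dataclass
class RepairCountMatrix:
    """Sparse cells x features matrix; features are "substrate:position" pairs."""

    cell_barcodes: list[str]
    features: list[tuple[str, int]]
    counts: sp.csr_matrix  # cells x features

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        if self.counts.shape != (len(self.cell_barcodes), len(self.features)):
            raise ValueError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_barcodes)} barcodes x {len(self.features)} features"
            )
        if len(set(self.feature_ids)) != len(self.features):
            raise ValueError("duplicate feature identifiers")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise ValueError("duplicate cell barcodes")

    @property
    def feature_ids(self) -> list[str]:
        return [f"{sub}:{pos}" for sub, pos in self.features]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> float:
        return float(self.counts.sum())

    def row(self, barcode: str) -> np.ndarray:
        idx = self.cell_barcodes.index(barcode)
        return np.asarray(self.counts[idx].todense()).ravel()

    def feature_counts(self, substrate: str, position: int) -> np.ndarray:
        """Dense per-cell counts for one (substrate, position); zeros if absent."""
        try:
            j = self.features.index((substrate, position))
        except ValueError:
            return np.zeros(len(self.cell_barcodes))
        return np.asarray(self.counts[:, j].todense()).ravel()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RepairCountMatrix):
            return NotImplemented
        return (
            self.cell_barcodes == other.cell_barcodes
            and self.features == other.features
            and (self.counts != other.counts).nnz == 0
        )


@dataclass(frozen=True)
class BackgroundProfile:
    """Mean ambient count per hairpin position across retained empty drops."""

    substrate_name: str
    position_means: dict[int, float]
    n_drops: int


def build_matrix(counts: PositionCounts, cells: Sequence[str]) -> RepairCountMatrix:
    """Assemble the sparse matrix restricted to the given cell barcodes.

    Listed cells with no signal keep an all-zero row; features are the
    (substrate, position) keys observed among retained cells, sorted by
    substrate name then position. Deterministic under permutation of the
    input entries.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell list")
    if len(set(cells)) != len(cells):
        raise ValueError("cell barcodes must be unique")
    cell_idx = {cb: i for i, cb in enumerate(cells)}
    retained = {
        key: n for key, n in counts.entries.items() if key[0] in cell_idx
    }
    features = sorted({(sub, pos) for _, sub, pos in retained})
    feat_idx = {f: j for j, f in enumerate(features)}
    rows, cols, data = [], [], []
    for (cb, sub, pos), n in retained.items():
        rows.append(cell_idx[cb])
        cols.append(feat_idx[(sub, pos)])
        data.append(n)
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(cells), len(features)), dtype=np.int64
    )
    return RepairCountMatrix(cells, features, mat)


def write_mtx(matrix: RepairCountMatrix, outdir: str | Path) -> None:
    """Write a 10x-style triplet: matrix.mtx + barcodes.tsv + features.tsv.

    The MatrixMarket file stores features x cells (the droplet-pipeline
    convention); barcodes.tsv holds one barcode per line and features.tsv
    one ``substrate:position<TAB>substrate<TAB>position`` line per feature.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"), sp.coo_matrix(matrix.counts.T), field="integer"
    )
    with open(outdir / "barcodes.tsv", "w") as fh:
        for cb in matrix.cell_barcodes:
            fh.write(cb + "\n")
    with open(outdir / "features.tsv", "w") as fh:
        for sub, pos in matrix.features:
            fh.write(f"{sub}:{pos}\t{sub}\t{pos}\n")


def read_mtx(outdir: str | Path) -> RepairCountMatrix:
    """Read a matrix written by :func:`write_mtx`; validates labels/shape."""
    outdir = Path(outdir)
    mat = sp.csr_matrix(scipy.io.mmread(str(outdir / "matrix.mtx"))).T
    with open(outdir / "barcodes.tsv") as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    features: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(outdir / "features.tsv") as fh:
        for line in fh:
            fid, sub, pos = line.rstrip("\n").split("\t")
            if fid in seen:
                raise ValueError(f"{outdir}/features.tsv: duplicate feature {fid!r}")
            seen.add(fid)
            features.append((sub, int(pos)))
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"{outdir}: matrix shape {mat.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features"
        )
    return RepairCountMatrix(barcodes, features, mat.astype(np.int64))


def top_n_by_umi(counts: PositionCounts, n: int) -> list[str]:
    """Rank barcodes by total molecule count (descending, ties lexicographic)
    and return the top ``n``. A plumbing fallback cell caller for purely
    synthetic runs; real runs take the mRNA pipeline's cell list.
    """
    totals: dict[str, int] = defaultdict(int)
    for (cb, _, _), c in counts.entries.items():
        totals[cb] += c
    ranked = sorted(totals, key=lambda cb: (-totals[cb], cb))
    return ranked[:n]


def empty_drop_profile(
    counts: PositionCounts,
    cells: Sequence[str],
    n_keep: int | str = "match_cells",
) -> list[BackgroundProfile]:
    """Ambient background: per-position mean count over retained empty drops.

    Barcodes absent from ``cells`` are ranked by total molecule count
    (descending, ties lexicographic); the top ``n_keep`` (default: as many
    as there are cell-associated barcodes) are retained. Per substrate,
    the mean count at each observed position is taken across all retained
    drops, counting absent entries as zero.
    """
    cell_set = set(cells)
    totals: dict[str, int] = defaultdict(int)
    for (cb, _, _), c in counts.entries.items():
        if cb not in cell_set:
            totals[cb] += c
    if not totals:
        raise ValueError("no non-cell barcodes present")
    if n_keep == "match_cells":
        n_keep = len(cells)
    if not isinstance(n_keep, int) or n_keep < 1:
        raise ValueError(f"invalid n_keep: {n_keep!r}")
    retained = set(sorted(totals, key=lambda cb: (-totals[cb], cb))[:n_keep])
    n_drops = len(retained)

    sums: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for (cb, sub, pos), c in counts.entries.items():
        if cb in retained:
            sums[sub][pos] += c
    return [
        BackgroundProfile(
            substrate_name=sub,
            position_means={pos: total / n_drops for pos, total in sorted(by_pos.items())},
            n_drops=n_drops,
        )
        for sub, by_pos in sorted(sums.items())
    ]


def write_background_tsv(
    profiles: Sequence[BackgroundProfile], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("substrate\tposition\tmean\tn_drops\n")
        for prof in profiles:
            for pos, mean in sorted(prof.position_means.items()):
                fh.write(f"{prof.substrate_name}\t{pos}\t{mean:.6g}\t{prof.n_drops}\n")
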