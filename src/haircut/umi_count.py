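"""UMI deduplication and per-(cell, substrate, position) molecule counting.

PCR amplifies each captured molecule into many reads; the UMI collapses
them back. The directional method additionally absorbs UMIs one
substitution away from a much more abundant neighbor (sequencing-error
children), using the adjacency criterion count(parent) >= 2*count(child)-1.
Grouping is stratified per (cell barcode, substrate, hairpin position):
counts at different incision positions are distinct measurements and are
never merged.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GroupMethod",
    "UmiEvent",
    "UmiCluster",
    "PositionCounts",
    "group_umis",
    "count_positions",
]


class GroupMethod(str, Enum):
    UNIQUE = "unique"
    DIRECTIONAL = "directional"


@dataclass(frozen=True)
class UmiEvent:
    """One read assigned to a (cell, substrate, position) stratum."""

    cell_barcode: str
    substrate_name: str
    position: int
    umi: str
    read_support: int = 1

    def __post_init__(self) -> None:
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")


@dataclass(frozen=True)
class UmiCluster:
    """A deduplicated molecule: member UMIs and the highest-count representative."""

    representative: str
    members: tuple[str, ...]
    total_reads: int


Stratum = tuple[str, str, int]  # (cell_barcode, substrate_name, position)


class PositionCounts:
    """Mapping (cell, substrate, position) -> deduplicated molecule count."""

    def __init__(self, entries: Mapping[Stratum, int]):
        for key, count in entries.items():
            if count < 1:
                raise ValueError(f"non-positive count for stratum {key}")
        self.entries: dict[Stratum, int] = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionCounts):
            return NotImplemented
        return self.entries == other.entries

    def total(self) -> int:
        return sum(self.entries.values())

    def barcodes(self) -> set[str]:
        return {cb for cb, _, _ in self.entries}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cell_barcode\tsubstrate\tposition\tcount\n")
            for (cb, sub, pos) in sorted(self.entries):
                fh.write(f"{cb}\t{sub}\t{pos}\t{self.entries[(cb, sub, pos)]}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PositionCounts":
        entries: dict[Stratum, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("cell_barcode"):
                raise ValueError(f"{path}: unexpected header {header!r}")
            for line in fh:
                cb, sub, pos, count = line.rstrip("\n").split("\t")
                entries[(cb, sub, int(pos))] = int(count)
        return cls(entries)


def _hamming1_neighbors_in(umi: str, universe: Mapping[str, int]) -> list[str]:
    """UMIs in ``universe`` exactly one substitution from ``umi``."""
    hits = []
    for i, orig in enumerate(umi):
        for base in "ACGTN":
            if base == orig:
                continue
            cand = umi[:i] + base + umi[i + 1:]
            if cand in universe:
                hits.append(cand)
    return hits


def group_umis(
    umis: Mapping[str, int], method: GroupMethod | str = GroupMethod.DIRECTIONAL
) -> list[UmiCluster]:
    """Cluster a stratum's UMIs into molecules.

    ``unique``: every distinct UMI is its own molecule. ``directional``:
    a directed edge a -> b exists when Hamming(a, b) == 1 and
    count(a) >= 2*count(b) - 1; clusters are the nodes reachable (along
    such edges, transitively) from unvisited roots, with roots taken in
    descending count order, ties broken lexicographically. The tie-break
    makes clustering independent of input order.
    """
    method = GroupMethod(method)
    if not umis:
        raise ValueError("empty UMI mapping")
    lengths = {len(u) for u in umis}
    if len(lengths) != 1:
        raise ValueError(f"mixed UMI lengths in one stratum: {sorted(lengths)}")
    if method is GroupMethod.UNIQUE:
        return [UmiCluster(u, (u,), c) for u, c in sorted(umis.items())]

    order = sorted(umis, key=lambda u: (-umis[u], u))
    visited: set[str] = set()
    clusters: list[UmiCluster] = []
    for root in order:
        if root in visited:
            continue
        members = []
        queue = deque([root])
        visited.add(root)
        while queue:
            node = queue.popleft()
            members.append(node)
            for nb in _hamming1_neighbors_in(node, umis):
                if nb not in visited and umis[node] >= 2 * umis[nb] - 1:
                    visited.add(nb)
                    queue.append(nb)
        members.sort(key=lambda u: (-umis[u], u))
        clusters.append(UmiCluster(
            representative=members[0],
            members=tuple(members),
            total_reads=sum(umis[m] for m in members),
        ))
    return clusters


def count_positions(
    events: Iterable[UmiEvent],
    method: GroupMethod | str = GroupMethod.DIRECTIONAL,
) -> PositionCounts:
    """Deduplicate UMIs within each stratum and count molecules.

    Events must carry corrected cell barcodes. Strata are independent: the
    same UMI observed at two positions of one substrate yields two
    molecules (no cross-position merging).
    """
    strata: dict[Stratum, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for ev in events:
        strata[(ev.cell_barcode, ev.substrate_name, ev.position)][ev.umi] += \
            ev.read_support
    entries = {
        key: len(group_umis(umis, method)) for key, umis in strata.items()
    }
    return PositionCounts(entries)
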