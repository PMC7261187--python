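"""Ungapped end-anchored placement of trimmed reads on hairpin references.

The incision readout is the 1-based reference position of the read's 5'
end, so alignment is deliberately simple and exact: the read is slid over
every forward-strand offset of every reference at which it is fully
contained, mismatches are counted, and the unique minimum under the
mismatch budget wins. Hairpin references are ~50-100 nt synthetic
sequences; indels would corrupt the positional signal and are not
modeled. Reverse-complement placements are never considered — the assay
reads the substrate in one orientation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from haircut.read_processing import BarcodeCall
from haircut.substrate_model import SubstrateSet

__all__ = [
    "AlignmentStatus",
    "HairpinAlignment",
    "HairpinAligner",
    "align_read",
    "write_tagged_sam",
    "read_tagged_sam",
]


class AlignmentStatus(str, Enum):
    ALIGNED = "aligned"
    UNALIGNED = "unaligned"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class HairpinAlignment:
    """A unique forward-strand placement of a read on a hairpin reference."""

    substrate_name: str
    start_position: int  # 1-based 5' end on the reference
    mismatches: int
    aligned_length: int


_BASE_CODE = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _BASE_CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class HairpinAligner:
    """Exhaustive forward-strand Hamming aligner over a substrate set.

    For each reference the read is compared against every window of its
    own length (vectorized over offsets); the best placement across all
    references is reported if it is unique and within ``max_mismatches``.
    Results are memoized per read sequence — amplified libraries repeat
    sequences heavily.
    """

    def __init__(self, refs: SubstrateSet, max_mismatches: int = 2):
        if len(refs) == 0:
            raise ValueError("empty SubstrateSet")
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        self.max_mismatches = max_mismatches
        self._names = refs.names
        self._encoded = {s.name: _encode(s.sequence) for s in refs}
        self._cache: dict[str, HairpinAlignment | AlignmentStatus] = {}

    def align(self, sequence: str) -> HairpinAlignment | AlignmentStatus:
        """Place one read; returns an alignment or UNALIGNED/AMBIGUOUS."""
        hit = self._cache.get(sequence)
        if hit is None:
            hit = self._align_uncached(sequence)
            self._cache[sequence] = hit
        return hit

    def _align_uncached(self, sequence: str) -> HairpinAlignment | AlignmentStatus:
        read = _encode(sequence)
        L = len(read)
        if L == 0:
            return AlignmentStatus.UNALIGNED
        best = self.max_mismatches + 1
        best_hits: list[tuple[str, int]] = []
        for name in self._names:
            ref = self._encoded[name]
            if L > len(ref):
                continue  # read must be fully contained in the reference
            windows = np.lib.stride_tricks.sliding_window_view(ref, L)
            mm = (windows != read).sum(axis=1)
            local_best = int(mm.min())
            if local_best > best:
                continue
            if local_best < best:
                best = local_best
                best_hits = []
            if best <= self.max_mismatches:
                for off in np.flatnonzero(mm == best):
                    best_hits.append((name, int(off) + 1))
        if best > self.max_mismatches:
            return AlignmentStatus.UNALIGNED
        if len(best_hits) > 1:
            return AlignmentStatus.AMBIGUOUS
        name, pos = best_hits[0]
        return HairpinAlignment(name, pos, best, L)


def align_read(
    trimmed, refs: SubstrateSet, max_mismatches: int = 2
) -> HairpinAlignment | AlignmentStatus:
    """One-shot alignment of a trimmed read (see :class:`HairpinAligner`).

    ``trimmed`` may be a :class:`~haircut.read_processing.TrimmedRead` or a
    plain sequence string.
    """
    seq = trimmed if isinstance(trimmed, str) else trimmed.sequence
    return HairpinAligner(refs, max_mismatches).align(seq)


def write_tagged_sam(
    alignments: Sequence[HairpinAlignment],
    barcode_calls: Sequence[BarcodeCall],
    refs: SubstrateSet,
    path: str | Path,
) -> None:
    """Write aligned reads as a SAM file with XT/CB/UB tags.

    XT carries "substrate:position" (the per-read incision readout), CB
    the corrected cell barcode and UB the UMI. Only aligned records are
    written; unaligned/ambiguous reads are tallied upstream.
    """
    if len(alignments) != len(barcode_calls):
        raise ValueError("alignments and barcode_calls must pair up")
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": s.name, "LN": len(s.sequence)} for s in refs],
    }
    tid = {s.name: i for i, s in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (aln, call) in enumerate(zip(alignments, barcode_calls)):
            ref_seq = refs[aln.substrate_name].sequence
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"read{i}"
            rec.reference_id = tid[aln.substrate_name]
            rec.reference_start = aln.start_position - 1  # SAM is 0-based here
            rec.mapping_quality = 255
            rec.cigarstring = f"{aln.aligned_length}M"
            rec.query_sequence = ref_seq[
                aln.start_position - 1: aln.start_position - 1 + aln.aligned_length
            ]
            rec.set_tag("XT", f"{aln.substrate_name}:{aln.start_position}")
            if call.corrected_barcode is not None:
                rec.set_tag("CB", call.corrected_barcode)
            rec.set_tag("UB", call.umi)
            rec.set_tag("NM", aln.mismatches)
            out.write(rec)


def read_tagged_sam(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Parse a tagged SAM back into (substrate, position, barcode, umi) tuples."""
    out = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            out.append((
                rec.reference_name,
                rec.reference_start + 1,
                rec.get_tag("CB") if rec.has_tag("CB") else "",
                rec.get_tag("UB") if rec.has_tag("UB") else "",
            ))
    return out
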