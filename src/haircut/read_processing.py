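"""Barcode/UMI extraction from R1 and TSO/polyA trimming of R2.

R1 carries the droplet cell barcode (16 nt) followed by the UMI (10 nt) in
the 10x 3' v2 layout. R2 is the substrate-derived cDNA read: an optional
template-switch oligo (TSO) remnant at the 5' end, the hairpin body whose
first base marks the incision position, and the polyA tail at the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "BarcodeStatus",
    "BarcodeCall",
    "TrimmedRead",
    "DEFAULT_TSO",
    "extract_barcode_umi",
    "correct_barcode",
    "BarcodeCorrector",
    "trim_read2",
    "load_whitelist",
]

# 3'-most 13 nt of the canonical 10x template-switch oligo
# (AAGCAGTGGTATCAACGCAGAGTACATGGG): the portion appended to the cDNA 5'
# end by template switching and therefore seen at the start of R2.
DEFAULT_TSO = "CAGAGTACATGGG"

BARCODE_LEN = 16
UMI_LEN = 10


class BarcodeStatus(str, Enum):
    EXACT = "exact"
    CORRECTED = "corrected"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class BarcodeCall:
    """Result of matching a raw cell barcode against the whitelist."""

    raw_barcode: str
    corrected_barcode: str | None
    umi: str
    status: BarcodeStatus

    def __post_init__(self) -> None:
        if self.status is BarcodeStatus.UNMATCHED:
            if self.corrected_barcode is not None:
                raise ValueError("unmatched call cannot carry a corrected barcode")
        else:
            if self.corrected_barcode is None:
                raise ValueError("matched call must carry a corrected barcode")
            if self.status is BarcodeStatus.EXACT and \
                    self.corrected_barcode != self.raw_barcode:
                raise ValueError("exact call must keep the raw barcode")


@dataclass(frozen=True)
class TrimmedRead:
    """R2 after TSO and polyA removal."""

    sequence: str
    qualities: str
    tso_trimmed: int
    polya_trimmed: int

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")
        if self.tso_trimmed < 0 or self.polya_trimmed < 0:
            raise ValueError("trimmed lengths must be >= 0")


def extract_barcode_umi(
    r1_sequence: str, barcode_len: int = BARCODE_LEN, umi_len: int = UMI_LEN
) -> tuple[str, str] | None:
    """Slice the cell barcode and UMI from an R1 sequence.

    Returns ``None`` for reads shorter than ``barcode_len + umi_len``
    (the caller tallies these); trailing bases beyond the UMI are ignored.
    """
    if len(r1_sequence) < barcode_len + umi_len:
        return None
    return r1_sequence[:barcode_len], r1_sequence[barcode_len:barcode_len + umi_len]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class BarcodeCorrector:
    """Whitelist matcher: exact hit, else unique Hamming-1 neighbor.

    Candidate neighbors are generated from the raw barcode (3L variants for
    length L) and looked up in the whitelist set, so correction cost is
    independent of whitelist size. Results are memoized: droplet data
    repeats each barcode thousands of times.
    """

    def __init__(self, whitelist: set[str] | frozenset[str]):
        if not whitelist:
            raise ValueError("whitelist must be non-empty")
        lengths = {len(b) for b in whitelist}
        if len(lengths) != 1:
            raise ValueError("whitelist barcodes must share one length")
        self._whitelist = frozenset(whitelist)
        self._length = lengths.pop()
        self._cache: dict[str, BarcodeCall] = {}

    def __call__(self, raw: str, umi: str = "") -> BarcodeCall:
        cached = self._cache.get(raw)
        if cached is not None:
            return BarcodeCall(raw, cached.corrected_barcode, umi, cached.status)
        call = self._correct(raw, umi)
        self._cache[raw] = call
        return call

    def _correct(self, raw: str, umi: str) -> BarcodeCall:
        if len(raw) != self._length:
            raise ValueError(
                f"barcode length {len(raw)} != whitelist length {self._length}"
            )
        if raw in self._whitelist:
            return BarcodeCall(raw, raw, umi, BarcodeStatus.EXACT)
        hits = []
        for i, orig in enumerate(raw):
            for base in "ACGT":
                if base == orig:
                    continue
                candidate = raw[:i] + base + raw[i + 1:]
                if candidate in self._whitelist:
                    hits.append(candidate)
                    if len(hits) > 1:
                        return BarcodeCall(raw, None, umi, BarcodeStatus.UNMATCHED)
        if len(hits) == 1:
            return BarcodeCall(raw, hits[0], umi, BarcodeStatus.CORRECTED)
        return BarcodeCall(raw, None, umi, BarcodeStatus.UNMATCHED)


def correct_barcode(raw: str, whitelist: set[str], umi: str = "") -> BarcodeCall:
    """One-shot barcode correction (see :class:`BarcodeCorrector`)."""
    return BarcodeCorrector(whitelist)(raw, umi)


def _polya_suffix_length(
    seq: str, min_run: int, max_non_a_frac: float
) -> int:
    """Length of the maximal 3' suffix with >= (1 - max_non_a_frac) A content.

    Scans right-to-left; the A fraction may dip and recover, so the whole
    read is examined and the longest qualifying suffix wins. A qualifying
    suffix must begin with an A (the tolerance absorbs errors inside the
    tail, not trailing read bases ahead of it) and be at least
    ``min_run`` long.
    """
    if not seq:
        return 0
    is_a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[::-1] == ord("A")
    n_a = np.cumsum(is_a)
    k = np.arange(1, len(seq) + 1)
    ok = (k >= min_run) & ((k - n_a) <= max_non_a_frac * k) & is_a
    return int(k[ok].max()) if ok.any() else 0


def trim_read2(
    seq: str,
    quals: str,
    tso: str = DEFAULT_TSO,
    min_polya_run: int = 6,
    polya_max_non_a_frac: float = 0.1,
    min_len: int = 20,
) -> TrimmedRead | None:
    """Trim the 5' TSO remnant and 3' polyA tail from R2.

    The TSO is removed when the read's full-length prefix matches it with
    at most one mismatch. The polyA tail is the longest 3' suffix of at
    least ``min_polya_run`` bases whose non-A fraction is at most
    ``polya_max_non_a_frac``. Returns ``None`` (caller tallies a discard)
    when fewer than ``min_len`` bases remain — too short for a unique
    hairpin placement.
    """
    if len(seq) != len(quals):
        raise ValueError("sequence/quality length mismatch")
    tso_trimmed = 0
    if tso and len(seq) >= len(tso) and _hamming(seq[: len(tso)], tso) <= 1:
        tso_trimmed = len(tso)
        seq = seq[tso_trimmed:]
        quals = quals[tso_trimmed:]
    polya_trimmed = _polya_suffix_length(seq, min_polya_run, polya_max_non_a_frac)
    if polya_trimmed:
        seq = seq[:-polya_trimmed]
        quals = quals[:-polya_trimmed]
    if len(seq) < min_len:
        return None
    return TrimmedRead(seq, quals, tso_trimmed, polya_trimmed)


def load_whitelist(path: str | Path) -> frozenset[str]:
    """Read a one-barcode-per-line whitelist file."""
    with open(path) as fh:
        barcodes = frozenset(line.strip() for line in fh if line.strip())
    if not barcodes:
        raise ValueError(f"{path}: empty whitelist")
    return barcodes
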