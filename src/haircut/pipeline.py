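"""End-to-end processing: FASTQ pairs to deduplicated count matrix.

Chains extraction (barcode/UMI from R1), whitelist correction, R2
trimming, hairpin alignment, UMI deduplication and matrix assembly,
keeping a strict accounting: every input read pair lands in exactly one
QC category, so the tallies always sum to the input count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from haircut import __version__
from haircut.hairpin_align import (
    AlignmentStatus,
    HairpinAligner,
    HairpinAlignment,
    write_tagged_sam,
)
from haircut.read_processing import (
    BarcodeCall,
    BarcodeCorrector,
    BarcodeStatus,
    DEFAULT_TSO,
    extract_barcode_umi,
    load_whitelist,
    trim_read2,
)
from haircut.repair_matrix import (
    RepairCountMatrix,
    build_matrix,
    top_n_by_umi,
    write_mtx,
)
from haircut.substrate_model import SubstrateSet, load_substrate_table
from haircut.umi_count import GroupMethod, PositionCounts, UmiEvent, count_positions

__all__ = ["PipelineParams", "PipelineResult", "process_read_pairs", "run_count"]

_UNSEEN = object()

QC_CATEGORIES = (
    "counted",
    "excluded_short_r1",
    "umi_contains_n",
    "unmatched_barcode",
    "discarded_short_r2",
    "unaligned",
    "ambiguous",
)


@dataclass(frozen=True)
class PipelineParams:
    """Tunables for the processing chain (defaults documented per module)."""

    barcode_len: int = 16
    umi_len: int = 10
    tso: str = DEFAULT_TSO
    min_polya_run: int = 6
    polya_max_non_a_frac: float = 0.1
    min_len: int = 20
    max_mismatches: int = 2
    umi_method: GroupMethod = GroupMethod.DIRECTIONAL


@dataclass
class PipelineResult:
    """Everything the chain produces, kept for downstream evaluation."""

    events: list[UmiEvent]          # read-level (pre-dedup) counted records
    counts: PositionCounts          # deduplicated molecule counts, all barcodes
    matrix: RepairCountMatrix       # restricted to the cell list
    cells: list[str]
    qc: dict[str, int]
    alignments: list[HairpinAlignment]
    barcode_calls: list[BarcodeCall]


def _iter_pairs(r1_path: str | Path, r2_path: str | Path):
    with pysam.FastxFile(str(r1_path)) as r1, pysam.FastxFile(str(r2_path)) as r2:
        for rec1, rec2 in zip(r1, r2):
            yield rec1.sequence, rec2.sequence, rec2.quality or "I" * len(rec2.sequence)


def process_read_pairs(
    pairs: Iterable[tuple[str, str, str]],
    whitelist: frozenset[str] | set[str],
    substrates: SubstrateSet,
    cells: Sequence[str] | None = None,
    top_n_cells: int | None = None,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Run the full chain over (r1_seq, r2_seq, r2_qual) tuples.

    ``cells`` restricts the matrix to a known cell-barcode list (the mRNA
    pipeline's filtered barcodes); when absent, the ``top_n_cells``
    highest-total barcodes stand in (synthetic-run plumbing).
    """
    corrector = BarcodeCorrector(whitelist)
    aligner = HairpinAligner(substrates, params.max_mismatches)
    trim_cache: dict[str, object] = {}
    qc = {k: 0 for k in QC_CATEGORIES}
    events: list[UmiEvent] = []
    alignments: list[HairpinAlignment] = []
    barcode_calls: list[BarcodeCall] = []

    for r1_seq, r2_seq, r2_qual in pairs:
        extracted = extract_barcode_umi(r1_seq, params.barcode_len, params.umi_len)
        if extracted is None:
            qc["excluded_short_r1"] += 1
            continue
        raw_bc, umi = extracted
        if "N" in umi:
            qc["umi_contains_n"] += 1
            continue
        call = corrector(raw_bc, umi)
        if call.status is BarcodeStatus.UNMATCHED:
            qc["unmatched_barcode"] += 1
            continue
        trimmed = trim_cache.get(r2_seq, _UNSEEN)
        if trimmed is _UNSEEN:
            trimmed = trim_read2(
                r2_seq, r2_qual, params.tso, params.min_polya_run,
                params.polya_max_non_a_frac, params.min_len,
            )
            trim_cache[r2_seq] = trimmed
        if trimmed is None:
            qc["discarded_short_r2"] += 1
            continue
        hit = aligner.align(trimmed.sequence)
        if hit is AlignmentStatus.UNALIGNED:
            qc["unaligned"] += 1
            continue
        if hit is AlignmentStatus.AMBIGUOUS:
            qc["ambiguous"] += 1
            continue
        qc["counted"] += 1
        events.append(UmiEvent(
            call.corrected_barcode, hit.substrate_name, hit.start_position, umi
        ))
        alignments.append(hit)
        barcode_calls.append(call)

    counts = count_positions(events, params.umi_method) if events else \
        PositionCounts({})
    if cells is None:
        if top_n_cells is None:
            raise ValueError("either cells or top_n_cells must be given")
        cells = top_n_by_umi(counts, top_n_cells)
    matrix = build_matrix(counts, list(cells))
    return PipelineResult(
        events=events,
        counts=counts,
        matrix=matrix,
        cells=list(cells),
        qc=qc,
        alignments=alignments,
        barcode_calls=barcode_calls,
    )


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for a command-line ``count`` run."""

    r1: Path
    r2: Path
    whitelist: Path
    substrate_table: Path
    outdir: Path
    cells: Path | None = None
    top_n_cells: int | None = None
    params: PipelineParams = PipelineParams()
    seed: int | None = None
    write_sam: bool = True

    def validate(self) -> None:
        for attr in ("r1", "r2", "whitelist", "substrate_table"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if self.cells is not None and not Path(self.cells).exists():
            raise FileNotFoundError(f"cells: {self.cells} does not exist")
        if self.cells is None and self.top_n_cells is None:
            raise ValueError("provide a cell list or top_n_cells")


def run_count(cfg: RunConfig) -> PipelineResult:
    """Execute the full chain and write matrix + SAM + QC JSON + manifest.

    Output is a function of inputs and parameters only; rerunning on the
    same inputs reproduces byte-identical matrix files.
    """
    cfg.validate()
    whitelist = load_whitelist(cfg.whitelist)
    substrates = load_substrate_table(cfg.substrate_table)
    cells = None
    if cfg.cells is not None:
        with open(cfg.cells) as fh:
            cells = [line.strip() for line in fh if line.strip()]
    result = process_read_pairs(
        _iter_pairs(cfg.r1, cfg.r2), whitelist, substrates,
        cells=cells, top_n_cells=cfg.top_n_cells, params=cfg.params,
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx(result.matrix, outdir / "matrix")
    result.counts.write_tsv(outdir / "counts.tsv")
    if cfg.write_sam:
        write_tagged_sam(
            result.alignments, result.barcode_calls, substrates,
            outdir / "alignments.sam",
        )
    with open(outdir / "qc.json", "w") as fh:
        json.dump(result.qc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "version": __version__,
        "inputs": {
            "r1": str(cfg.r1), "r2": str(cfg.r2),
            "whitelist": str(cfg.whitelist),
            "substrate_table": str(cfg.substrate_table),
            "cells": str(cfg.cells) if cfg.cells else None,
        },
        "parameters": {
            "barcode_len": cfg.params.barcode_len,
            "umi_len": cfg.params.umi_len,
            "tso": cfg.params.tso,
            "min_polya_run": cfg.params.min_polya_run,
            "polya_max_non_a_frac": cfg.params.polya_max_non_a_frac,
            "min_len": cfg.params.min_len,
            "max_mismatches": cfg.params.max_mismatches,
            "umi_method": cfg.params.umi_method.value,
            "top_n_cells": cfg.top_n_cells,
        },
        "seed": cfg.seed,
        "qc": result.qc,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
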