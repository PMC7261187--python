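"""Seeded generator of synthetic Haircut experiments.

Emulates the assay end to end: droplets with genotype-dependent incision
position distributions over hairpin coordinates, intact (uncleaved)
substrates appearing as position-1 reads, empty-drop ambient background,
UMI duplication with geometric read multiplicity, and per-base
substitution error — emitting paired FASTQ (R1 = barcode + UMI, R2 =
optional TSO + hairpin body + polyA) plus complete per-read and per-cell
ground truth. A single seeded generator stream drives every draw in a
fixed documented order (whitelist, barcodes, doublet pairing, molecules,
read multiplicities, errors, final read shuffle), so output is
byte-identical for a given configuration and seed.

The incision distributions are simulator parameters chosen to reproduce
the *structure* of real data (a dominant incision site, downstream
processing signal, an intact fraction), not estimates of any particular
cell type's repair efficiency.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from haircut.read_processing import DEFAULT_TSO
from haircut.substrate_model import SubstrateSet, example_substrate_set

__all__ = [
    "CellProfile",
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "make_mixing_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CellProfile:
    """Incision behaviour of one cell population.

    ``incision_distributions`` maps substrate name -> {1-based position ->
    probability}; mass at position 1 is the intact (uncleaved) fraction,
    since reverse transcription of an unincised hairpin runs to the
    substrate's 5' end. ``umis_per_substrate`` is the Poisson mean number
    of captured molecules per substrate per droplet.
    """

    label: str
    incision_distributions: Mapping[str, Mapping[int, float]]
    umis_per_substrate: float

    def __post_init__(self) -> None:
        if self.umis_per_substrate < 0:
            raise ValueError("umis_per_substrate must be >= 0")
        for sub, dist in self.incision_distributions.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"profile {self.label!r}, substrate {sub!r}: "
                    f"position probabilities sum to {total}, not 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ValueError("negative position probability")


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one synthetic experiment."""

    substrates: SubstrateSet
    profiles: tuple[tuple[CellProfile, int], ...]  # (profile, n_cells)
    seed: int
    n_empty_drops: int = 0
    background_molecules: float = 0.0  # Poisson mean per substrate per empty drop
    background_intact_fraction: float = 0.9
    doublet_rate: float = 0.0
    reads_per_umi: float = 2.0  # geometric mean, support >= 1
    error_rate: float = 0.001  # per-base substitution probability
    tso_prob: float = 0.5      # fraction of R2 reads carrying the TSO remnant
    tso: str = DEFAULT_TSO
    umi_len: int = 10
    barcode_len: int = 16
    whitelist_size: int = 4000

    def __post_init__(self) -> None:
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ValueError("doublet_rate must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.reads_per_umi < 1.0:
            raise ValueError("reads_per_umi mean must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for profile, n in self.profiles:
            if n < 0:
                raise ValueError("negative cell count")
            for sub in profile.incision_distributions:
                if sub not in self.substrates:
                    raise ValueError(f"profile references unknown substrate {sub!r}")

    @property
    def n_cells(self) -> int:
        n_singlets = sum(n for _, n in self.profiles)
        return n_singlets + int(round(self.doublet_rate * n_singlets))


@dataclass
class SimTruth:
    """Ground truth for a simulated experiment.

    ``cells`` has one row per droplet barcode (cells and empty drops)
    with its label; ``molecule_counts`` maps (barcode, substrate,
    position) to the number of distinct captured molecules;
    ``reads`` has one row per sequenced read pair.
    """

    cells: pd.DataFrame          # columns: barcode, label
    molecule_counts: dict[tuple[str, str, int], int]
    reads: pd.DataFrame          # columns: read_id, barcode, umi, substrate, position
    whitelist: frozenset[str]

    def cell_labels(self) -> dict[str, str]:
        return dict(zip(self.cells["barcode"], self.cells["label"]))

    def cell_barcodes(self) -> list[str]:
        mask = self.cells["label"] != "empty"
        return list(self.cells.loc[mask, "barcode"])


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """n distinct random DNA k-mers."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), k))
        for row in _BASES[block]:
            kmer = row.tobytes().decode("ascii")
            if kmer not in seen:
                seen.add(kmer)
                out.append(kmer)
    return out


def _apply_errors(
    rng: np.random.Generator, seqs: list[str], error_rate: float
) -> list[str]:
    """Independent per-base substitution errors over a list of sequences."""
    if error_rate == 0:
        return seqs
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    n_err = rng.binomial(lengths, error_rate)
    out = list(seqs)
    for i in np.flatnonzero(n_err):
        arr = bytearray(out[i], "ascii")
        positions = rng.choice(lengths[i], size=n_err[i], replace=False)
        for pos in positions:
            orig = arr[pos]
            choices = [b for b in b"ACGT" if b != orig]
            arr[pos] = choices[rng.integers(0, len(choices))]
        out[i] = arr.decode("ascii")
    return out


def _write_fastq_gz(path: Path, names: list[str], seqs: list[str]) -> None:
    # fixed mtime/filename so identical content gzips byte-identically
    with gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0) as fh:
        chunks = []
        for name, seq in zip(names, seqs):
            chunks.append(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
        fh.write("".join(chunks).encode("ascii"))


def simulate_experiment(cfg: SimConfig, outdir: str | Path) -> SimTruth:
    """Generate R1/R2 FASTQ (gzipped) and ground truth for one experiment.

    Writes ``r1.fastq.gz`` and ``r2.fastq.gz`` under ``outdir`` plus
    ``truth_cells.tsv`` and ``truth_reads.tsv``; returns the in-memory
    :class:`SimTruth`. Deterministic (byte-identical files) given the
    same configuration and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    n_singlets = sum(n for _, n in cfg.profiles)
    n_doublets = int(round(cfg.doublet_rate * n_singlets))
    n_barcodes = n_singlets + n_doublets + cfg.n_empty_drops
    if n_barcodes > cfg.whitelist_size:
        raise ValueError(
            f"{n_barcodes} droplets exceed whitelist of {cfg.whitelist_size}"
        )

    # 1) whitelist, 2) droplet barcodes drawn without replacement
    whitelist = _random_kmers(rng, cfg.whitelist_size, cfg.barcode_len)
    chosen = rng.choice(cfg.whitelist_size, size=n_barcodes, replace=False)
    barcodes = [whitelist[i] for i in chosen]

    # assign profiles: singlets per profile, then doublets merging a random
    # pair of distinct profiles (or the sole profile twice)
    assignments: list[tuple[str, str, tuple[CellProfile, ...]]] = []
    cursor = 0
    for profile, n in cfg.profiles:
        for _ in range(n):
            assignments.append((barcodes[cursor], profile.label, (profile,)))
            cursor += 1
    profile_list = [p for p, _ in cfg.profiles]
    for _ in range(n_doublets):
        if len(profile_list) > 1:
            i, j = rng.choice(len(profile_list), size=2, replace=False)
        else:
            i = j = 0
        assignments.append(
            (barcodes[cursor], "doublet", (profile_list[i], profile_list[j]))
        )
        cursor += 1
    empty_barcodes = barcodes[cursor:]

    substrate_list = list(cfg.substrates)
    molecule_counts: dict[tuple[str, str, int], int] = {}
    # molecule draws: (barcode, substrate, position, umi)
    molecules: list[tuple[str, str, int]] = []

    def draw_molecules(barcode: str, substrate, dist: Mapping[int, float], n_mol: int):
        if n_mol == 0:
            return
        positions = sorted(dist)
        probs = np.array([dist[p] for p in positions])
        drawn = rng.choice(positions, size=n_mol, p=probs / probs.sum())
        for pos in drawn:
            pos = int(pos)
            molecules.append((barcode, substrate.name, pos))
            key = (barcode, substrate.name, pos)
            molecule_counts[key] = molecule_counts.get(key, 0) + 1

    # 3) per-droplet molecules: cells (including doublets), then empty drops
    for barcode, _, profiles in assignments:
        for substrate in substrate_list:
            for profile in profiles:
                dist = profile.incision_distributions.get(substrate.name)
                if dist is None:
                    continue
                n_mol = rng.poisson(profile.umis_per_substrate)
                draw_molecules(barcode, substrate, dist, n_mol)
    for barcode in empty_barcodes:
        for substrate in substrate_list:
            n_mol = rng.poisson(cfg.background_molecules)
            if n_mol == 0:
                continue
            # ambient material is intact-heavy; the rest spreads uniformly
            # over the substrate's scored sites (released incised fragments)
            sites = substrate.scored_sites or (1,)
            dist = {1: cfg.background_intact_fraction}
            residual = 1.0 - cfg.background_intact_fraction
            for site in sites:
                dist[site] = dist.get(site, 0.0) + residual / len(sites)
            draw_molecules(barcode, substrate, dist, n_mol)

    # 4) one UMI per molecule, 5) geometric read multiplicity
    n_mol_total = len(molecules)
    umi_codes = rng.integers(0, 4, size=(n_mol_total, cfg.umi_len))
    umis = [_BASES[row].tobytes().decode("ascii") for row in umi_codes]
    multiplicity = rng.geometric(1.0 / cfg.reads_per_umi, size=n_mol_total)
    has_tso = rng.random(int(multiplicity.sum())) < cfg.tso_prob

    r1_seqs: list[str] = []
    r2_seqs: list[str] = []
    read_truth: list[tuple[str, str, str, int]] = []
    ridx = 0
    for (barcode, sub_name, pos), umi, n_reads in zip(molecules, umis, multiplicity):
        substrate = cfg.substrates[sub_name]
        body = substrate.sequence[pos - 1:] + "A" * substrate.polya_length
        r1 = barcode + umi
        for _ in range(int(n_reads)):
            r2 = (cfg.tso if has_tso[ridx] else "") + body
            r1_seqs.append(r1)
            r2_seqs.append(r2)
            read_truth.append((barcode, umi, sub_name, pos))
            ridx += 1

    # 6) per-base substitution errors, then a deterministic shuffle so
    # downstream processing cannot depend on generation order
    r1_seqs = _apply_errors(rng, r1_seqs, cfg.error_rate)
    r2_seqs = _apply_errors(rng, r2_seqs, cfg.error_rate)
    order = rng.permutation(len(r1_seqs))
    names = [f"sim{i}" for i in range(len(r1_seqs))]
    r1_seqs = [r1_seqs[i] for i in order]
    r2_seqs = [r2_seqs[i] for i in order]
    read_truth = [read_truth[i] for i in order]

    _write_fastq_gz(outdir / "r1.fastq.gz", names, r1_seqs)
    _write_fastq_gz(outdir / "r2.fastq.gz", names, r2_seqs)

    cells = pd.DataFrame(
        [(bc, label) for bc, label, _ in assignments]
        + [(bc, "empty") for bc in empty_barcodes],
        columns=["barcode", "label"],
    )
    reads = pd.DataFrame(
        [(name, bc, umi, sub, pos)
         for name, (bc, umi, sub, pos) in zip(names, read_truth)],
        columns=["read_id", "barcode", "umi", "substrate", "position"],
    )
    cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    with open(outdir / "whitelist.txt", "w") as fh:
        for bc in whitelist:
            fh.write(bc + "\n")

    return SimTruth(
        cells=cells,
        molecule_counts=molecule_counts,
        reads=reads,
        whitelist=frozenset(whitelist),
    )


def make_mixing_config(
    n_per_genotype: int,
    depth: float = 40.0,
    doublet_rate: float = 0.05,
    seed: int = 0,
    n_empty_drops: int = 500,
    background_molecules: float = 1.0,
    error_rate: float = 0.001,
) -> SimConfig:
    """Two-genotype knockout mixing experiment configuration.

    Models a mixture of UNG-null and RNASEH2C-null cells with uracil
    (U:A) and ribonucleotide (rG:C) substrates. Each genotype incises only
    the substrate its remaining pathway recognizes: the incision
    distribution puts probability 0.6 at the scored site, 0.2 of
    downstream processing signal, and 0.2 intact; the other substrate
    stays fully intact. ``depth`` is the mean captured molecules per cell
    per substrate. The two profiles are mirror images (substrate roles
    swapped).
    """
    if n_per_genotype < 1:
        raise ValueError("n_per_genotype must be >= 1")
    panel = example_substrate_set()
    substrates = SubstrateSet([panel["uracilA"], panel["riboG"]])
    active_uracil = {45: 0.6, 46: 0.15, 47: 0.05, 1: 0.2}
    active_ribo = {44: 0.6, 45: 0.15, 46: 0.05, 1: 0.2}
    intact = {1: 1.0}
    ung_ko = CellProfile(
        label="UNG_KO",
        incision_distributions={"uracilA": intact, "riboG": active_ribo},
        umis_per_substrate=depth,
    )
    rnaseh2c_ko = CellProfile(
        label="RNASEH2C_KO",
        incision_distributions={"uracilA": active_uracil, "riboG": intact},
        umis_per_substrate=depth,
    )
    return SimConfig(
        substrates=substrates,
        profiles=((ung_ko, n_per_genotype), (rnaseh2c_ko, n_per_genotype)),
        seed=seed,
        n_empty_drops=n_empty_drops,
        background_molecules=background_molecules,
        doublet_rate=doublet_rate,
        reads_per_umi=2.0,
        error_rate=error_rate,
    )
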