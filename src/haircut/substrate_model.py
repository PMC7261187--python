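"""Hairpin substrate definitions and reference I/O.

A substrate is a synthetic polyadenylated DNA hairpin with a lesion at a
known position. Repair enzymes incise the strand, creating a new 5' end
whose position is captured by reverse transcription in the droplet; the
reference sequence stored here is the single strand as it appears in the
sequenced read, with the polyA tail excluded (reads are polyA-trimmed
before alignment, and terminal C3 spacers are never sequenced).

Coordinates are 1-based and inclusive everywhere in this package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "LesionType",
    "SubstrateSpec",
    "SubstrateSet",
    "load_substrate_table",
    "write_reference_fasta",
    "load_reference_fasta",
    "example_substrate_set",
]

_VALID_BASES = frozenset("ACGT")


class LesionType(str, Enum):
    """Kind of synthetic lesion carried by a hairpin substrate."""

    UNMODIFIED = "unmodified"
    U_A = "U_A"          # uracil:adenine base pair (UNG substrate)
    U_G = "U_G"          # uracil:guanine base pair (UNG/SMUG/MBD4 substrate)
    RIBOG_C = "riboG_C"  # ribonucleotide guanosine:C (RNASEH2 substrate)
    ABASIC_G = "abasic_G"  # abasic site opposite G (Ape-1 substrate)
    OTHER = "other"


@dataclass(frozen=True)
class SubstrateSpec:
    """One hairpin substrate.

    Parameters
    ----------
    name
        Unique identifier; used as the reference "chromosome" name.
    sequence
        Uppercase ACGT reference as sequenced, polyA tail excluded.
    lesion_position
        1-based position of the synthetic lesion.
    lesion_type
        Lesion chemistry (:class:`LesionType`).
    scored_sites
        1-based positions whose molecule counts define named repair
        activities, e.g. lesion_position + 1 for uracil incision.
    polya_length
        Length of the polyA tail on the physical oligo (not part of
        ``sequence``).
    """

    name: str
    sequence: str
    lesion_position: int
    lesion_type: LesionType = LesionType.OTHER
    scored_sites: tuple[int, ...] = ()
    polya_length: int = 30

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("substrate name must be non-empty")
        if not self.sequence:
            raise ValueError(f"substrate {self.name!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"substrate {self.name!r}: non-ACGT characters {sorted(bad)}"
            )
        if not 1 <= self.lesion_position <= len(self.sequence):
            raise ValueError(
                f"substrate {self.name!r}: lesion_position "
                f"{self.lesion_position} outside [1, {len(self.sequence)}]"
            )
        for site in self.scored_sites:
            if not 1 <= site <= len(self.sequence):
                raise ValueError(
                    f"substrate {self.name!r}: scored site {site} outside "
                    f"[1, {len(self.sequence)}]"
                )
        if self.polya_length < 0:
            raise ValueError(f"substrate {self.name!r}: negative polyA length")
        object.__setattr__(self, "scored_sites", tuple(self.scored_sites))

    def __len__(self) -> int:
        return len(self.sequence)


class SubstrateSet:
    """Ordered collection of uniquely named substrates."""

    def __init__(self, substrates: Iterable[SubstrateSpec]):
        self._substrates: list[SubstrateSpec] = list(substrates)
        if not self._substrates:
            raise ValueError("SubstrateSet must contain at least one substrate")
        names = [s.name for s in self._substrates]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate substrate names: {sorted(dupes)}")
        self._by_name = {s.name: s for s in self._substrates}

    def __iter__(self) -> Iterator[SubstrateSpec]:
        return iter(self._substrates)

    def __len__(self) -> int:
        return len(self._substrates)

    def __getitem__(self, name: str) -> SubstrateSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubstrateSet):
            return NotImplemented
        return self._substrates == other._substrates

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._substrates]


def load_substrate_table(path: str | Path) -> SubstrateSet:
    """Read a substrate metadata TSV into a validated :class:`SubstrateSet`.

    Expected columns: ``name``, ``sequence``, ``lesion_position``,
    ``lesion_type``, ``scored_sites`` (comma-separated 1-based positions),
    ``polya_length``. Errors are reported with the offending row number
    (1-based, excluding the header).
    """
    required = {"name", "sequence", "lesion_position", "lesion_type",
                "scored_sites", "polya_length"}
    substrates = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for rownum, row in enumerate(reader, start=1):
            try:
                sites = tuple(
                    int(tok) for tok in row["scored_sites"].split(",") if tok.strip()
                )
                spec = SubstrateSpec(
                    name=row["name"].strip(),
                    sequence=row["sequence"].strip().upper(),
                    lesion_position=int(row["lesion_position"]),
                    lesion_type=LesionType(row["lesion_type"]),
                    scored_sites=sites,
                    polya_length=int(row["polya_length"]),
                )
            except ValueError as exc:
                raise ValueError(f"{path} row {rownum}: {exc}") from exc
            substrates.append(spec)
    try:
        return SubstrateSet(substrates)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_substrate_table(substrates: SubstrateSet, path: str | Path) -> None:
    """Write the substrate metadata TSV (inverse of :func:`load_substrate_table`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "sequence", "lesion_position", "lesion_type",
                         "scored_sites", "polya_length"])
        for s in substrates:
            writer.writerow([
                s.name, s.sequence, s.lesion_position, s.lesion_type.value,
                ",".join(str(p) for p in s.scored_sites), s.polya_length,
            ])


def write_reference_fasta(substrates: SubstrateSet, path: str | Path) -> None:
    """Write one FASTA record per substrate (header = name, no polyA)."""
    with open(path, "w") as fh:
        for s in substrates:
            fh.write(f">{s.name}\n{s.sequence}\n")


def load_reference_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a hairpin reference FASTA as ordered (name, sequence) pairs."""
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


# Example substrate panel mirroring the published coordinate layout: five
# lesion chemistries, lesion at position 44, uracil incision scored at 45
# (UNG removes the uracil, Ape-1/Pol-beta cleave the abasic site one base
# downstream of the read start), ribonucleotide incision scored at 44
# (RNASEH2 cuts 5' of the ribonucleotide and the reverse transcriptase
# copies through it), abasic processing scored at 45 (short patch) and 46
# (long patch). Sequences are fixed arbitrary 70-mers chosen so that any
# >=20 nt read placed at any wrong (substrate, offset) pair carries at
# least 7 mismatches, keeping end-anchored alignment unambiguous; the last
# six bases contain no A so polyA trimming cannot bite into the reference.
_EXAMPLE_SEQUENCES = {
    "unmodified": "CTCGCACATTTTGGCAGAAGCGGGAAGCAGTTAACTTACATATTGTGCGCCGCGACTCTCTATTGTTCTT",
    "uracilA":    "TCCTGATCGCCCATTCACGGTCATCGGCGACTCACGCATGTATTATCTGTACCATAGAGCAGTCTGGGTC",
    "uracilG":    "TGTTTCGTAAAGAGGCCACCGCAGATAGGGGTGACATCATGATTGTGGGCGATGATCTAATTTTGCTTCC",
    "riboG":      "GTGGTACGGTGGGAACTTTGGATCTCTTATCACGAGCTAACACTGAATATTAAAGGACACAGGGTGTGGC",
    "abasicG":    "ACCGTAGTGGAGTACAAGTTGTCACACATCCCGGGAACTGGGGTGTCCCCCCGAATCGCAGATATGTTGT",
}

LESION_POSITION = 44


def example_substrate_set(polya_length: int = 30) -> SubstrateSet:
    """The five-substrate example panel (unmodified, U:A, U:G, rG:C, abasic:G).

    Lesions sit at position 44; uracil incision is scored at 45,
    ribonucleotide incision at 44, abasic short-/long-patch processing at
    45/46.
    """
    return SubstrateSet([
        SubstrateSpec("unmodified", _EXAMPLE_SEQUENCES["unmodified"],
                      LESION_POSITION, LesionType.UNMODIFIED, (45,), polya_length),
        SubstrateSpec("uracilA", _EXAMPLE_SEQUENCES["uracilA"],
                      LESION_POSITION, LesionType.U_A, (45,), polya_length),
        SubstrateSpec("uracilG", _EXAMPLE_SEQUENCES["uracilG"],
                      LESION_POSITION, LesionType.U_G, (45,), polya_length),
        SubstrateSpec("riboG", _EXAMPLE_SEQUENCES["riboG"],
                      LESION_POSITION, LesionType.RIBOG_C, (44,), polya_length),
        SubstrateSpec("abasicG", _EXAMPLE_SEQUENCES["abasicG"],
                      LESION_POSITION, LesionType.ABASIC_G, (45, 46), polya_length),
    ])
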