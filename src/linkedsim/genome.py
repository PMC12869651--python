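"""Diploid genome input/output.

The simulator consumes a phased diploid assembly supplied as two haplotype
FASTA files (e.g. the paternal and maternal contig sets of a trio-phased
assembly). The two haplotypes are independent contig collections: names,
counts and lengths may differ between them, and coordinates on one haplotype
have no meaning on the other. All coordinates in this package are 0-based,
half-open.

Sequences are restricted to the alphabet ``{A, C, G, T, N}``; soft-masked
(lowercase) input is accepted and uppercased on load. IUPAC ambiguity codes
other than N are rejected because downstream fragment and read simulation
copies bases verbatim and an ambiguity code in a read is not a sequencer
output.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict

from Bio import SeqIO

from .errors import FastaFormatError

_BAD_CHAR = re.compile(r"[^ACGTN]")


def _open_text_auto(path):
    """Open plain or gzip-compressed text transparently (by magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_fasta(path) -> Dict[str, str]:
    """Read one haplotype FASTA into an ordered contig-name -> sequence map."""
    contigs: Dict[str, str] = {}
    with _open_text_auto(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in contigs:
                raise FastaFormatError(
                    f"{path}: duplicate contig name {record.id!r} within one haplotype"
                )
            seq = str(record.seq).upper()
            if not seq:
                raise FastaFormatError(f"{path}: contig {record.id!r} is empty")
            match = _BAD_CHAR.search(seq)
            if match:
                raise FastaFormatError(
                    f"{path}: contig {record.id!r} position {match.start() + 1}: "
                    f"illegal character {match.group()!r} (allowed: A,C,G,T,N)"
                )
            contigs[record.id] = seq
    if not contigs:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return contigs


@dataclass
class DiploidGenome:
    """Two haplotype sequence sets keyed by contig name (order preserved)."""

    hap1: Dict[str, str]
    hap2: Dict[str, str]

    def haplotype(self, hap: int) -> Dict[str, str]:
        if hap == 1:
            return self.hap1
        if hap == 2:
            return self.hap2
        raise ValueError(f"haplotype must be 1 or 2, got {hap!r}")

    @property
    def L_hap1(self) -> int:
        return sum(len(s) for s in self.hap1.values())

    @property
    def L_hap2(self) -> int:
        return sum(len(s) for s in self.hap2.values())

    def length(self, hap: int) -> int:
        return sum(len(s) for s in self.haplotype(hap).values())

    @property
    def total_length(self) -> int:
        return self.L_hap1 + self.L_hap2


def load_diploid(fasta_hap1, fasta_hap2) -> DiploidGenome:
    """Load a diploid genome from two haplotype FASTA files (plain or .gz)."""
    return DiploidGenome(hap1=_read_fasta(fasta_hap1), hap2=_read_fasta(fasta_hap2))


def haplotype_length(genome: DiploidGenome, hap: int) -> int:
    """Total bases of one haplotype (the L_h that volume targeting uses)."""
    return genome.length(hap)


def write_fasta(contigs: Dict[str, str], path, width: int = 70) -> None:
    """Write one haplotype to FASTA; gzip output if the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for name, seq in contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_diploid(genome: DiploidGenome, path_hap1, path_hap2) -> None:
    write_fasta(genome.hap1, path_hap1)
    write_fasta(genome.hap2, path_hap2)
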