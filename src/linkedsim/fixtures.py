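"""Synthetic diploid genomes with known phased variants and a truth VCF.

The simulator's natural input is a phased human assembly; for testing and
self-contained runs this module builds small stand-ins: an i.i.d. random
base reference with configurable GC content, diploidized by placing phased
SNPs, small indels and optional SV-sized insertions/deletions. Every variant
is recorded in a phased VCFv4.2 truth file whose coordinates refer to the
base reference, and the two haplotype sequences are built by applying each
variant's alleles according to its genotype.

These genomes deliberately lack the repeat structure, segmental duplications
and variant clustering of real genomes; they exercise the simulator's
bookkeeping (coordinates, phasing, coverage), not aligner-facing realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import PlacementError
from .genome import DiploidGenome, write_fasta

_GENOTYPES = ("0|1", "1|0", "1|1")


@dataclass
class TruthVariant:
    """One phased variant on the base reference (1-based position, VCF-style
    alleles: indels carry a left anchor base)."""

    contig: str
    pos: int
    vtype: str  # "SNP", "INS" or "DEL"
    ref: str
    alt: str
    genotype: str  # "0|1", "1|0" or "1|1"

    def on_hap(self, hap: int) -> bool:
        return self.genotype.split("|")[hap - 1] == "1"


def generate_reference(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """i.i.d. random DNA with P(G) = P(C) = gc/2. Deterministic given seed."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng([seed, 23])
    at = (1.0 - gc) / 2
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    draw = rng.choice(bases, size=length, p=[at, gc / 2, gc / 2, at])
    return bytes(draw).decode("ascii")


def _random_bases(rng, n: int) -> str:
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, n)]).decode(
        "ascii"
    )


def _other_base(rng, base: str) -> str:
    alternatives = [b for b in "ACGT" if b != base]
    return alternatives[int(rng.integers(0, 3))]


def diploidize(
    reference: str,
    snp_rate: float = 0.001,
    indel_rate: float = 0.0001,
    sv_spec: Sequence[Tuple[str, int, int]] = (),
    seed: int = 0,
    contig: str = "sim1",
) -> Tuple[str, str, List[TruthVariant]]:
    """Place phased variants on a reference; return both haplotypes + truth.

    ``sv_spec`` lists (type, length, count) with type "INS" or "DEL" and
    length the number of inserted/deleted bases (>= 50 for SV class by
    convention, though any length >= 1 is accepted). Small indel lengths are
    geometric with mean 3 bp. Each variant's genotype is 0|1, 1|0 or 1|1 with
    probability 1/3. Variants never overlap (a 1 bp buffer separates them).
    """
    for rate, label in ((snp_rate, "snp_rate"), (indel_rate, "indel_rate")):
        if not 0 <= rate <= 0.1:
            raise ValueError(f"{label} must be in [0, 0.1], got {rate}")
    rng = np.random.default_rng([seed, 29])
    L = len(reference)
    occupied = np.zeros(L, dtype=bool)
    variants: List[TruthVariant] = []

    def claim(start0: int, end0: int) -> bool:
        lo = max(0, start0 - 1)
        hi = min(L, end0 + 1)
        if occupied[lo:hi].any():
            return False
        occupied[lo:hi] = True
        return True

    # SVs first: they are the hardest to place without overlap.
    for vtype, length, count in sv_spec:
        if vtype not in ("INS", "DEL"):
            raise ValueError(f"sv type must be INS or DEL, got {vtype!r}")
        if length < 1 or count < 1:
            raise ValueError("sv length and count must be >= 1")
        for _ in range(count):
            span = length + 1 if vtype == "DEL" else 1
            placed = False
            for _try in range(1000):
                pos = int(rng.integers(1, L - span))  # 1-based anchor, not last base
                if not claim(pos - 1, pos - 1 + span):
                    continue
                anchor = reference[pos - 1]
                if vtype == "DEL":
                    ref = reference[pos - 1 : pos + length]
                    alt = anchor
                else:
                    ref = anchor
                    alt = anchor + _random_bases(rng, length)
                variants.append(
                    TruthVariant(contig, pos, vtype, ref, alt, _pick_gt(rng))
                )
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place {vtype} of {length} bp without overlap "
                    f"on a {L} bp reference"
                )

    # Small variants: candidate positions are binomial draws; candidates that
    # collide with an already-claimed interval are dropped (rare at the
    # supported rates, and the truth VCF records exactly what was introduced).
    n_snp = int(rng.binomial(L, snp_rate)) if snp_rate > 0 else 0
    n_indel = int(rng.binomial(L, indel_rate)) if indel_rate > 0 else 0
    if n_snp:
        for pos0 in rng.choice(L, size=n_snp, replace=False):
            pos0 = int(pos0)
            if not claim(pos0, pos0 + 1):
                continue
            ref = reference[pos0]
            variants.append(
                TruthVariant(
                    contig, pos0 + 1, "SNP", ref, _other_base(rng, ref), _pick_gt(rng)
                )
            )
    if n_indel:
        for pos0 in rng.choice(L - 10, size=n_indel, replace=False):
            pos = int(pos0) + 1  # keep anchor off the first base
            is_del = rng.random() < 0.5
            length = int(rng.geometric(1.0 / 3.0))
            if is_del and pos + length >= L:
                continue
            span = length + 1 if is_del else 1
            if not claim(pos - 1, pos - 1 + span):
                continue
            anchor = reference[pos - 1]
            if is_del:
                variants.append(
                    TruthVariant(
                        contig, pos, "DEL",
                        reference[pos - 1 : pos + length], anchor, _pick_gt(rng),
                    )
                )
            else:
                variants.append(
                    TruthVariant(
                        contig, pos, "INS",
                        anchor, anchor + _random_bases(rng, length), _pick_gt(rng),
                    )
                )

    variants.sort(key=lambda v: v.pos)
    hap1 = _apply(reference, variants, hap=1)
    hap2 = _apply(reference, variants, hap=2)
    return hap1, hap2, variants


def _pick_gt(rng) -> str:
    return _GENOTYPES[int(rng.integers(0, 3))]


def _apply(reference: str, variants: Sequence[TruthVariant], hap: int) -> str:
    """Build one haplotype left-to-right by substituting alt alleles."""
    parts = []
    cursor = 0
    for v in variants:
        start0 = v.pos - 1
        parts.append(reference[cursor:start0])
        if v.on_hap(hap):
            parts.append(v.alt)
        else:
            parts.append(v.ref)
        cursor = start0 + len(v.ref)
    parts.append(reference[cursor:])
    return "".join(parts)


def write_truth_vcf(
    variants: Sequence[TruthVariant],
    contig: str,
    contig_length: int,
    path,
    sample: str = "SYNTH",
) -> None:
    """Minimal phased single-sample VCFv4.2 with the introduced variants."""
    with open(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##contig=<ID={contig},length={contig_length}>\n")
        out.write('##INFO=<ID=VTYPE,Number=1,Type=String,Description="Variant type">\n')
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for v in variants:
            out.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"VTYPE={v.vtype}\tGT\t{v.genotype}\n"
            )


def synthetic_diploid(
    length: int = 1_000_000,
    gc: float = 0.41,
    snp_rate: float = 0.001,
    indel_rate: float = 0.0001,
    sv_spec: Sequence[Tuple[str, int, int]] = (),
    seed: int = 0,
    contig: str = "sim1",
) -> Tuple[DiploidGenome, List[TruthVariant], str]:
    """One-call fixture: (DiploidGenome, truth variants, base reference)."""
    reference = generate_reference(length, gc=gc, seed=seed)
    hap1, hap2, variants = diploidize(
        reference,
        snp_rate=snp_rate,
        indel_rate=indel_rate,
        sv_spec=sv_spec,
        seed=seed,
        contig=contig,
    )
    genome = DiploidGenome(hap1={contig: hap1}, hap2={contig: hap2})
    return genome, variants, reference


def write_fixture(
    outdir,
    length: int = 1_000_000,
    gc: float = 0.41,
    snp_rate: float = 0.001,
    indel_rate: float = 0.0001,
    sv_spec: Sequence[Tuple[str, int, int]] = (),
    seed: int = 0,
    contig: str = "sim1",
) -> dict:
    """Write hap1.fa, hap2.fa and truth.vcf for a synthetic diploid."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, variants, reference = synthetic_diploid(
        length, gc, snp_rate, indel_rate, sv_spec, seed, contig
    )
    paths = {
        "hap1": str(outdir / "hap1.fa"),
        "hap2": str(outdir / "hap2.fa"),
        "vcf": str(outdir / "truth.vcf"),
    }
    write_fasta(genome.hap1, paths["hap1"])
    write_fasta(genome.hap2, paths["hap2"])
    write_truth_vcf(variants, contig, len(reference), paths["vcf"])
    return paths
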