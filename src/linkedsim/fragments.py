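"""Long DNA fragment simulation.

Linked-read libraries start from long DNA molecules. Physical coverage CF is
the cumulative fold-coverage of the genome by those molecules; the total DNA
volume is V = CF x L. Each haplotype receives half the physical coverage, so
haplotype h is covered to CF/2 over its own length L_h. Fragment start
positions are uniform over the haplotype (contigs weighted by length) and
fragment lengths are exponential with mean mu_FL, conditioned on a minimum
length (rejection resampling keeps the distribution a clean truncated
exponential rather than a clamped one).

Generation proceeds until the cumulative fragment bases of each haplotype
reach (CF/2) x L_h, which makes achieved physical coverage exact up to the
final fragment. Fragments overrunning their contig are truncated at the end;
fragments with more than ``max_n_frac`` N content are rejected and redrawn.
Each haplotype draws from its own child RNG stream, so haplotype 1's
fragments do not change when haplotype 2's assembly does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .errors import ConsistencyError, UnsatisfiablePlanError
from .genome import DiploidGenome

MANIFEST_COLUMNS = ("fragment_id", "hap", "contig", "start", "end", "length", "barcode")


@dataclass
class Fragment:
    """One simulated long DNA molecule on a single haplotype contig."""

    id: int
    hap: int
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    barcode: Optional["object"] = None  # BarcodeTriple once assigned

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentPlan:
    """Parameters of the long-fragment model.

    cf
        Physical coverage (fold) summed over both haplotypes; each haplotype
        is targeted at cf/2 over its own length.
    mu_fl
        Mean fragment length of the exponential length law, in bases.
    min_fl
        Minimum fragment length; shorter raw draws are rejected and redrawn
        (truncated exponential). Default 1000 bp — the exponential otherwise
        produces molecules shorter than a single read.
    max_n_frac
        Fragments whose N fraction exceeds this are rejected and redrawn.
    """

    cf: float
    mu_fl: float
    min_fl: int = 1000
    max_n_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.cf < 0:
            raise ValueError(f"CF must be >= 0, got {self.cf}")
        if self.mu_fl <= 0:
            raise ValueError(f"mu_FL must be > 0, got {self.mu_fl}")
        if self.min_fl < 1:
            raise ValueError(f"min_FL must be >= 1, got {self.min_fl}")


def total_dna_volume(cf: float, L: int) -> float:
    """Total DNA volume V = CF x L in bases."""
    if cf < 0 or L < 0:
        raise ValueError(f"CF and L must be non-negative, got CF={cf}, L={L}")
    return cf * L


def expected_barcode_count(cf: float, genome_size: int, mu_fl: float) -> int:
    """Expected number of barcoded partitions, Nbc = ceil(CF x G / mu_FL).

    This is an expectation under the exponential length law, not a guarantee:
    the realized fragment (hence barcode) count of a volume-targeted run
    fluctuates around it.
    """
    if cf <= 0 or genome_size <= 0:
        raise ValueError("CF and genome_size must be > 0")
    if mu_fl <= 0:
        raise ValueError(f"mu_FL must be > 0, got {mu_fl}")
    return math.ceil(cf * genome_size / mu_fl)


def _n_prefix_counts(seq: str) -> Optional[np.ndarray]:
    """Prefix sums of N counts, or None when the contig has no N at all."""
    if "N" not in seq:
        return None
    is_n = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("N")
    out = np.zeros(len(seq) + 1, dtype=np.int64)
    np.cumsum(is_n, out=out[1:])
    return out


def simulate_fragments(genome: DiploidGenome, plan: FragmentPlan) -> List[Fragment]:
    """Draw long fragments per haplotype until each reaches (CF/2) x L_h.

    Returns fragments sorted by (haplotype, contig order, start) with serial
    ids assigned after sorting. Deterministic for a fixed plan seed.
    """
    raw_fragments: List[Fragment] = []
    for hap in (1, 2):
        contigs = genome.haplotype(hap)
        names = list(contigs)
        lengths = np.array([len(contigs[n]) for n in names], dtype=np.int64)
        L_h = int(lengths.sum())
        target = 0.5 * plan.cf * L_h
        if target <= 0:
            continue
        if not np.any(lengths >= plan.min_fl):
            raise UnsatisfiablePlanError(
                f"haplotype {hap}: no contig reaches min_FL={plan.min_fl} "
                f"(longest is {int(lengths.max())} bp) but (CF/2)*L_h="
                f"{target:.0f} > 0"
            )
        n_prefix = {name: _n_prefix_counts(contigs[name]) for name in names}
        cum_p = np.cumsum(lengths / lengths.sum())
        rng = np.random.default_rng([plan.seed, hap])

        volume = 0
        attempts = 0
        # Failsafe for pathological inputs (e.g. nearly all-N contigs): far
        # beyond the expected draw count for any satisfiable plan.
        max_attempts = max(100_000, int(20 * target / plan.mu_fl) + 100_000)
        done = False
        while not done:
            batch = 1024
            u_contig = rng.random(batch)
            raw_len = rng.exponential(plan.mu_fl, batch)
            u_start = rng.random(batch)
            cidx = np.searchsorted(cum_p, u_contig, side="right")
            cidx = np.minimum(cidx, len(names) - 1)
            for j in range(batch):
                attempts += 1
                if attempts > max_attempts:
                    raise UnsatisfiablePlanError(
                        f"haplotype {hap}: gave up after {attempts} draws "
                        f"({len(raw_fragments)} fragments accepted); check "
                        f"min_FL and N content against the contigs"
                    )
                length = int(np.rint(raw_len[j]))
                if length < plan.min_fl:
                    continue
                ci = int(cidx[j])
                clen = int(lengths[ci])
                start = int(u_start[j] * clen)
                end = min(start + length, clen)
                if end - start < plan.min_fl:
                    continue
                prefix = n_prefix[names[ci]]
                if prefix is not None:
                    n_count = int(prefix[end] - prefix[start])
                    if n_count > plan.max_n_frac * (end - start):
                        continue
                raw_fragments.append(
                    Fragment(id=-1, hap=hap, contig=names[ci], start=start, end=end)
                )
                volume += end - start
                if volume >= target:
                    done = True
                    break

    order = {
        (hap, name): i
        for hap in (1, 2)
        for i, name in enumerate(genome.haplotype(hap))
    }
    raw_fragments.sort(key=lambda f: (f.hap, order[(f.hap, f.contig)], f.start, f.end))
    for i, frag in enumerate(raw_fragments):
        frag.id = i
    return raw_fragments


def achieved_physical_coverage(fragments: List[Fragment], genome: DiploidGenome) -> Dict[int, float]:
    """Sum of fragment lengths over L_h, per haplotype."""
    out = {}
    for hap in (1, 2):
        L_h = genome.length(hap)
        total = sum(f.length for f in fragments if f.hap == hap)
        out[hap] = total / L_h if L_h else 0.0
    return out


def write_fragment_manifest(fragments: List[Fragment], path) -> None:
    """Tab-separated fragment manifest (one row per fragment, '.' = no barcode)."""
    with open(path, "wt") as out:
        out.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for f in fragments:
            tag = f.barcode.tag if f.barcode is not None else "."
            out.write(
                f"{f.id}\t{f.hap}\t{f.contig}\t{f.start}\t{f.end}\t{f.length}\t{tag}\n"
            )


def read_fragment_manifest(path) -> List[dict]:
    """Parse a fragment manifest back into a list of row dicts."""
    rows = []
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MANIFEST_COLUMNS:
            raise ConsistencyError(f"{path}: unexpected manifest header {header}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "fragment_id": int(parts[0]),
                    "hap": int(parts[1]),
                    "contig": parts[2],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "length": int(parts[5]),
                    "barcode": None if parts[6] == "." else parts[6],
                }
            )
    return rows
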