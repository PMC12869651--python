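"""Library self-verification: empirical summaries vs. the configuration.

QC recomputes, from the emitted artefacts alone (fragment manifest, truth
sidecar, FASTQ), the quantities the simulation was configured to achieve:
physical coverage per haplotype, read coverage against the DNA volume,
fragment-length and insert-size statistics, the realized substitution rate,
and barcode cardinalities. The substitution rate is measured by comparing
each read to its truth substring on the source haplotype — no aligner is
involved, so the measurement has no mapping artefacts.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConsistencyError
from .fragments import read_fragment_manifest, total_dna_volume
from .genome import DiploidGenome
from .presets import SimulationConfig, _open_fastq_auto
from .reads import read_truth_sidecar, reverse_complement


@dataclass
class LibraryQCReport:
    """Empirical summaries of one simulated library."""

    n_fragments: Dict[int, int]
    achieved_cf: Dict[int, float]
    fragment_length_mean: float
    fragment_length_median: float
    n_reads: int
    emitted_bases: int
    achieved_read_coverage: float  # emitted bases / V
    insert_mean: Optional[float]
    insert_sd: Optional[float]
    n_pairs: Optional[int]
    observed_error_rate: float
    mismatches: int
    compared_bases: int
    barcodes_used: int
    fragments_per_barcode: Dict[int, int]  # histogram: partition size -> count
    fragments_without_reads: int

    def to_dict(self) -> dict:
        return {
            "n_fragments": {str(k): v for k, v in self.n_fragments.items()},
            "achieved_cf": {str(k): self.achieved_cf[k] for k in sorted(self.achieved_cf)},
            "fragment_length_mean": self.fragment_length_mean,
            "fragment_length_median": self.fragment_length_median,
            "n_reads": self.n_reads,
            "emitted_bases": self.emitted_bases,
            "achieved_read_coverage": self.achieved_read_coverage,
            "insert_mean": self.insert_mean,
            "insert_sd": self.insert_sd,
            "n_pairs": self.n_pairs,
            "observed_error_rate": self.observed_error_rate,
            "mismatches": self.mismatches,
            "compared_bases": self.compared_bases,
            "barcodes_used": self.barcodes_used,
            "fragments_per_barcode": {
                str(k): self.fragments_per_barcode[k]
                for k in sorted(self.fragments_per_barcode)
            },
            "fragments_without_reads": self.fragments_without_reads,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["Library QC report", "-----------------"]
        for hap in sorted(self.achieved_cf):
            lines.append(
                f"haplotype {hap}: {self.n_fragments.get(hap, 0)} fragments, "
                f"achieved CF/2 = {self.achieved_cf[hap]:.3f}"
            )
        lines.append(
            f"fragment length: mean {self.fragment_length_mean:.0f} bp, "
            f"median {self.fragment_length_median:.0f} bp"
        )
        lines.append(
            f"reads: {self.n_reads} ({self.emitted_bases} bases), "
            f"achieved CR = {self.achieved_read_coverage:.4f}"
        )
        if self.insert_mean is not None:
            lines.append(
                f"insert size: mean {self.insert_mean:.1f} bp, "
                f"sd {self.insert_sd:.1f} bp over {self.n_pairs} pairs"
            )
        lines.append(
            f"substitutions: {self.mismatches}/{self.compared_bases} "
            f"= {self.observed_error_rate:.6f}"
        )
        lines.append(f"barcodes used: {self.barcodes_used}")
        lines.append(f"fragments-per-barcode histogram: {dict(sorted(self.fragments_per_barcode.items()))}")
        lines.append(f"fragments without reads: {self.fragments_without_reads}")
        return "\n".join(lines) + "\n"


def _strip_mate(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def qc_from_manifests(
    fragment_manifest,
    truth_sidecar,
    fastq_set: Sequence,
    genome: DiploidGenome,
    config: SimulationConfig,
) -> LibraryQCReport:
    """Compute the QC report for one run from its emitted files."""
    rows = read_fragment_manifest(fragment_manifest)
    known_fragments = {r["fragment_id"] for r in rows}
    truth = read_truth_sidecar(truth_sidecar)

    n_fragments: Dict[int, int] = {1: 0, 2: 0}
    frag_bases: Dict[int, int] = {1: 0, 2: 0}
    lengths: List[int] = []
    barcode_counts: Dict[str, int] = {}
    for r in rows:
        n_fragments[r["hap"]] += 1
        frag_bases[r["hap"]] += r["length"]
        lengths.append(r["length"])
        if r["barcode"] is not None:
            barcode_counts[r["barcode"]] = barcode_counts.get(r["barcode"], 0) + 1

    achieved_cf = {
        hap: frag_bases[hap] / genome.length(hap) for hap in (1, 2) if genome.length(hap)
    }

    n_reads = 0
    emitted_bases = 0
    mismatches = 0
    compared = 0
    fragments_with_reads = set()
    pair_coords: Dict[str, List[dict]] = {}
    for path in fastq_set:
        with _open_fastq_auto(path) as fh:
            for name_line, seq, _qual in FastqGeneralIterator(fh):
                name = name_line.split(" ")[0]
                info = truth.get(name)
                if info is None:
                    raise ConsistencyError(
                        f"read {name!r} has no truth sidecar entry"
                    )
                if info["fragment_id"] not in known_fragments:
                    raise ConsistencyError(
                        f"read {name!r} references unknown fragment "
                        f"{info['fragment_id']}"
                    )
                fragments_with_reads.add(info["fragment_id"])
                n_reads += 1
                emitted_bases += len(seq)
                ref = genome.haplotype(info["hap"])[info["contig"]][
                    info["start"] : info["end"]
                ]
                if info["strand"] == "-":
                    ref = reverse_complement(ref)
                a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                b = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
                if a.size != b.size:
                    raise ConsistencyError(
                        f"read {name!r}: length {a.size} != truth interval {b.size}"
                    )
                mismatches += int((a != b).sum())
                compared += a.size
                if config.mode == "PE":
                    pair_coords.setdefault(_strip_mate(name), []).append(info)

    inserts: List[int] = []
    for mates in pair_coords.values():
        if len(mates) == 2:
            inserts.append(
                max(m["end"] for m in mates) - min(m["start"] for m in mates)
            )

    total_L = genome.total_length
    v = total_dna_volume(config.cf, total_L) / 2  # per-hap CF/2 on each L_h sums to CF*L/2
    # V as the read budget uses it: sum over haplotypes of (CF/2) * L_h.
    achieved_read_coverage = emitted_bases / v if v else 0.0

    histogram: Dict[int, int] = {}
    for count in barcode_counts.values():
        histogram[count] = histogram.get(count, 0) + count
    # histogram maps partition size -> number of fragments in partitions of
    # that size, so it sums to the barcoded fragment count.

    return LibraryQCReport(
        n_fragments=n_fragments,
        achieved_cf=achieved_cf,
        fragment_length_mean=float(np.mean(lengths)) if lengths else 0.0,
        fragment_length_median=float(np.median(lengths)) if lengths else 0.0,
        n_reads=n_reads,
        emitted_bases=emitted_bases,
        achieved_read_coverage=achieved_read_coverage,
        insert_mean=float(np.mean(inserts)) if inserts else None,
        insert_sd=float(np.std(inserts, ddof=1)) if len(inserts) > 1 else None,
        n_pairs=len(inserts) if config.mode == "PE" else None,
        observed_error_rate=mismatches / compared if compared else 0.0,
        mismatches=mismatches,
        compared_bases=compared,
        barcodes_used=len(barcode_counts),
        fragments_per_barcode=histogram,
        fragments_without_reads=len(known_fragments) - len(fragments_with_reads),
    )


def barcode_cardinality(fastq_set: Sequence) -> tuple:
    """Distinct barcode tags and a reads-per-barcode summary from read names.

    Parses the stLFR "#i1_i2_i3" suffix of each read name; returns
    (n_distinct_tags, summary dict).
    """
    counts: Dict[str, int] = {}
    for path in fastq_set:
        with _open_fastq_auto(path) as fh:
            for name_line, _seq, _qual in FastqGeneralIterator(fh):
                name = _strip_mate(name_line.split(" ")[0])
                if "#" not in name:
                    raise ValueError(f"read name without barcode tag: {name!r}")
                counts[name.rpartition("#")[2]] = counts.get(name.rpartition("#")[2], 0) + 1
    if not counts:
        return 0, {"total_reads": 0}
    values = list(counts.values())
    summary = {
        "total_reads": sum(values),
        "min_reads_per_barcode": min(values),
        "mean_reads_per_barcode": sum(values) / len(values),
        "max_reads_per_barcode": max(values),
    }
    return len(counts), summary
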