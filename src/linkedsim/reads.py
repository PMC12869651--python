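"""Barcoded short-read generation over long fragments.

Each fragment is covered by reads at read coverage CR: the total read budget
is CR x V / RL individual reads, apportioned per fragment as
n_f = round(CR x length_f / RL). Paired-end mode draws insert sizes from
Normal(mu_IS, sigma_IS) (rounded, clamped to [2 RL, fragment length]) and
places the pair uniformly on the fragment in FR orientation; single-end mode
places fixed-length reads uniformly with a fair coin for strand.

Base qualities come from a positional (per-cycle) model; substitution errors
are injected with per-base probability p_i = c * 10^(-Q_i/10), where the
scale c is calibrated against the quality model's exact discretized quality
distribution so that the mean error probability equals the configured error
rate. Substituted bases are drawn uniformly from the three alternatives and N
bases are never substituted. No indel, adapter or duplicate artefacts are
modelled.

Read names follow the stLFR convention ``S<serial>#<i1>_<i2>_<i3>`` with mate
suffixes ``/1``/``/2`` in paired-end mode; unbarcoded (plain Illumina) mode
uses the null tag ``0_0_0``.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .fragments import Fragment
from .genome import DiploidGenome

QMIN, QMAX = 2, 41
_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_INDEX[_a] = _i
_INDEX_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

# Probability ceiling for a single base substitution; keeps c*10^(-Q/10) a
# probability even for extreme user-supplied profiles.
_P_CAP = 0.75


def reverse_complement(seq: str) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return bytes(_COMP[arr][::-1]).decode("ascii")


@dataclass
class ReadParams:
    """Read-layer parameters: mode, RL, CR, insert law, error rate, barcoding."""

    mode: str  # "PE" or "SE"
    rl: int = 150
    cr: float = 0.1
    mu_is: float = 600.0
    sigma_is: Optional[float] = None  # default 0.1 * mu_is
    error_rate: float = 0.01
    barcode_on: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("PE", "SE"):
            raise ValueError(f"mode must be 'PE' or 'SE', got {self.mode!r}")
        if self.rl < 1:
            raise ValueError(f"RL must be >= 1, got {self.rl}")
        if self.cr < 0:
            raise ValueError(f"CR must be >= 0, got {self.cr}")
        if not 0 <= self.error_rate < 1:
            raise ValueError(f"error rate must be in [0, 1), got {self.error_rate}")
        if self.sigma_is is None:
            self.sigma_is = 0.1 * self.mu_is
        if self.mode == "PE" and self.mu_is < 2 * self.rl:
            raise ValueError(
                f"PE mode requires mu_IS >= 2*RL ({self.mu_is} < {2 * self.rl})"
            )


@dataclass(frozen=True)
class QualityModel:
    """Per-cycle Phred quality model: Normal(mean_q[c], sd_q[c]), rounded and
    clamped to [2, 41]."""

    mean_q: np.ndarray
    sd_q: np.ndarray

    def __post_init__(self):
        mean_q = np.asarray(self.mean_q, dtype=float)
        sd_q = np.broadcast_to(np.asarray(self.sd_q, dtype=float), mean_q.shape).copy()
        object.__setattr__(self, "mean_q", mean_q)
        object.__setattr__(self, "sd_q", sd_q)
        if mean_q.ndim != 1 or mean_q.size < 1:
            raise ValueError("quality model needs one mean per cycle")
        if np.any(mean_q < QMIN) or np.any(mean_q > QMAX):
            raise ValueError(f"mean qualities must lie in [{QMIN}, {QMAX}]")
        if np.any(sd_q < 0):
            raise ValueError("quality dispersions must be >= 0")

    @property
    def rl(self) -> int:
        return self.mean_q.size

    @classmethod
    def default(cls, rl: int) -> "QualityModel":
        """Positional Illumina-like profile: mean Q declining linearly from 38
        at cycle 1 to 30 at the last cycle, Gaussian jitter sd 3."""
        mean = np.linspace(38.0, 30.0, rl) if rl > 1 else np.array([38.0])
        return cls(mean_q=mean, sd_q=np.full(rl, 3.0))

    @classmethod
    def flat(cls, rl: int, q: float = 30.0, sd: float = 0.0) -> "QualityModel":
        return cls(mean_q=np.full(rl, float(q)), sd_q=np.full(rl, float(sd)))

    @classmethod
    def from_table(cls, path) -> "QualityModel":
        """Load an empirical profile: TSV with columns cycle, mean_q, sd_q."""
        rows = []
        with open(path, "rt") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("cycle"):
                    continue
                cycle, mean, sd = line.split("\t")
                rows.append((int(cycle), float(mean), float(sd)))
        rows.sort()
        if [c for c, _, _ in rows] != list(range(1, len(rows) + 1)):
            raise ValueError(f"{path}: cycles must be 1..RL without gaps")
        return cls(
            mean_q=np.array([m for _, m, _ in rows]),
            sd_q=np.array([s for _, _, s in rows]),
        )

    def sample(self, rng, n_reads: int) -> np.ndarray:
        """(n_reads, RL) integer quality matrix."""
        q = rng.normal(self.mean_q, self.sd_q, size=(n_reads, self.rl))
        return np.clip(np.rint(q), QMIN, QMAX).astype(np.int64)

    def quality_pmf(self) -> np.ndarray:
        """(RL, 40) matrix: P(Q = q) per cycle for q in [2, 41], computed
        exactly from the rounded/clamped normal (CDF differences, tails lumped
        into the clamp bounds)."""
        qs = np.arange(QMIN, QMAX + 1)
        pmf = np.zeros((self.rl, qs.size))
        for c in range(self.rl):
            mu, sd = self.mean_q[c], self.sd_q[c]
            if sd <= 0:
                fixed = int(np.clip(np.rint(mu), QMIN, QMAX))
                pmf[c, fixed - QMIN] = 1.0
                continue
            upper = norm.cdf(qs + 0.5, loc=mu, scale=sd)
            lower = norm.cdf(qs - 0.5, loc=mu, scale=sd)
            p = upper - lower
            p[0] = upper[0]  # everything below the clamp collapses to QMIN
            p[-1] = 1.0 - lower[-1]
            pmf[c] = p
        return pmf

    def mean_error_prob(self) -> float:
        """E[10^(-Q/10)] under the exact sampled quality distribution."""
        qs = np.arange(QMIN, QMAX + 1)
        per_cycle = self.quality_pmf() @ (10.0 ** (-qs / 10.0))
        return float(per_cycle.mean())


def calibrate_error_scale(qmodel: QualityModel, error_rate: float) -> float:
    """Scale c with mean(c * 10^(-Q/10)) = error_rate over the quality model."""
    if not 0 <= error_rate < 1:
        raise ValueError(f"error rate must be in [0, 1), got {error_rate}")
    if error_rate == 0:
        return 0.0
    return error_rate / qmodel.mean_error_prob()


@dataclass
class ReadRecord:
    """One simulated read with its truth coordinates on the source haplotype."""

    name: str
    sequence: str
    qualities: str  # Phred+33
    fragment_id: int
    hap: int
    contig: str
    ref_start: int  # 0-based on the haplotype contig
    ref_end: int
    strand: str  # '+' or '-'
    barcode_seq: Optional[str] = None  # 30-mer, only when BX tagging is on


@dataclass
class ReadPairRecord:
    mate1: ReadRecord
    mate2: ReadRecord

    @property
    def insert(self) -> int:
        return self.mate2.ref_end - self.mate1.ref_start


def read_budget(cr: float, v: float, rl: int) -> int:
    """Total number of individual reads: round(CR x V / RL)."""
    if cr < 0 or v < 0:
        raise ValueError("CR and V must be non-negative")
    if rl < 1:
        raise ValueError(f"RL must be >= 1, got {rl}")
    return int(np.rint(cr * v / rl))


def reads_for_fragment(cr: float, fragment_length: int, rl: int) -> int:
    """Per-fragment read budget n_f = round(CR x length_f / RL)."""
    return int(np.rint(cr * fragment_length / rl))


def _inject_errors(seq_mat: np.ndarray, qual_mat: np.ndarray, scale: float, rng) -> None:
    """Substitute bases in place with p = min(scale * 10^(-Q/10), cap)."""
    if scale <= 0 or seq_mat.size == 0:
        return
    p = np.minimum(scale * 10.0 ** (-qual_mat / 10.0), _P_CAP)
    hit = rng.random(seq_mat.shape) < p
    hit &= _BASE_INDEX[seq_mat] != 255  # never substitute N
    n_hits = int(hit.sum())
    if n_hits == 0:
        return
    shift = rng.integers(1, 4, n_hits).astype(np.uint8)
    idx = _BASE_INDEX[seq_mat[hit]]
    seq_mat[hit] = _INDEX_BASE[(idx + shift) % 4]


def apply_errors(
    sequence: str,
    qualities: Sequence[int],
    error_rate: float,
    seed: int = 0,
    scale: Optional[float] = None,
) -> str:
    """Apply quality-driven substitution errors to one sequence.

    When ``scale`` is None it is calibrated against the supplied qualities so
    their mean error probability equals ``error_rate``; library simulation
    instead calibrates once per run against the quality model (see
    :func:`calibrate_error_scale`) and passes the resulting scale in.
    """
    quals = np.asarray(qualities, dtype=np.int64)
    if len(sequence) != quals.size:
        raise ValueError("sequence and qualities must have equal length")
    if not 0 <= error_rate < 1:
        raise ValueError(f"error rate must be in [0, 1), got {error_rate}")
    if error_rate == 0:
        return sequence
    if scale is None:
        scale = error_rate / float(np.mean(10.0 ** (-quals / 10.0)))
    mat = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()[None, :]
    _inject_errors(mat, quals[None, :], scale, np.random.default_rng(seed))
    return bytes(mat[0]).decode("ascii")


def _phred_string(qual_row: np.ndarray) -> str:
    return bytes((qual_row + 33).astype(np.uint8)).decode("ascii")


def _fragment_rng(params: ReadParams, fragment: Fragment):
    # Child stream per fragment: reads of one fragment are invariant to the
    # rest of the library.
    return np.random.default_rng([params.seed, 3, fragment.id])


def simulate_pe_reads(
    fragment: Fragment,
    genome: DiploidGenome,
    params: ReadParams,
    qmodel: Optional[QualityModel] = None,
    scale: Optional[float] = None,
    serial_start: int = 0,
    barcode_tag: str = "0_0_0",
    barcode_seq: Optional[str] = None,
    rng=None,
) -> List[ReadPairRecord]:
    """Paired-end reads over one fragment (FR orientation, normal inserts).

    Fragments shorter than 2 RL yield no pairs (the caller counts them as
    skipped). Inserts are clamped to [2 RL, fragment length], so fragments
    shorter than the drawn insert still contribute full-span pairs.
    """
    if qmodel is None:
        qmodel = QualityModel.default(params.rl)
    if scale is None:
        scale = calibrate_error_scale(qmodel, params.error_rate)
    rl = params.rl
    flen = fragment.length
    n_reads = reads_for_fragment(params.cr, flen, rl)
    if flen < 2 * rl or n_reads == 0:
        return []
    n_pairs = max(1, int(np.rint(n_reads / 2)))
    if rng is None:
        rng = _fragment_rng(params, fragment)

    inserts = np.clip(
        np.rint(rng.normal(params.mu_is, params.sigma_is, n_pairs)).astype(np.int64),
        2 * rl,
        flen,
    )
    starts = rng.integers(0, flen - inserts + 1)

    frag_seq = genome.haplotype(fragment.hap)[fragment.contig][
        fragment.start : fragment.end
    ]
    frag_arr = np.frombuffer(frag_seq.encode("ascii"), dtype=np.uint8)
    offsets = np.arange(rl)
    m1 = frag_arr[starts[:, None] + offsets].copy()
    m2 = _COMP[frag_arr[(starts + inserts - rl)[:, None] + offsets]][:, ::-1].copy()
    quals = qmodel.sample(rng, 2 * n_pairs)
    seq_mat = np.concatenate([m1, m2], axis=0)
    _inject_errors(seq_mat, quals, scale, rng)

    pairs = []
    for i in range(n_pairs):
        serial = serial_start + i
        s, ins = int(starts[i]), int(inserts[i])
        a1 = fragment.start + s
        a2 = fragment.start + s + ins - rl
        mate1 = ReadRecord(
            name=f"S{serial}#{barcode_tag}/1",
            sequence=bytes(seq_mat[i]).decode("ascii"),
            qualities=_phred_string(quals[i]),
            fragment_id=fragment.id,
            hap=fragment.hap,
            contig=fragment.contig,
            ref_start=a1,
            ref_end=a1 + rl,
            strand="+",
            barcode_seq=barcode_seq,
        )
        mate2 = ReadRecord(
            name=f"S{serial}#{barcode_tag}/2",
            sequence=bytes(seq_mat[n_pairs + i]).decode("ascii"),
            qualities=_phred_string(quals[n_pairs + i]),
            fragment_id=fragment.id,
            hap=fragment.hap,
            contig=fragment.contig,
            ref_start=a2,
            ref_end=a2 + rl,
            strand="-",
            barcode_seq=barcode_seq,
        )
        pairs.append(ReadPairRecord(mate1=mate1, mate2=mate2))
    return pairs


def simulate_se_reads(
    fragment: Fragment,
    genome: DiploidGenome,
    params: ReadParams,
    qmodel: Optional[QualityModel] = None,
    scale: Optional[float] = None,
    serial_start: int = 0,
    barcode_tag: str = "0_0_0",
    barcode_seq: Optional[str] = None,
    rng=None,
) -> List[ReadRecord]:
    """Single-end fixed-length reads over one fragment, fair-coin strand."""
    if qmodel is None:
        qmodel = QualityModel.default(params.rl)
    if scale is None:
        scale = calibrate_error_scale(qmodel, params.error_rate)
    rl = params.rl
    flen = fragment.length
    if flen < rl:
        return []
    n_reads = reads_for_fragment(params.cr, flen, rl)
    if n_reads == 0:
        return []
    if rng is None:
        rng = _fragment_rng(params, fragment)

    starts = rng.integers(0, flen - rl + 1, n_reads)
    reverse = rng.random(n_reads) < 0.5
    frag_seq = genome.haplotype(fragment.hap)[fragment.contig][
        fragment.start : fragment.end
    ]
    frag_arr = np.frombuffer(frag_seq.encode("ascii"), dtype=np.uint8)
    seq_mat = frag_arr[starts[:, None] + np.arange(rl)].copy()
    seq_mat[reverse] = _COMP[seq_mat[reverse]][:, ::-1]
    quals = qmodel.sample(rng, n_reads)
    _inject_errors(seq_mat, quals, scale, rng)

    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        a = fragment.start + s
        reads.append(
            ReadRecord(
                name=f"S{serial_start + i}#{barcode_tag}",
                sequence=bytes(seq_mat[i]).decode("ascii"),
                qualities=_phred_string(quals[i]),
                fragment_id=fragment.id,
                hap=fragment.hap,
                contig=fragment.contig,
                ref_start=a,
                ref_end=a + rl,
                strand="-" if reverse[i] else "+",
                barcode_seq=barcode_seq,
            )
        )
    return reads


class _DeterministicGzipText:
    """Gzip text writer with fixed mtime/filename: identical content in,
    identical bytes out."""

    def __init__(self, path):
        self._raw = open(path, "wb")
        self._gz = gzip.GzipFile(filename="", mode="wb", fileobj=self._raw, mtime=0)
        self._text = io.TextIOWrapper(self._gz, encoding="ascii", newline="\n")

    def write(self, s: str):
        self._text.write(s)

    def close(self):
        self._text.close()
        self._raw.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


TRUTH_COLUMNS = ("name", "hap", "contig", "start", "end", "strand", "fragment_id")


class FastqWriter:
    """Streaming FASTQ (+ optional truth sidecar) writer for one library.

    PE mode writes <prefix>_1.fq.gz and <prefix>_2.fq.gz in matched order;
    SE mode writes <prefix>.fq.gz. The sidecar is a plain TSV with one row per
    read giving its truth coordinates for aligner-free verification.
    """

    def __init__(self, out_prefix, mode: str, truth_sidecar: bool = True, bx_tag: bool = False):
        self.mode = mode
        self.bx_tag = bx_tag
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        if mode == "PE":
            self.paths = [Path(f"{prefix}_1.fq.gz"), Path(f"{prefix}_2.fq.gz")]
            self._out = [_DeterministicGzipText(p) for p in self.paths]
        else:
            self.paths = [Path(f"{prefix}.fq.gz")]
            self._out = [_DeterministicGzipText(self.paths[0])]
        self.truth_path = Path(f"{prefix}.truth.tsv") if truth_sidecar else None
        self._truth = None
        if self.truth_path is not None:
            self._truth = open(self.truth_path, "wt")
            self._truth.write("\t".join(TRUTH_COLUMNS) + "\n")
        self.n_reads = 0

    def _fastq_block(self, read: ReadRecord) -> str:
        header = f"@{read.name}"
        if self.bx_tag and read.barcode_seq:
            header += f" BX:Z:{read.barcode_seq}"
        return f"{header}\n{read.sequence}\n+\n{read.qualities}\n"

    def _truth_row(self, read: ReadRecord) -> str:
        return (
            f"{read.name}\t{read.hap}\t{read.contig}\t{read.ref_start}\t"
            f"{read.ref_end}\t{read.strand}\t{read.fragment_id}\n"
        )

    def write_read(self, read: ReadRecord) -> None:
        self._out[0].write(self._fastq_block(read))
        if self._truth:
            self._truth.write(self._truth_row(read))
        self.n_reads += 1

    def write_pair(self, pair: ReadPairRecord) -> None:
        self._out[0].write(self._fastq_block(pair.mate1))
        self._out[1].write(self._fastq_block(pair.mate2))
        if self._truth:
            self._truth.write(self._truth_row(pair.mate1))
            self._truth.write(self._truth_row(pair.mate2))
        self.n_reads += 2

    def close(self):
        for out in self._out:
            out.close()
        if self._truth:
            self._truth.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def emit_fastq(
    records: Sequence[Union[ReadRecord, ReadPairRecord]],
    out_prefix,
    params: ReadParams,
    truth_sidecar: bool = True,
    bx_tag: bool = False,
) -> dict:
    """Write a record list to gzip FASTQ; returns the output paths."""
    with FastqWriter(out_prefix, params.mode, truth_sidecar, bx_tag) as writer:
        for rec in records:
            if isinstance(rec, ReadPairRecord):
                writer.write_pair(rec)
            else:
                writer.write_read(rec)
        return {
            "fastq": [str(p) for p in writer.paths],
            "truth": str(writer.truth_path) if writer.truth_path else None,
            "n_reads": writer.n_reads,
        }


def read_truth_sidecar(path) -> dict:
    """Parse a truth sidecar into name -> row dict."""
    out = {}
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected sidecar header {header}")
        for line in fh:
            name, hap, contig, start, end, strand, fid = line.rstrip("\n").split("\t")
            out[name] = {
                "hap": int(hap),
                "contig": contig,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "fragment_id": int(fid),
            }
    return out
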