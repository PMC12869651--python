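"""Library types, the Exp1-Exp12 parameter grid, and hybrid libraries.

Four library types are supported: plain Illumina paired-end (PE100_NGS,
barcoding disabled), barcoded paired-end (PE100_stLFR), and barcoded
single-end with extended read lengths (SE500_stLFR, SE1000_stLFR). Total read
coverage factors as CF x CR, so a 35x library can spend its budget on many
lightly-sequenced molecules (CF=350, CR=0.1) or fewer deeply-sequenced ones
(CF=47, CR=0.75). The twelve presets cross that CF-CR grid with mean fragment
lengths of 50, 75 and 100 kb; insert size 600 bp, error rate 1% and NFL=1
are held fixed. 70x presets double CF and keep CR.

Hybrid libraries merge two independently simulated libraries at FASTQ level
with per-source read-name prefixes so the merged read set has globally unique
names and a manifest recording each read's origin.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .fragments import FragmentPlan
from .reads import ReadParams, _DeterministicGzipText

LIBRARY_TYPES = {
    "PE100_NGS": {"mode": "PE", "rl": 100, "barcode_on": False},
    "PE100_stLFR": {"mode": "PE", "rl": 100, "barcode_on": True},
    "SE500_stLFR": {"mode": "SE", "rl": 500, "barcode_on": True},
    "SE1000_stLFR": {"mode": "SE", "rl": 1000, "barcode_on": True},
}

# CF-CR pairs for 35x total coverage, from (350, 0.1) to (47, 0.75). The last
# pair multiplies to 35.25x; it is stored as conventionally quoted and the
# config reports the achieved product.
CF_CR_GRID_35X = ((350, 0.1), (140, 0.25), (70, 0.5), (47, 0.75))
MU_FL_BY_GROUP = (50_000, 75_000, 100_000)  # Exp1-4, Exp5-8, Exp9-12


@dataclass
class SimulationConfig:
    """Full parameter set of one simulated library."""

    library_type: str
    cf: float
    cr: float
    mu_fl: float
    rl: int
    mode: str
    barcode_on: bool
    mu_is: float = 600.0
    sigma_is: Optional[float] = None
    error_rate: float = 0.01
    nfl: int = 1
    min_fl: int = 1000
    seed: int = 0
    bx_tag: bool = False

    def __post_init__(self):
        if self.library_type not in LIBRARY_TYPES:
            raise ValueError(
                f"unknown library type {self.library_type!r}; "
                f"choose from {sorted(LIBRARY_TYPES)}"
            )
        spec = LIBRARY_TYPES[self.library_type]
        if (self.mode, self.rl, self.barcode_on) != (
            spec["mode"],
            spec["rl"],
            spec["barcode_on"],
        ):
            raise ValueError(
                f"{self.library_type} fixes mode={spec['mode']}, RL={spec['rl']}, "
                f"barcode_on={spec['barcode_on']}"
            )
        if self.sigma_is is None:
            self.sigma_is = 0.1 * self.mu_is

    @property
    def total_coverage(self) -> float:
        """Achieved total read coverage CF x CR."""
        return self.cf * self.cr

    def to_fragment_plan(self) -> FragmentPlan:
        return FragmentPlan(
            cf=self.cf, mu_fl=self.mu_fl, min_fl=self.min_fl, seed=self.seed
        )

    def to_read_params(self) -> ReadParams:
        return ReadParams(
            mode=self.mode,
            rl=self.rl,
            cr=self.cr,
            mu_is=self.mu_is,
            sigma_is=self.sigma_is,
            error_rate=self.error_rate,
            barcode_on=self.barcode_on,
            seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "wt") as out:
            yaml.safe_dump(data, out, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "rt") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def make_config(library_type: str, **kwargs) -> SimulationConfig:
    """Build a config for a library type, filling mode/RL/barcoding from it."""
    if library_type not in LIBRARY_TYPES:
        raise ValueError(
            f"unknown library type {library_type!r}; choose from {sorted(LIBRARY_TYPES)}"
        )
    spec = LIBRARY_TYPES[library_type]
    kwargs.setdefault("mode", spec["mode"])
    kwargs.setdefault("rl", spec["rl"])
    kwargs.setdefault("barcode_on", spec["barcode_on"])
    return SimulationConfig(library_type=library_type, **kwargs)


def preset(
    exp_id: int,
    library_type: str,
    total_coverage: int = 35,
    seed: int = 0,
) -> SimulationConfig:
    """Experiment preset Exp1..Exp12 for one library type at 35x or 70x.

    Within each group of four the CF-CR pairs run (350,0.1), (140,0.25),
    (70,0.5), (47,0.75); mu_FL is 50/75/100 kb for groups 1-3. At 70x the CF
    values are doubled with CR unchanged.
    """
    if not 1 <= exp_id <= 12:
        raise ValueError(f"exp_id must be 1..12, got {exp_id}")
    if total_coverage not in (35, 70):
        raise ValueError(f"total_coverage must be 35 or 70, got {total_coverage}")
    cf, cr = CF_CR_GRID_35X[(exp_id - 1) % 4]
    if total_coverage == 70:
        cf *= 2
    mu_fl = MU_FL_BY_GROUP[(exp_id - 1) // 4]
    return make_config(
        library_type,
        cf=float(cf),
        cr=float(cr),
        mu_fl=float(mu_fl),
        seed=seed,
    )


def _open_fastq_auto(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    return gzip.open(path, "rt") if magic == b"\x1f\x8b" else open(path, "rt")


def _copy_renamed(src_path, out, prefix: str, seen: set, manifest, source_label: str) -> int:
    """Stream FASTQ records, prefixing read names; returns records copied."""
    n = 0
    with _open_fastq_auto(src_path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"{src_path}: truncated FASTQ record")
            body = header[1:].rstrip("\n")
            name, sep, comment = body.partition(" ")
            new_name = prefix + name
            if new_name in seen:
                raise RuntimeError(
                    f"read name collision after prefixing: {new_name!r}"
                )
            seen.add(new_name)
            out.write(f"@{new_name}{sep}{comment}\n{seq}{plus}{qual}")
            manifest.write(f"{new_name}\t{source_label}\t{src_path}\n")
            n += 1
    return n


def build_hybrid(
    library_a: Sequence, library_b: Sequence, out_prefix
) -> dict:
    """Merge two emitted libraries into one hybrid library at FASTQ level.

    ``library_a``/``library_b`` are the FASTQ path lists of each source
    library ([R1, R2] for PE, [reads] for SE). Read names are re-prefixed
    "A"/"B" for global uniqueness; barcode tags are untouched within each
    source but namespaced by the prefix (the two libraries were barcoded
    independently). Same-arity inputs merge elementwise (_1/_2 or single
    file); a PE+SE mix keeps the pair files and adds an _se file. A manifest
    records the source of every read.
    """
    library_a = [str(p) for p in library_a]
    library_b = [str(p) for p in library_b]
    for paths, label in ((library_a, "A"), (library_b, "B")):
        if len(paths) not in (1, 2):
            raise ValueError(f"library {label}: expected 1 or 2 FASTQ files, got {len(paths)}")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(f"{prefix}.hybrid_manifest.tsv")
    seen: set = set()
    outputs = []
    n_reads = 0
    with open(manifest_path, "wt") as manifest:
        manifest.write("name\tsource\tsource_file\n")
        if len(library_a) == len(library_b):
            suffixes = ["_1.fq.gz", "_2.fq.gz"] if len(library_a) == 2 else [".fq.gz"]
            for i, suffix in enumerate(suffixes):
                path = Path(f"{prefix}{suffix}")
                with _DeterministicGzipText(path) as out:
                    n_reads += _copy_renamed(library_a[i], out, "A", seen, manifest, "A")
                    n_reads += _copy_renamed(library_b[i], out, "B", seen, manifest, "B")
                outputs.append(str(path))
        else:
            pe, pe_label = (library_a, "A") if len(library_a) == 2 else (library_b, "B")
            se, se_label = (library_b, "B") if len(library_a) == 2 else (library_a, "A")
            for i, suffix in enumerate(["_1.fq.gz", "_2.fq.gz"]):
                path = Path(f"{prefix}{suffix}")
                with _DeterministicGzipText(path) as out:
                    n_reads += _copy_renamed(pe[i], out, pe_label, seen, manifest, pe_label)
                outputs.append(str(path))
            path = Path(f"{prefix}_se.fq.gz")
            with _DeterministicGzipText(path) as out:
                n_reads += _copy_renamed(se[0], out, se_label, seen, manifest, se_label)
            outputs.append(str(path))
    return {"fastq": outputs, "manifest": str(manifest_path), "n_reads": n_reads}
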