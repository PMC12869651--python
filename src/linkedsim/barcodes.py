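"""stLFR combinatorial barcoding.

stLFR chemistry tags each long DNA molecule with an ordered triple of 10-mer
barcodes drawn from a fixed whitelist of 1536 sequences (three successive
ligation rounds, each choosing one 10-mer). With replacement within a triple
the combination space holds 1536^3 = 3,623,878,656 distinct 30-mers. Because
the bead chemistry captures one molecule per partition, the assignment is one
fragment per barcode triple (the ``nfl`` knob relaxes this to k fragments per
partition to emulate droplet-style collisions).

The real whitelist is proprietary to the platform; :func:`build_default_whitelist`
generates a deterministic stand-in with minimum pairwise Hamming distance 2,
and :func:`load_whitelist` accepts the genuine list when the user has it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .errors import BarcodeCapacityError, WhitelistFormatError
from .fragments import Fragment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_WHITELIST_SIZE = 1536
BARCODE_LENGTH = 10


@dataclass(frozen=True)
class BarcodeWhitelist:
    """Ordered list of distinct 10-mer barcode sequences."""

    entries: tuple

    @property
    def size(self) -> int:
        return len(self.entries)

    def __post_init__(self):
        seen = set()
        for i, bc in enumerate(self.entries):
            if len(bc) != BARCODE_LENGTH or set(bc) - set("ACGT"):
                raise WhitelistFormatError(
                    f"entry {i + 1}: {bc!r} is not a 10-mer over A,C,G,T"
                )
            if bc in seen:
                raise WhitelistFormatError(f"entry {i + 1}: duplicate barcode {bc!r}")
            seen.add(bc)


@dataclass(frozen=True)
class BarcodeTriple:
    """Ordered triple of 1-based whitelist indices; renders as "i1_i2_i3"."""

    i1: int
    i2: int
    i3: int

    @property
    def tag(self) -> str:
        return f"{self.i1}_{self.i2}_{self.i3}"

    @classmethod
    def from_tag(cls, tag: str) -> "BarcodeTriple":
        parts = tag.split("_")
        if len(parts) != 3:
            raise ValueError(f"not a barcode tag: {tag!r}")
        return cls(int(parts[0]), int(parts[1]), int(parts[2]))

    def sequence(self, whitelist: BarcodeWhitelist) -> str:
        """The 30-mer obtained by concatenating the three 10-mers."""
        return (
            whitelist.entries[self.i1 - 1]
            + whitelist.entries[self.i2 - 1]
            + whitelist.entries[self.i3 - 1]
        )


def build_default_whitelist(
    seed: int = 0, size: int = DEFAULT_WHITELIST_SIZE
) -> BarcodeWhitelist:
    """Deterministic synthetic whitelist with min pairwise Hamming distance 2.

    Candidates are uniform random 10-mers; a candidate within Hamming
    distance 1 of any accepted barcode is rejected (rejection sampling).
    """
    rng = np.random.default_rng(seed)
    accepted = np.empty((size, BARCODE_LENGTH), dtype=np.uint8)
    n = 0
    while n < size:
        cand = _BASES[rng.integers(0, 4, BARCODE_LENGTH)]
        if n:
            dist = (accepted[:n] != cand).sum(axis=1)
            if int(dist.min()) < 2:
                continue
        accepted[n] = cand
        n += 1
    entries = tuple(bytes(row).decode("ascii") for row in accepted)
    return BarcodeWhitelist(entries=entries)


def load_whitelist(path) -> BarcodeWhitelist:
    """Load a whitelist file: one 10-mer per line, all distinct."""
    entries: List[str] = []
    seen = set()
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            bc = line.strip().upper()
            if not bc:
                continue
            if len(bc) != BARCODE_LENGTH or set(bc) - set("ACGT"):
                raise WhitelistFormatError(
                    f"{path}:{lineno}: {bc!r} is not a 10-mer over A,C,G,T"
                )
            if bc in seen:
                raise WhitelistFormatError(f"{path}:{lineno}: duplicate barcode {bc!r}")
            seen.add(bc)
            entries.append(bc)
    if not entries:
        raise WhitelistFormatError(f"{path}: empty whitelist")
    return BarcodeWhitelist(entries=tuple(entries))


def write_whitelist(whitelist: BarcodeWhitelist, path) -> None:
    with open(path, "wt") as out:
        for bc in whitelist.entries:
            out.write(bc + "\n")


def combination_space_size(whitelist: BarcodeWhitelist) -> int:
    """Number of distinct ordered triples (with replacement): size^3."""
    return whitelist.size**3


def _decode(code: int, size: int) -> BarcodeTriple:
    return BarcodeTriple(
        i1=code // (size * size) + 1,
        i2=(code // size) % size + 1,
        i3=code % size + 1,
    )


def sample_triples(n: int, whitelist: BarcodeWhitelist, rng) -> List[BarcodeTriple]:
    """Sample n distinct triples uniformly without replacement from the space.

    Implemented by drawing integer codes in [0, size^3) and rejecting repeats;
    demand is far below the space in any realistic run, so rejections are rare.
    """
    space = combination_space_size(whitelist)
    if n > space:
        raise BarcodeCapacityError(
            f"need {n} distinct barcode triples but the combination space "
            f"holds only {space}"
        )
    seen: Dict[int, None] = {}
    while len(seen) < n:
        for code in rng.integers(0, space, max(64, n - len(seen))):
            code = int(code)
            if code not in seen:
                seen[code] = None
                if len(seen) == n:
                    break
    return [_decode(code, whitelist.size) for code in seen]


def assign_barcodes(
    fragments: Sequence[Fragment],
    whitelist: BarcodeWhitelist,
    nfl: int = 1,
    seed: int = 0,
) -> Dict[int, BarcodeTriple]:
    """Assign one distinct barcode triple per partition of ``nfl`` fragments.

    With nfl=1 (stLFR behaviour) the mapping is a bijection between fragments
    and triples. With nfl=k fragments are randomly grouped into partitions of
    size k (the last partition may be smaller) and each partition shares one
    triple. Triples are sampled uniformly without replacement. Fragments'
    ``barcode`` fields are set in place; the fragment-id -> triple mapping is
    returned.
    """
    if nfl < 1:
        raise ValueError(f"NFL must be >= 1, got {nfl}")
    n_partitions = math.ceil(len(fragments) / nfl) if fragments else 0
    space = combination_space_size(whitelist)
    if n_partitions > space:
        raise BarcodeCapacityError(
            f"{len(fragments)} fragments at NFL={nfl} need {n_partitions} "
            f"partitions but the combination space holds only {space}"
        )
    rng = np.random.default_rng([seed, 17])
    triples = sample_triples(n_partitions, whitelist, rng)
    order = rng.permutation(len(fragments))
    mapping: Dict[int, BarcodeTriple] = {}
    for slot, frag_idx in enumerate(order):
        frag = fragments[int(frag_idx)]
        triple = triples[slot // nfl]
        frag.barcode = triple
        mapping[frag.id] = triple
    return mapping
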