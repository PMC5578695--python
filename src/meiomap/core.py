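"""Domain types for four-spore tetrad genotype data.

A tetrad is the set of four haploid spores from one meiosis of a hybrid
diploid (two sequenced parental backgrounds, labelled P1 and P2).  Each
spore is genotyped at every SNP marker that distinguishes the parents, so
a chromosome's data is a 4 x M matrix of parental-origin calls.  Normal
Mendelian segregation gives 2:2 at every marker; deviations (3:1, 1:3,
4:0, 0:4) mark gene-conversion tracts, and changes in *which* two spores
carry the P1 allele between consecutive 2:2 markers mark crossovers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

# Per-call codes in genotype matrices (int8).
MISSING = 0
P1 = 1
P2 = 2

# Segregation classes.
SEG_2_2 = "2:2"
SEG_3_1 = "3:1"
SEG_1_3 = "1:3"
SEG_4_0 = "4:0"
SEG_0_4 = "0:4"
SEG_INCOMPLETE = "INCOMPLETE"

ABERRANT_CLASSES = frozenset({SEG_4_0, SEG_0_4})

#: Default S. cerevisiae chromosome lengths (bp), sacCer3 assembly.
YEAST_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chrI", 230218),
    ("chrII", 813184),
    ("chrIII", 316620),
    ("chrIV", 1531933),
    ("chrV", 576874),
    ("chrVI", 270161),
    ("chrVII", 1090940),
    ("chrVIII", 562643),
    ("chrIX", 439888),
    ("chrX", 745751),
    ("chrXI", 666816),
    ("chrXII", 1078177),
    ("chrXIII", 924431),
    ("chrXIV", 784333),
    ("chrXV", 1091291),
    ("chrXVI", 948066),
)


@dataclass(frozen=True)
class GenomeMap:
    """Ordered chromosome names and lengths (bp).

    Chromosomes are binned into the conventional yeast size classes:
    small (<0.5 Mb), medium (0.5-0.9 Mb) and large (>0.9 Mb).
    """

    chromosomes: tuple[tuple[str, int], ...] = YEAST_CHROMOSOMES

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")
        object.__setattr__(self, "chromosomes", tuple(map(tuple, self.chromosomes)))

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def size_class(self, chrom: str) -> str:
        """'small' (<0.5 Mb), 'medium' (0.5-0.9 Mb) or 'large' (>0.9 Mb)."""
        length = self.length(chrom)
        if length < 500_000:
            return "small"
        if length <= 900_000:
            return "medium"
        return "large"


@dataclass(frozen=True)
class MarkerMap:
    """Sorted SNP marker positions (1-based bp) per chromosome."""

    positions: Mapping[str, np.ndarray]
    parents: tuple[str, str] = ("P1", "P2")

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: positions must be 1-D")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            clean[chrom] = arr
        object.__setattr__(self, "positions", clean)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def n_markers(self, chrom: str) -> int:
        return int(self.positions[chrom].size)


@dataclass
class Tetrad:
    """Four-spore genotype matrices, one 4 x M int8 matrix per chromosome."""

    id: str
    genotypes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, mat in self.genotypes.items():
            mat = np.asarray(mat, dtype=np.int8)
            if mat.ndim != 2 or mat.shape[0] != 4:
                raise ValueError(f"{chrom}: genotype matrix must be 4 x M")
            self.genotypes[chrom] = mat

    def matrix(self, chrom: str) -> np.ndarray:
        try:
            return self.genotypes[chrom]
        except KeyError:
            raise KeyError(f"tetrad {self.id}: no chromosome {chrom!r}") from None

    def copy(self) -> "Tetrad":
        return Tetrad(self.id, {c: m.copy() for c, m in self.genotypes.items()})


@dataclass(frozen=True)
class SegregationProfile:
    """Per-marker segregation class, plus the 2:2 phase.

    ``phase[i]`` is the frozenset of spore indices (0-3) carrying the P1
    allele at marker ``i`` when its class is 2:2, otherwise ``None``.
    """

    chrom: str
    positions: np.ndarray
    classes: tuple[str, ...]
    phases: tuple[frozenset | None, ...]

    def __len__(self) -> int:
        return len(self.classes)


def segregation_class(calls: Sequence[int]) -> tuple[str, frozenset | None]:
    """Classify the four parental-origin calls at one marker.

    Returns ``(class, phase)``; ``phase`` — the unordered pair of spore
    indices carrying P1 — is given only for 2:2 markers.  Any MISSING call
    makes the marker INCOMPLETE.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if calls.shape != (4,):
        raise ValueError("exactly 4 spore calls required")
    if np.any(calls == MISSING):
        return SEG_INCOMPLETE, None
    n1 = int(np.sum(calls == P1))
    if n1 == 2:
        return SEG_2_2, frozenset(np.flatnonzero(calls == P1).tolist())
    return {3: SEG_3_1, 1: SEG_1_3, 4: SEG_4_0, 0: SEG_0_4}[n1], None


_CLASS_BY_N1 = (SEG_0_4, SEG_1_3, SEG_2_2, SEG_3_1, SEG_4_0)
_PHASE_BY_CODE = tuple(
    frozenset(i for i in range(4) if c >> i & 1) for c in range(16)
)


def build_profile(tetrad: Tetrad, chrom: str, markers: MarkerMap) -> SegregationProfile:
    """Compute the per-marker segregation profile of one chromosome."""
    mat = tetrad.matrix(chrom)
    pos = markers.positions[chrom]
    if mat.shape[1] != pos.size:
        raise ValueError(
            f"{chrom}: matrix has {mat.shape[1]} markers, map has {pos.size}"
        )
    complete = np.all(mat != MISSING, axis=0)
    is_p1 = mat == P1
    n1 = np.sum(is_p1, axis=0)
    code = (is_p1 * np.array([[1], [2], [4], [8]], dtype=np.int8)).sum(axis=0)
    classes = tuple(
        _CLASS_BY_N1[n] if ok else SEG_INCOMPLETE
        for n, ok in zip(n1.tolist(), complete.tolist())
    )
    phases = tuple(
        _PHASE_BY_CODE[c] if (ok and n == 2) else None
        for c, ok, n in zip(code.tolist(), complete.tolist(), n1.tolist())
    )
    return SegregationProfile(chrom, pos, classes, phases)


def filter_shared_aberrant(
    tetrads: Iterable[Tetrad], markers: MarkerMap
) -> tuple[list[Tetrad], "pd.DataFrame"]:
    """Mask markers with 4:0/0:4 segregation shared between tetrads.

    A marker that segregates 4:0 or 0:4 in two or more tetrads is almost
    certainly a genotyping or marker artifact rather than two independent
    double conversions, and is set to MISSING in *all* tetrads.  Markers
    aberrant in a single tetrad are retained (they feed the two-chromatid
    conversion class downstream).  Returns the filtered tetrads (copies)
    and a removal report with columns (chrom, pos, n_tetrads_aberrant).

    Idempotent: masked markers are INCOMPLETE, never 4:0, on a second pass.
    """
    import pandas as pd

    tetrads = list(tetrads)
    rows = []
    if len(tetrads) < 2:
        warnings.warn("shared-aberrant filter needs >=2 tetrads; no-op")
        report = pd.DataFrame(rows, columns=["chrom", "pos", "n_tetrads_aberrant"])
        return [t.copy() for t in tetrads], report

    out = [t.copy() for t in tetrads]
    for chrom in markers.chromosomes:
        pos = markers.positions[chrom]
        if pos.size == 0:
            continue
        counts = np.zeros(pos.size, dtype=int)
        for t in out:
            mat = t.matrix(chrom)
            complete = np.all(mat != MISSING, axis=0)
            n1 = np.sum(mat == P1, axis=0)
            counts += complete & ((n1 == 4) | (n1 == 0))
        shared = np.flatnonzero(counts >= 2)
        for j in shared:
            rows.append({"chrom": chrom, "pos": int(pos[j]), "n_tetrads_aberrant": int(counts[j])})
            for t in out:
                t.matrix(chrom)[:, j] = MISSING
    report = pd.DataFrame(rows, columns=["chrom", "pos", "n_tetrads_aberrant"])
    return out, report
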