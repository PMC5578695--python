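"""Classical yeast genetics assays.

Four small, self-contained analyses used alongside genome-wide mapping:

* scoring fluorescent-spore tetrads (RFP/CFP markers in repulsion on one
  chromosome arm) as parental ditype / tetratype / nonparental ditype
  and the percent-tetratype crossover proxy;
* Perkins tetrad map distances, cM = 100 (TT/2 + 3 NPD) / n, with a
  standard error from the per-tetrad score decomposition;
* spore-viability distributions from dissected tetrads, including the
  meiosis-I nondisjunction signature (excess of 4-, 2- and 0-viable
  tetrads over 3- and 1-viable ones);
* Luria-Delbruck fluctuation analysis of reversion rates by the
  Lea-Coulson method of the median, with order-statistic confidence
  intervals and a wild-type/null phenotype call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

PD, TT, NPD, ABERRANT = "PD", "TT", "NPD", "aberrant"

PHENOTYPE_WT = "+"
PHENOTYPE_INTERMEDIATE = "±"
PHENOTYPE_NULL = "−"
PHENOTYPE_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TetradTypeCounts:
    """PD/TT/NPD tallies for one two-marker interval."""

    pd: int
    tt: int
    npd: int

    def __post_init__(self) -> None:
        if min(self.pd, self.tt, self.npd) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_scored(self) -> int:
        return self.pd + self.tt + self.npd


@dataclass(frozen=True)
class MapDistance:
    cm: float
    se: float


@dataclass(frozen=True)
class FluctuationResult:
    """Mutation-rate estimate from parallel cultures.

    ``m`` is the expected number of mutations per culture; ``rate`` is
    per cell per generation (m / cells per culture); ``ci95`` brackets
    the rate.  ``below_detection`` marks an all-zero median (rate is
    then an upper bound from m solved at the smallest resolvable count).
    """

    median_revertants: float
    m: float
    rate: float
    ci95: tuple[float, float]
    n_cultures: int
    below_detection: bool = False


@dataclass(frozen=True)
class ViabilityStats:
    n_tetrads: int
    class_freq: tuple[float, float, float, float, float]  # 4,3,2,1,0 viable
    percent_sv: float
    mi_nd_index: float  # fraction of tetrads in the {4,2,0} classes


def type_fluorescent_tetrad(
    spores: Sequence[tuple[bool, bool]]
) -> str:
    """Score one fluorescent tetrad as PD, TT, NPD or aberrant.

    Each spore is an ``(RFP, CFP)`` presence pair; the parental
    configuration has the markers in repulsion (R-/-C), so a parental
    ditype is {R, R, C, C}, a tetratype {R, C, RC, none} and a
    nonparental ditype {RC, RC, none, none}.  Any other pattern (e.g.
    nondisjunction) is aberrant.
    """
    if len(spores) != 4:
        raise ValueError("a tetrad has exactly 4 spores")
    pattern = sorted((bool(r), bool(c)) for r, c in spores)
    if pattern == sorted([(True, False)] * 2 + [(False, True)] * 2):
        return PD
    if pattern == sorted(
        [(True, False), (False, True), (True, True), (False, False)]
    ):
        return TT
    if pattern == sorted([(True, True)] * 2 + [(False, False)] * 2):
        return NPD
    return ABERRANT


def count_fluorescent_tetrads(
    tetrads: Sequence[Sequence[tuple[bool, bool]]], score_npd: bool = False
) -> TetradTypeCounts:
    """Tally fluorescent tetrads.

    The fluorescent assay cannot distinguish NPDs from meiosis-I
    nondisjunction, so by default NPD patterns are excluded from the
    scored total (``score_npd=True`` retains them).
    """
    tally = {PD: 0, TT: 0, NPD: 0}
    for spores in tetrads:
        t = type_fluorescent_tetrad(spores)
        if t in tally:
            tally[t] += 1
    if not score_npd:
        tally[NPD] = 0
    return TetradTypeCounts(tally[PD], tally[TT], tally[NPD])


def percent_tetratype(counts: TetradTypeCounts) -> float:
    """100 x TT / scored tetrads."""
    if counts.n_scored == 0:
        raise ValueError("no scored tetrads")
    return 100.0 * counts.tt / counts.n_scored


def chi2_tetratype(a: TetradTypeCounts, b: TetradTypeCounts) -> tuple[float, float]:
    """2x2 chi-square (TT vs non-TT), no continuity correction."""
    table = np.array(
        [[a.tt, a.n_scored - a.tt], [b.tt, b.n_scored - b.tt]], dtype=float
    )
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate 2x2 table")
    chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected < 5):
        warnings.warn("chi-square expected cell < 5; p-value approximate")
    return float(chi2), float(p)


def tetratype_phenotype(
    allele: TetradTypeCounts,
    wt: TetradTypeCounts,
    null: TetradTypeCounts,
    alpha: float = 0.01,
) -> str:
    """Classify an allele's crossover proficiency against both controls.

    Indistinguishable from wild-type but not from the null gives "+",
    the reverse gives "−", distinguishable from both "±", and
    distinguishable from neither is indeterminate.
    """
    _, p_wt = chi2_tetratype(allele, wt)
    _, p_null = chi2_tetratype(allele, null)
    differs_wt = p_wt < alpha
    differs_null = p_null < alpha
    if differs_null and not differs_wt:
        return PHENOTYPE_WT
    if differs_wt and not differs_null:
        return PHENOTYPE_NULL
    if differs_wt and differs_null:
        return PHENOTYPE_INTERMEDIATE
    return PHENOTYPE_INDETERMINATE


#: per-tetrad recombination scores underlying the Perkins formula
_PERKINS_SCORES = {PD: 0.0, TT: 0.5, NPD: 3.0}


def perkins_distance(counts: TetradTypeCounts) -> MapDistance:
    """Perkins tetrad map distance, cM = 100 (TT/2 + 3 NPD) / n, with SE.

    The SE treats each tetrad as carrying a score of 0 (PD), 0.5 (TT) or
    3 (NPD): SE = 100 x sd(scores) / sqrt(n).
    """
    n = counts.n_scored
    if n == 0:
        raise ValueError("no scored tetrads")
    cm = 100.0 * (counts.tt / 2.0 + 3.0 * counts.npd) / n
    scores = np.concatenate(
        [
            np.full(counts.pd, _PERKINS_SCORES[PD]),
            np.full(counts.tt, _PERKINS_SCORES[TT]),
            np.full(counts.npd, _PERKINS_SCORES[NPD]),
        ]
    )
    se = 100.0 * float(np.std(scores, ddof=1)) / np.sqrt(n) if n > 1 else float("nan")
    return MapDistance(cm, se)


def viability_stats(viable_counts: Sequence[int]) -> ViabilityStats:
    """Distribution of viable spores per tetrad and derived indices."""
    arr = np.asarray(viable_counts, dtype=int)
    if arr.size == 0:
        raise ValueError("need at least one tetrad")
    if arr.min() < 0 or arr.max() > 4:
        raise ValueError("viable-spore counts must be in 0..4")
    freq = tuple(float(np.mean(arr == k)) for k in (4, 3, 2, 1, 0))
    percent_sv = 100.0 * float(arr.sum()) / (4 * arr.size)
    mi_nd = float(np.mean(np.isin(arr, (4, 2, 0))))
    return ViabilityStats(arr.size, freq, percent_sv, mi_nd)


def chi2_viability(
    a: Sequence[int], b: Sequence[int]
) -> tuple[float, float]:
    """2x2 chi-square on viable vs inviable spores between two strains."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    table = np.array(
        [
            [a.sum(), 4 * a.size - a.sum()],
            [b.sum(), 4 * b.size - b.sum()],
        ],
        dtype=float,
    )
    if np.array_equal(table[0], table[1]):
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# -- fluctuation analysis ---------------------------------------------------


def lea_coulson_m(median_revertants: float) -> float:
    """Solve r = m (1.24 + ln m) for the expected mutations per culture.

    The Lea-Coulson method-of-the-median equation; r = 1.24 gives
    m = 1 exactly.
    """
    r = float(median_revertants)
    if r <= 0:
        raise ValueError("median revertant count must be positive")
    lo = np.exp(-1.24) * 1e-12  # far left of the increasing branch
    lo = max(lo, 1e-12)
    hi = max(4.0, r)
    while hi * (1.24 + np.log(hi)) < r:
        hi *= 2.0
    return float(optimize.brentq(lambda m: m * (1.24 + np.log(m)) - r, lo, hi))


def _median_ci_ranks(n: int, conf: float = 0.95) -> tuple[int, int]:
    """Order-statistic (Dixon-Massey) rank bounds for the median (0-based).

    The largest rank l with P(Binomial(n, 1/2) < l) <= (1-conf)/2 and its
    symmetric partner u = n + 1 - l give coverage >= conf.
    """
    alpha = (1.0 - conf) / 2.0
    l = 1
    while l < n and sps.binom.cdf(l - 1, n, 0.5) <= alpha:
        l += 1
    l = max(l - 1, 1)
    u = n + 1 - l
    return l - 1, u - 1


def fluctuation_rate(
    revertant_counts: Sequence[int], cells_per_culture: float, conf: float = 0.95
) -> FluctuationResult:
    """Lea-Coulson median estimate of the mutation rate with a 95% CI.

    The median revertant count r solves r = m (1.24 + ln m) for the
    expected mutations per culture m; the rate is m divided by the
    number of cells per culture.  The CI takes the nonparametric
    order-statistic bounds on the median and pushes each bound through
    the same transform.  An all-zero median is reported as below the
    detection limit with the rate solved at a half-count bound.
    """
    counts = np.asarray(revertant_counts, dtype=float)
    if counts.size < 5:
        raise ValueError("need at least 5 cultures")
    if cells_per_culture <= 0:
        raise ValueError("cells_per_culture must be > 0")
    med = float(np.median(counts))
    lo_i, hi_i = _median_ci_ranks(counts.size, conf)
    srt = np.sort(counts)
    lo_count, hi_count = float(srt[lo_i]), float(srt[hi_i])

    def to_rate(r: float) -> float:
        if r <= 0:
            return 0.0
        return lea_coulson_m(r) / cells_per_culture

    if med <= 0:
        # below detection: bound by half a revertant at the median
        m = lea_coulson_m(0.5)
        return FluctuationResult(
            med, m, m / cells_per_culture,
            (0.0, to_rate(max(hi_count, 0.5))), counts.size, below_detection=True,
        )
    m = lea_coulson_m(med)
    return FluctuationResult(
        med, m, m / cells_per_culture,
        (to_rate(lo_count), to_rate(max(hi_count, med))), counts.size,
    )


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def rate_phenotype(
    allele: FluctuationResult, wt: FluctuationResult, null: FluctuationResult
) -> tuple[str, float]:
    """Phenotype call by 95%-CI overlap, plus the fold change vs wild type.

    Overlapping the wild-type CI but not the null CI gives "+", the
    reverse "−", neither "±", both indeterminate.
    """
    fold = allele.rate / wt.rate
    with_wt = _overlap(allele.ci95, wt.ci95)
    with_null = _overlap(allele.ci95, null.ci95)
    if with_wt and not with_null:
        return PHENOTYPE_WT, fold
    if with_null and not with_wt:
        return PHENOTYPE_NULL, fold
    if not with_wt and not with_null:
        return PHENOTYPE_INTERMEDIATE, fold
    return PHENOTYPE_INDETERMINATE, fold
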