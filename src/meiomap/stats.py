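"""Genome-wide statistics on classified recombination events.

Count comparisons between genotypes use Welch's two-sided t-test on
per-tetrad means; tract-length comparisons use the Wilcoxon rank-sum
(Mann-Whitney, midranks for ties, normal approximation) or the
two-sample Kolmogorov-Smirnov test; per-chromosome event counts are
regressed on chromosome length by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GenomeMap


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str  # "t", "wilcoxon", "ks" or "chi2"
    statistic: float
    pvalue: float
    labels: tuple[str, str]
    n: tuple[int, int]


@dataclass(frozen=True)
class ChromRegression:
    """OLS fit of per-chromosome mean event count against chromosome length."""

    slope: float  # events per bp
    intercept: float  # events
    per_chrom: pd.DataFrame  # chrom, length, mean, se [, ref_mean, t, p, flagged]


def compare_means(
    a: Sequence[float], b: Sequence[float], labels: tuple[str, str] = ("a", "b")
) -> GroupComparison:
    """Welch two-sided t-test for a difference in per-tetrad means.

    With zero variance in both samples and equal means the test is
    degenerate; t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return GroupComparison("t", 0.0, 1.0, labels, (a.size, b.size))
        return GroupComparison("t", np.inf, 0.0, labels, (a.size, b.size))
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison("t", float(t), float(p), labels, (a.size, b.size))


def compare_tracts(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "wilcoxon",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided rank-sum or KS comparison of tract-length samples.

    Rank-sum ties are handled by midranks with the tie-corrected normal
    approximation (no continuity correction, so identical samples give
    p = 1 exactly).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    if test == "wilcoxon":
        if np.array_equal(np.sort(a), np.sort(b)):
            u = a.size * b.size / 2.0
            return GroupComparison("wilcoxon", u, 1.0, labels, (a.size, b.size))
        u, p = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        return GroupComparison("wilcoxon", float(u), float(p), labels, (a.size, b.size))
    if test == "ks":
        d, p = sps.ks_2samp(a, b)
        return GroupComparison("ks", float(d), float(p), labels, (a.size, b.size))
    raise ValueError(f"unknown test {test!r}")


def per_chrom_regression(
    counts: pd.DataFrame,
    genome: GenomeMap,
    ref_counts: pd.DataFrame | None = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> ChromRegression:
    """Regress per-chromosome mean counts on chromosome length.

    ``counts`` has one row per tetrad and one column per chromosome.
    With ``ref_counts`` (a reference genotype's table) each chromosome is
    additionally compared by a two-sided Welch t-test and flagged at
    p < ``alpha``; an optional Benjamini-Hochberg correction across
    chromosomes is off by default.
    """
    chroms = [c for c in genome.names if c in counts.columns]
    if len(chroms) < 3:
        raise ValueError("need counts for at least 3 chromosomes")
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    means = counts[chroms].mean(axis=0).to_numpy(dtype=float)
    ses = counts[chroms].sem(axis=0).to_numpy(dtype=float)
    fit = sps.linregress(lengths, means)
    per = pd.DataFrame(
        {"chrom": chroms, "length": lengths.astype(int), "mean": means, "se": ses}
    )
    if ref_counts is not None:
        pvals, tvals, refmeans = [], [], []
        for c in chroms:
            cmp = compare_means(counts[c], ref_counts[c], labels=("sample", "ref"))
            tvals.append(cmp.statistic)
            pvals.append(cmp.pvalue)
            refmeans.append(float(np.mean(ref_counts[c])))
        pvals = np.asarray(pvals)
        if bh_correct:
            order = np.argsort(pvals)
            ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            out = np.empty_like(pvals)
            out[order] = np.minimum(adj, 1.0)
            pvals = out
        per["ref_mean"] = refmeans
        per["t"] = tvals
        per["p"] = pvals
        per["flagged"] = pvals < alpha
    return ChromRegression(float(fit.slope), float(fit.intercept), per)


def median_tract(lengths: Sequence[float]) -> float:
    """Median tract length over non-zero tracts.

    Crossovers without a detectable conversion have zero-length tracts;
    those are excluded before taking the median.  Raises ``ValueError``
    when no non-zero tract exists.
    """
    arr = np.asarray(lengths, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("no non-zero tracts; median undefined")
    return float(np.median(arr))


def class_tract_lengths(
    events: pd.DataFrame, groups: pd.DataFrame, cls: str, convention: str = "mid"
) -> np.ndarray:
    """Tract lengths (chosen convention) of tracts in groups of one class.

    ``events`` is the raw-event table (tract rows carry ``tract_min``/
    ``tract_mid``/``tract_max``), ``groups`` the classified group table;
    both carry ``tetrad_id``/``chrom``/``group_id``.
    """
    if convention not in ("min", "mid", "max"):
        raise ValueError("convention must be 'min', 'mid' or 'max'")
    keys = groups.loc[groups["class"] == cls, ["tetrad_id", "chrom", "group_id"]]
    sel = events.merge(keys, on=["tetrad_id", "chrom", "group_id"])
    sel = sel[sel["kind"] == "GC_TRACT"]
    return sel[f"tract_{convention}"].to_numpy(dtype=float)
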