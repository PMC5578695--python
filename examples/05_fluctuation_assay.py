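"""Luria-Delbruck fluctuation analysis of a reversion assay.

Revertant counts from parallel cultures estimate the per-cell,
per-generation mutation rate by the Lea-Coulson method of the median;
rates are normalized to wild type and phenotyped by confidence-interval
overlap (mismatch-repair defects raise the rate severalfold).
"""

from meiomap.assays import fluctuation_rate, rate_phenotype

cells_per_culture = 2e7

wt_counts = [1, 0, 2, 1, 3, 1, 2, 0, 1, 2, 1, 1]
null_counts = [9, 14, 6, 22, 11, 8, 31, 12, 9, 16, 10, 13]
allele_counts = [2, 1, 3, 1, 4, 2, 1, 2, 3, 1, 2, 2]

wt = fluctuation_rate(wt_counts, cells_per_culture)
null = fluctuation_rate(null_counts, cells_per_culture)
allele = fluctuation_rate(allele_counts, cells_per_culture)

for name, r in [("wild type", wt), ("null", null), ("test allele", allele)]:
    print(f"{name:11s} median {r.median_revertants:>4.1f} revertants -> "
          f"rate {r.rate:.2e} (95% CI {r.ci95[0]:.2e} - {r.ci95[1]:.2e})")

call, fold = rate_phenotype(allele, wt, null)
print(f"\nTest allele: {fold:.2f}x the wild-type rate, phenotype {call!r}")
print("('+' = CI overlaps wild type only; a mutator allele would overlap "
      "the null instead)")
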