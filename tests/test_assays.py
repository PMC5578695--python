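"""Classical assays: fluorescent tetrads, Perkins distances, viability,
Luria-Delbruck fluctuation analysis."""

import numpy as np
import pytest

from meiomap import assays as A
from meiomap.assays import (
    FluctuationResult,
    TetradTypeCounts,
    chi2_tetratype,
    chi2_viability,
    count_fluorescent_tetrads,
    fluctuation_rate,
    lea_coulson_m,
    percent_tetratype,
    perkins_distance,
    rate_phenotype,
    tetratype_phenotype,
    type_fluorescent_tetrad,
    viability_stats,
)

R, C, RC, NONE = (True, False), (False, True), (True, True), (False, False)


class TestFluorescentTyping:
    @pytest.mark.parametrize(
        "spores, expected",
        [
            ((R, R, C, C), A.PD),
            ((R, C, RC, NONE), A.TT),
            ((RC, NONE, R, C), A.TT),
            ((RC, RC, NONE, NONE), A.NPD),
            ((R, R, R, C), A.ABERRANT),  # nondisjunction-like
            ((RC, RC, RC, NONE), A.ABERRANT),
        ],
    )
    def test_patterns(self, spores, expected):
        assert type_fluorescent_tetrad(spores) == expected

    def test_npd_excluded_from_scoring_by_default(self):
        tetrads = [(R, R, C, C), (R, C, RC, NONE), (RC, RC, NONE, NONE)]
        counts = count_fluorescent_tetrads(tetrads)
        assert (counts.pd, counts.tt, counts.npd) == (1, 1, 0)
        counts = count_fluorescent_tetrads(tetrads, score_npd=True)
        assert counts.npd == 1


class TestPercentTetratype:
    def test_arithmetic(self):
        assert percent_tetratype(TetradTypeCounts(160, 90, 0)) == 36.0
        assert percent_tetratype(TetradTypeCounts(250, 0, 0)) == 0.0

    def test_zero_scored_rejected(self):
        with pytest.raises(ValueError):
            percent_tetratype(TetradTypeCounts(0, 0, 0))

    def test_20_cm_interval_gives_40_percent_tt(self, rng):
        """With no NPDs, %TT = 2 x map distance: a 20 cM interval yields
        40% tetratypes (binomial check at n = 10^4)."""
        n = 10_000
        p_tt = 2 * 20 / 100
        tt = rng.binomial(n, p_tt)
        counts = TetradTypeCounts(n - tt, tt, 0)
        se = 100 * np.sqrt(p_tt * (1 - p_tt) / n)
        assert abs(percent_tetratype(counts) - 40.0) < 3 * se
        # and the Perkins inverse at NPD = 0
        assert perkins_distance(counts).cm == pytest.approx(
            percent_tetratype(counts) / 2
        )


class TestTetratypePhenotype:
    wt = TetradTypeCounts(158, 92, 0)  # ~36.7% of 250
    null = TetradTypeCounts(210, 40, 0)  # ~16% of 250

    def test_wild_type_like(self):
        allele = TetradTypeCounts(316, 184, 0)
        assert tetratype_phenotype(allele, self.wt, self.null) == A.PHENOTYPE_WT

    def test_null_like(self):
        allele = TetradTypeCounts(420, 80, 0)
        assert tetratype_phenotype(allele, self.wt, self.null) == A.PHENOTYPE_NULL

    def test_intermediate(self):
        """Counts midway between the controls differ from both at p<0.01."""
        allele = TetradTypeCounts(1470, 530, 0)  # 26.5% at n=2000
        wt = TetradTypeCounts(1266, 734, 0)  # 36.7% at n=2000
        null = TetradTypeCounts(1678, 322, 0)  # 16.1% at n=2000
        _, p_wt = chi2_tetratype(allele, wt)
        _, p_null = chi2_tetratype(allele, null)
        assert p_wt < 0.01 and p_null < 0.01
        assert (
            tetratype_phenotype(allele, wt, null) == A.PHENOTYPE_INTERMEDIATE
        )


class TestPerkins:
    def test_formula_examples(self):
        assert perkins_distance(TetradTypeCounts(60, 40, 0)).cm == 20.0
        assert perkins_distance(TetradTypeCounts(48, 50, 2)).cm == 31.0

    def test_npd_zero_equals_half_percent_tt(self):
        counts = TetradTypeCounts(130, 120, 0)
        assert perkins_distance(counts).cm == percent_tetratype(counts) / 2

    def test_se_matches_bootstrap(self, rng):
        """Per-tetrad score SE agrees with a 10^4-resample bootstrap."""
        counts = TetradTypeCounts(48, 50, 2)
        se = perkins_distance(counts).se
        scores = np.concatenate([np.zeros(48), np.full(50, 0.5), np.full(2, 3.0)])
        boots = np.empty(10_000)
        for i in range(10_000):
            boots[i] = 100 * rng.choice(scores, size=100, replace=True).mean()
        assert abs(se - boots.std(ddof=1)) / boots.std(ddof=1) < 0.05

    def test_simulator_round_trip_20_cm(self):
        """Tetrads simulated at 0.4 expected COs per meiosis between two
        markers (= 20 cM, no interference) return 20 cM by Perkins."""
        from meiomap import GenomeMap, MarkerMap, SimParams, sample_events, paint_tetrad

        genome = GenomeMap((("c", 100_000),))
        markers = MarkerMap({"c": np.array([1, 100_000])})
        params = SimParams(
            mean_co_per_meiosis=0.4, interference_shape=1.0,
            mean_detectable_nco=0, p_co_assoc_tract=0,
        )
        rng = np.random.default_rng(1234)
        tally = {0: 0, 2: 0, 4: 0}
        n = 10_000
        for _ in range(n):
            truth = sample_events(params, genome, rng)
            mat = paint_tetrad(truth, markers).matrix("c")
            recomb = int(np.sum(mat[:, 0] != mat[:, 1]))
            tally[recomb] += 1
        counts = TetradTypeCounts(tally[0], tally[2], tally[4])
        d = perkins_distance(counts)
        assert abs(d.cm - 20.0) < 3 * d.se


class TestViability:
    def test_all_viable(self):
        v = viability_stats([4] * 10)
        assert v.percent_sv == 100.0
        assert v.class_freq == (1.0, 0.0, 0.0, 0.0, 0.0)

    def test_mi_nondisjunction_index(self):
        v = viability_stats([4] * 5 + [2] * 5)
        assert v.mi_nd_index == 1.0
        v = viability_stats([3, 1, 3, 1])
        assert v.mi_nd_index == 0.0

    def test_chi2_equal_samples(self):
        chi2, p = chi2_viability([4, 3, 2], [4, 3, 2])
        assert chi2 == 0.0 and p == 1.0

    def test_chi2_detects_viability_drop(self):
        good = [4] * 90 + [3] * 10
        bad = [4] * 40 + [2] * 40 + [0] * 20
        _, p = chi2_viability(good, bad)
        assert p < 1e-6


class TestFluctuation:
    def test_lea_coulson_fixed_point(self):
        """r = 1.24 solves to exactly one mutation per culture."""
        assert lea_coulson_m(1.24) == pytest.approx(1.0, abs=1e-9)
        r = fluctuation_rate([1.24] * 10, 1e8)
        assert r.rate == pytest.approx(1e-8, rel=1e-6)

    def test_all_zero_below_detection(self):
        r = fluctuation_rate([0] * 10, 1e8)
        assert r.below_detection
        assert r.ci95[0] == 0.0

    def test_scale_consistency(self):
        counts = [3, 5, 2, 8, 4, 6, 3, 9, 1, 5]
        r1 = fluctuation_rate(counts, 1e7)
        r2 = fluctuation_rate(counts, 1e8)
        assert r1.rate == pytest.approx(10 * r2.rate)
        assert r1.ci95[1] == pytest.approx(10 * r2.ci95[1])

    def test_ci_contains_rate(self, rng):
        counts = rng.poisson(6, size=20).tolist()
        r = fluctuation_rate(counts, 1e8)
        assert r.ci95[0] <= r.rate <= r.ci95[1]

    def test_needs_five_cultures(self):
        with pytest.raises(ValueError):
            fluctuation_rate([1, 2, 3], 1e7)


class TestRatePhenotype:
    def _res(self, rate, lo, hi):
        return FluctuationResult(1.0, 1.0, rate, (lo, hi), 10)

    def test_fold_normalization_from_published_medians(self):
        """Rates 9.07 and 2.00 (x10^-6) against a wild type of 1.43 give
        fold changes 6.34 and 1.40."""
        wt = self._res(1.43e-6, 1.23e-6, 1.65e-6)
        null = self._res(9.07e-6, 7.4e-6, 10.28e-6)
        _, fold_null = rate_phenotype(null, wt, null)
        assert round(fold_null, 2) == 6.34
        allele32 = self._res(2.00e-6, 1.54e-6, 2.22e-6)
        _, fold32 = rate_phenotype(allele32, wt, null)
        assert round(fold32, 2) == 1.40

    def test_overlap_rules(self):
        wt = self._res(1.4e-6, 1.2e-6, 1.7e-6)
        null = self._res(9.1e-6, 7.4e-6, 10.3e-6)
        assert rate_phenotype(self._res(1.5e-6, 1.3e-6, 1.8e-6), wt, null)[0] == A.PHENOTYPE_WT
        assert rate_phenotype(self._res(8.0e-6, 7.5e-6, 9.0e-6), wt, null)[0] == A.PHENOTYPE_NULL
        assert rate_phenotype(self._res(4.0e-6, 3.0e-6, 5.0e-6), wt, null)[0] == A.PHENOTYPE_INTERMEDIATE
        assert rate_phenotype(self._res(4.0e-6, 1.5e-6, 8.0e-6), wt, null)[0] == A.PHENOTYPE_INDETERMINATE
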