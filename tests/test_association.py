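"""Trait summaries, single-marker GLM, co-detection, and rank statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirvar.association import (
    TraitTable,
    anova_year_effect,
    co_detect,
    correlation_scan,
    glm_single_marker,
    ld_r2,
    pairwise_trait_correlation,
    summary_table,
    trait_summary,
    wilcoxon_rank_sum,
)
from mirvar.errors import ValidationError
from mirvar.variants import GenotypeMatrix

from oracles import exact_rank_sum_p, ols_fit


def two_point(mean, sd):
    """A 2-point sample with exactly the given mean and sample SD."""
    h = sd / math.sqrt(2)
    return [mean - h, mean + h]


class TestTraitSummary:
    def test_hand_computed_example(self):
        s = trait_summary([1, 2, 3])
        assert s.mean == 2 and s.sd == pytest.approx(1.0)
        assert s.cv == pytest.approx(0.5)
        assert s.median == 2

    def test_constant_vector(self):
        s = trait_summary([5, 5, 5])
        assert s.sd == 0.0 and s.cv == 0.0

    def test_even_n_median_midpoint(self):
        assert trait_summary([1, 2, 3, 10]).median == pytest.approx(2.5)

    def test_cv_two_decimal_rounding(self):
        # a distribution with mean 151.91 and SD 25.23 has CV 0.17
        s = trait_summary(two_point(151.91, 25.23))
        assert s.rounded()["cv"] == 0.17

    def test_zero_mean_cv_missing(self):
        s = trait_summary([-1.0, 1.0])
        assert s.cv is None

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            trait_summary([1.0])


class TestGLM:
    def test_perfect_separation(self):
        fit = glm_single_marker([0, 0, 2, 2], [1, 1, 2, 2])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.p == 0.0

    def test_hand_computed_slope_and_r2(self):
        fit = glm_single_marker([0, 0, 2, 2], [1, 2, 2, 3])
        assert fit.effect == pytest.approx(0.5)
        assert fit.r2 == pytest.approx(0.5)
        # P from the F(1, 2) distribution: F = r2*(n-2)/(1-r2) = 2
        assert fit.p == pytest.approx(float(sps.f.sf(2.0, 1, 2)))

    def test_monomorphic_untestable(self):
        fit = glm_single_marker([2, 2, 2, 2], [1, 2, 3, 4])
        assert fit.untestable and fit.p is None

    def test_pairwise_complete_deletion(self):
        g = [0, 0, 2, 2, np.nan]
        y = [1, 2, 2, 3, 100]
        fit = glm_single_marker(g, y)
        assert fit.n == 4
        assert fit.effect == pytest.approx(0.5)

    def test_equals_pooled_t_test_on_two_group_data(self):
        """For dosages in {0,2} the regression F test is the pooled
        two-sample t test: F = t^2 with identical P (1000 random sets)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n0 = int(rng.integers(3, 15))
            n1 = int(rng.integers(3, 15))
            y0 = rng.normal(0, 1, n0)
            y1 = rng.normal(rng.uniform(-1, 1), 1, n1)
            g = np.r_[np.zeros(n0), np.full(n1, 2.0)]
            y = np.r_[y0, y1]
            fit = glm_single_marker(g, y)
            t, p = sps.ttest_ind(y1, y0, equal_var=True)
            f = fit.r2 * (fit.n - 2) / (1 - fit.r2)
            assert f == pytest.approx(t * t, rel=1e-9)
            assert fit.p == pytest.approx(p, rel=1e-9)
            slope, r2 = ols_fit(list(g), list(y))
            assert fit.effect == pytest.approx(slope)
            assert fit.r2 == pytest.approx(r2)


class TestCorrelationScan:
    def _matrix(self, rng, n=60, m=20):
        acc = [f"a{i}" for i in range(n)]
        data = {f"v{j}": 2.0 * (rng.uniform(size=n) < 0.4) for j in range(m)}
        return GenotypeMatrix(pd.DataFrame(data, index=acc))

    def _traits(self, rng, gm, effect_key=None, beta=0.0):
        rows = []
        for year in (2016, 2017):
            base = rng.normal(10, 1, len(gm.accessions))
            if effect_key is not None:
                base = base + beta * gm.df[effect_key].to_numpy()
            for a, v in zip(gm.accessions, base):
                rows.append({"accession": a, "trait": "t1", "year": year,
                             "value": v})
        return TraitTable(pd.DataFrame(rows))

    def test_threshold_is_one_over_m(self):
        rng = np.random.default_rng(0)
        gm = self._matrix(rng, m=20)
        scan = correlation_scan(gm, self._traits(rng, gm))
        assert scan.threshold == pytest.approx(1.0 / scan.m_markers)

    def test_planted_effect_flagged_significant(self):
        rng = np.random.default_rng(1)
        gm = self._matrix(rng, n=120, m=10)
        traits = self._traits(rng, gm, effect_key="v3", beta=1.5)
        scan = correlation_scan(gm, traits)
        hits = {r.variant_key for r in scan.results if r.significant}
        assert "v3" in hits

    def test_scan_matches_per_marker_glm(self):
        """The vectorized scan reproduces glm_single_marker per test."""
        rng = np.random.default_rng(2)
        gm = self._matrix(rng, n=40, m=8)
        # inject missingness
        df = gm.df.copy()
        mask = rng.uniform(size=df.shape) < 0.1
        df[mask] = np.nan
        gm = GenotypeMatrix(df)
        traits = self._traits(rng, gm)
        scan = correlation_scan(gm, traits)
        for r in scan.results:
            y = traits.values("t1", r.year).reindex(gm.accessions)
            fit = glm_single_marker(gm.dosages(r.variant_key),
                                    y.to_numpy())
            assert r.untestable == fit.untestable
            if not fit.untestable:
                assert r.p == pytest.approx(fit.p, rel=1e-9)
                assert r.r2 == pytest.approx(fit.r2, rel=1e-9)

    def test_no_eligible_markers_raises(self):
        gm = GenotypeMatrix(pd.DataFrame(
            {"v0": [0.0, 0.0, 0.0]}, index=["a", "b", "c"]))
        rows = [{"accession": a, "trait": "t", "year": 2016, "value": 1.0}
                for a in "abc"]
        with pytest.raises(ValidationError):
            correlation_scan(gm, TraitTable(pd.DataFrame(rows)))


class TestCoDetect:
    def _res(self, key, trait, year, p, sig, r2=0.1):
        from mirvar.association import AssociationResult
        return AssociationResult(key, trait, year, 100, 1.0, r2, p, sig)

    def test_all_years_significant_is_codetected(self):
        res = [self._res("v", "t", y, 1e-4, True, r2)
               for y, r2 in [(2016, 0.12), (2017, 0.17), (2018, 0.15)]]
        (cd,) = co_detect(res, [2016, 2017, 2018])
        assert cd.co_detected
        assert cd.r2_range == (0.12, 0.17)
        assert cd.neglog10_p[0] == pytest.approx(4.0)

    def test_two_of_three_years_not_codetected(self):
        res = [self._res("v", "t", 2016, 1e-4, True),
               self._res("v", "t", 2017, 1e-4, True),
               self._res("v", "t", 2018, 0.5, False)]
        (cd,) = co_detect(res, [2016, 2017, 2018])
        assert not cd.co_detected
        assert cd.years_significant == {2016, 2017}


class TestRankAndCorrelation:
    def test_wilcoxon_exact_separated_groups(self):
        # U = 0; exact two-sided P = 2/20
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_wilcoxon_interleaved_near_one(self):
        p = wilcoxon_rank_sum([1, 4], [2, 3])
        assert p == pytest.approx(1.0)

    def test_wilcoxon_exact_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            na = int(rng.integers(2, 9))
            nb = int(rng.integers(2, 9))
            a = list(rng.normal(0, 1, na))
            b = list(rng.normal(0.5, 1, nb))
            assert wilcoxon_rank_sum(a, b) == pytest.approx(
                exact_rank_sum_p(a, b))

    def test_wilcoxon_approximation_close_to_exact_at_n30(self):
        rng = np.random.default_rng(6)
        a = list(rng.normal(0, 1, 30))
        b = list(rng.normal(0.4, 1, 30))
        p_approx = wilcoxon_rank_sum(a, b)
        p_scipy_exact = sps.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact").pvalue
        assert p_approx == pytest.approx(p_scipy_exact, abs=0.01)

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_pearson_perfect_and_inverse(self):
        r, _ = pairwise_trait_correlation([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)
        r, _ = pairwise_trait_correlation([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_pearson_hand_computed(self):
        r, p = pairwise_trait_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        # P from t = r*sqrt((n-2)/(1-r^2)) on n-2 df
        t = 0.8 * math.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * sps.t.sf(t, 2))

    def test_pearson_zero_variance_missing(self):
        r, p = pairwise_trait_correlation([1, 1, 1], [1, 2, 3])
        assert math.isnan(r)


class TestAnova:
    def test_hand_decomposition(self):
        # groups [1,2], [3,4]: SSB = 4, SSW = 1, F = 8 on (1, 2) df
        f, p = anova_year_effect([[1, 2], [3, 4]])
        assert f == pytest.approx(8.0)
        assert p == pytest.approx(float(sps.f.sf(8.0, 1, 2)))

    def test_identical_groups_f_zero(self):
        f, _ = anova_year_effect([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)

    def test_single_group_raises(self):
        with pytest.raises(ValidationError):
            anova_year_effect([[1, 2]])

    def test_large_shift_always_rejected(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(50):
            g1 = rng.normal(0, 1, 30)
            g2 = rng.normal(5, 1, 30)
            _, p = anova_year_effect([g1, g2])
            rejections += p < 0.05
        assert rejections == 50


class TestLD:
    def test_identical_vectors(self):
        assert ld_r2([0, 0, 2, 2], [0, 0, 2, 2]) == pytest.approx(1.0)

    def test_orthogonal_contrast(self):
        assert ld_r2([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0)

    def test_partial_correlation_closed_form(self):
        # corr([0,0,2,2],[0,0,0,2]) = 1/sqrt(3) -> r2 = 1/3
        assert ld_r2([0, 0, 2, 2], [0, 0, 0, 2]) == pytest.approx(1 / 3)

    def test_monomorphic_is_nan(self):
        assert math.isnan(ld_r2([2, 2, 2], [0, 2, 0]))


class TestTraitTable:
    def test_replicate_averaging_on_load(self):
        df = pd.DataFrame([
            {"accession": "a", "trait": "t", "year": 2016, "value": 1.0},
            {"accession": "a", "trait": "t", "year": 2016, "value": 3.0},
            {"accession": "b", "trait": "t", "year": 2016, "value": 5.0},
        ])
        tt = TraitTable.from_long(df)
        assert tt.values("t", 2016)["a"] == pytest.approx(2.0)

    def test_summary_table_layout(self):
        rng = np.random.default_rng(8)
        rows = [{"accession": f"a{i}", "trait": "height", "year": y,
                 "value": float(rng.normal(150, 25))}
                for y in (2016, 2017) for i in range(50)]
        tab = summary_table(TraitTable(pd.DataFrame(rows)))
        assert set(tab.columns) >= {"trait", "year", "min", "max", "median",
                                    "mean", "sd", "cv"}
        assert len(tab) == 2
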