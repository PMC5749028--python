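import numpy as np
import pytest
from scipy import stats

import triadgen as tg
from triadgen.metrics import (
    CaseComplementFit,
    ld_comparison,
    ld_decay_curve,
    pairwise_r,
)


def _map(bp, chrom=None):
    n = len(bp)
    chrom = chrom or ["1"] * n
    return tg.MarkerMap(
        [f"rs{i}" for i in range(n)], chrom, np.zeros(n), bp, ["A"] * n, ["G"] * n
    )


class TestGenotypeCorrelation:
    def test_identity_gives_one(self):
        g = np.array([0, 1, 2, 1, 0])
        assert tg.genotype_correlation(g, g) == pytest.approx(1.0)

    def test_constant_vector_flagged_nan(self):
        assert np.isnan(tg.genotype_correlation([0, 1, 2], [1, 1, 1]))

    def test_hand_computed_value(self):
        g1 = np.array([0, 1, 2, 1], dtype=float)
        g2 = np.array([0, 1, 1, 2], dtype=float)
        # direct Pearson formula
        expected = (np.mean(g1 * g2) - g1.mean() * g2.mean()) / (g1.std() * g2.std())
        assert tg.genotype_correlation(g1, g2) == pytest.approx(expected)

    def test_too_few_complete_pairs(self):
        with pytest.raises(ValueError, match="complete"):
            tg.genotype_correlation([0, tg.MISSING], [tg.MISSING, 1])

    def test_pairwise_r_matches_scalar_function(self, rng):
        mm = _map([100, 60_000, 120_000, 500_000])
        g = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
        ii, jj, rr = pairwise_r(g, mm, window_bp=200_000)
        # qualifying pairs: (0,1),(0,2),(1,2) and (2,3) is 380 kb apart -> excluded
        assert set(zip(ii.tolist(), jj.tolist())) == {(0, 1), (0, 2), (1, 2)}
        for i, j, r in zip(ii, jj, rr):
            assert r == pytest.approx(tg.genotype_correlation(g[:, i], g[:, j]))


class TestLdComparison:
    def test_identity_replicate_trivially_perfect(self, tiny_source):
        rep = ld_comparison(
            tiny_source.genotypes, [tiny_source.genotypes], tiny_source.marker_map
        )
        assert rep.summary_correlation == pytest.approx(1.0)
        assert rep.frac_within_tol == 1.0
        assert rep.frac_exceed_rare == 0.0

    def test_cross_chromosome_pairs_excluded(self, rng):
        mm = _map([100, 200], chrom=["1", "2"])
        g = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        ii, _, _ = pairwise_r(g, mm, window_bp=10**9)
        assert ii.size == 0

    def test_zero_window_has_no_pairs(self, tiny_source):
        ii, _, _ = pairwise_r(tiny_source.genotypes, tiny_source.marker_map, 0)
        assert ii.size == 0


class TestLdDecay:
    def test_perfect_ld_block_decays_across_boundaries(self, rng):
        from triadgen.synthetic_source import BlockSpec

        n = 10
        haps = np.vstack([np.ones(n), np.zeros(n)]).astype(np.int8)
        blocks = [
            BlockSpec(haps, np.array([0.4, 0.6]), 2000 * np.arange(1, n + 1), 0.5),
            BlockSpec(haps, np.array([0.4, 0.6]),
                      40_000 + 2000 * np.arange(1, n + 1), 0.0),
        ]
        ds = tg.generate_source(500, [blocks], rng)
        curve = ld_decay_curve(ds.genotypes, ds.marker_map, window_bp=60_000, n_bins=6)
        short = curve["mean_r2"].iloc[0]
        long = curve["mean_r2"].dropna().iloc[-1]
        assert short > 0.99
        assert long < 0.5  # independent blocks (r=0.5) decorrelate

    def test_empty_bins_flagged_not_zero(self, rng):
        mm = _map([100, 200])
        g = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        curve = ld_decay_curve(g, mm, window_bp=10_000, n_bins=5)
        assert curve["n_pairs"].sum() == 1
        assert curve["mean_r2"].isna().sum() == 4


class TestMafPredictionInterval:
    def test_degenerate_maf_zero(self):
        assert tg.maf_prediction_interval(0.0, 4000) == (0.0, 0.0)

    def test_exact_binomial_quantiles_at_half(self):
        lo, hi = tg.maf_prediction_interval(0.5, 4000)
        assert lo == stats.binom.ppf(0.025, 4000, 0.5) / 4000
        assert hi == stats.binom.ppf(0.975, 4000, 0.5) / 4000
        assert hi - 0.5 == pytest.approx(0.0155, abs=5e-4)

    def test_interval_coverage_by_direct_summation(self):
        for p0, n in [(0.3, 4000), (0.01, 4000), (0.15, 800)]:
            lo, hi = tg.maf_prediction_interval(p0, n)
            k = np.arange(n + 1)
            mass = stats.binom.pmf(k, n, p0)
            cover = mass[(k >= lo * n - 1e-9) & (k <= hi * n + 1e-9)].sum()
            assert cover >= 0.95

    def test_coverage_report_identity_and_nominal(self, rng):
        maf0 = np.array([0.0, 0.1, 0.3])
        reps = np.tile(maf0, (5, 1))
        out = tg.maf_coverage_report(maf0, reps, n_alleles=4000)
        assert np.all(out["per_snp"] == 1.0)
        # binomial-simulated replicates achieve ~nominal coverage
        n = 4000
        maf0 = np.array([0.05, 0.2, 0.4])
        sim = rng.binomial(n, maf0[None, :].repeat(400, 0)) / n
        out = tg.maf_coverage_report(maf0, sim, n_alleles=n)
        assert abs(out["mean"] - 0.95) < 0.02

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="two replicates"):
            tg.maf_coverage_report(np.array([0.1]), np.array([[0.1]]), 100)


class TestTdt:
    def test_balanced_transmissions_null(self):
        # 50 families with both parents het, child het: b = c
        m = np.ones(100, dtype=int)
        f = np.ones(100, dtype=int)
        c = np.ones(100, dtype=int)
        chi2, p, b, cc = tg.tdt_test(m, f, c)
        assert b == cc == 100
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_worked_example_b60_c40(self):
        """60 transmissions vs 40 non-transmissions: chi2 = 4, p ~ 0.0455."""
        m = np.ones(100, dtype=int)
        f = np.zeros(100, dtype=int)
        c = np.concatenate([np.ones(60, dtype=int), np.zeros(40, dtype=int)])
        chi2, p, b, cc = tg.tdt_test(m, f, c)
        assert (b, cc) == (60, 40)
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-12)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_homozygous_parents_only_flagged(self):
        chi2, p, b, c = tg.tdt_test([0, 2], [2, 2], [1, 2])
        assert np.isnan(chi2) and np.isnan(p)

    def test_hom_parent_contribution_subtracted(self):
        # m het, f hom-variant: child 2 means m transmitted the variant
        chi2, p, b, c = tg.tdt_test([1], [2], [2])
        assert (b, c) == (1, 0)


class TestCaseComplementFit:
    def test_all_concordant_pairs_error(self):
        x = np.ones((10, 1))
        with pytest.raises(ValueError, match="informative"):
            tg.fit_case_complement(x, x)

    def test_null_symmetry_under_label_swap(self, rng):
        xc = rng.integers(0, 2, size=(500, 2)).astype(float)
        xk = rng.integers(0, 2, size=(500, 2)).astype(float)
        a = tg.fit_case_complement(xc, xk)
        b = tg.fit_case_complement(xk, xc)
        assert np.allclose(a.coef, -b.coef)
        assert np.allclose(a.se, b.se)

    def test_null_estimates_near_one(self, rng):
        xc = rng.integers(0, 2, size=(4000, 2)).astype(float)
        xk = rng.integers(0, 2, size=(4000, 2)).astype(float)
        fit = tg.fit_case_complement(xc, xk)
        assert np.all(np.abs(fit.coef) < 4 * fit.se)
        assert fit.covers(np.ones(2)).all()

    def test_recovers_known_conditional_model(self, rng):
        """Simulate matched pairs directly from the conditional likelihood
        (independent oracle) and recover beta."""
        beta = np.log(2.5)
        n = 6000
        d = rng.integers(-1, 2, size=n).astype(float)  # X_case - X_comp in {-1,0,1}
        # P(case is the labeled case | d) = sigmoid(beta * d); flip otherwise
        keep = rng.random(n) < 1 / (1 + np.exp(-beta * d))
        d_obs = np.where(keep, d, -d)
        fit = tg.fit_case_complement(d_obs[:, None], np.zeros((n, 1)))
        assert fit.coef[0] == pytest.approx(beta, abs=3 * fit.se[0])
        assert fit.n_informative == int((d != 0).sum())

    def test_interaction_features_included(self, rng):
        xc = rng.integers(0, 2, size=(200, 1)).astype(float)
        xk = rng.integers(0, 2, size=(200, 1)).astype(float)
        e = rng.integers(0, 2, size=200)
        fit = tg.fit_case_complement(xc, xk, exposure=e)
        assert fit.names == ["pathway1", "pathway1:E"]
        assert fit.coef.shape == (2,)


class TestFitCohort:
    def test_zero_noise_exact_recovery(self):
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1]] * 10, dtype=float)
        Y = 0.5 + X @ np.array([0.1, 0.15])
        fit = tg.fit_cohort(X, Y, model_kind="quantitative")
        assert fit.params["const"] == pytest.approx(0.5)
        assert fit.params["pathway1"] == pytest.approx(0.1)
        assert fit.params["pathway2"] == pytest.approx(0.15)

    def test_null_pathways_estimate_zero(self, rng):
        X = rng.integers(0, 2, size=(5000, 2)).astype(float)
        Y = rng.normal(0, 1, 5000)
        fit = tg.fit_cohort(X, Y, model_kind="quantitative")
        for name in ("pathway1", "pathway2"):
            assert abs(fit.params[name]) < 4 * fit.bse[name]

    def test_stratified_null_confounding_removed_by_subpop_intercepts(self, rng):
        """Marginal confounding from subpopulation structure disappears when
        subpopulation intercepts enter the linear model."""
        n = 6000
        sub = rng.integers(0, 2, size=n)
        X = (rng.random((n, 1)) < np.where(sub == 1, 0.6, 0.2)[:, None]).astype(float)
        Y = 1.1 * sub + rng.normal(0, 1, n)  # trait depends on subpop only
        naive = tg.fit_cohort(X, Y, model_kind="quantitative")
        assert naive.params["pathway1"] > 0.2  # biased without adjustment
        adj = tg.fit_cohort(X, Y, subpop=np.where(sub == 1, "b", "a"),
                            model_kind="quantitative")
        assert abs(adj.params["pathway1"]) < 4 * adj.bse["pathway1"]

    def test_log_binomial_recovers_rr(self, rng):
        n = 20000
        X = rng.integers(0, 2, size=(n, 1)).astype(float)
        pr = 0.05 * np.where(X[:, 0] == 1, 2.0, 1.0)
        Y = (rng.random(n) < pr).astype(float)
        fit = tg.fit_cohort(X, Y, model_kind="rr")
        assert np.exp(fit.params["pathway1"]) == pytest.approx(2.0, rel=0.15)
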