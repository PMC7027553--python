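import warnings

import numpy as np
import pytest
from scipy import stats

from coldmeta import (Biome, CIMethod, DepthBin, EffectSize, LatitudeBand,
                      MetaFit, StratumLabels, bca_ci, build_vcov,
                      fit_fixed_effect, gls_pooled, significance,
                      subgroup_analysis, wald_ci)
from coldmeta.effects import smd_variance
from coldmeta.errors import (EmptySetError, InvalidInputError, NumericalError)
from coldmeta.inference import choose_ci_method


def labeled_effect(y, v, biome=Biome.TUNDRA, depth=DepthBin.D5,
                   band=LatitudeBand.HIGH_N, cluster=None, n_w=5, n_c=5,
                   response="DON"):
    labeled_effect.counter = getattr(labeled_effect, "counter", 0) + 1
    return EffectSize(
        y=y, v=v, record_ref=f"d{labeled_effect.counter}/{response}",
        labels=StratumLabels(depth, band, biome), n_w=n_w, n_c=n_c,
        control_cluster=cluster or f"c{labeled_effect.counter}",
        response=response)


class TestFixedEffect:
    def test_single_effect(self):
        fit = fit_fixed_effect(np.array([0.7]), np.array([0.25]))
        assert fit.estimate == 0.7
        assert fit.se == pytest.approx(0.5)
        assert fit.ci_method is CIMethod.NONE
        assert np.isnan(fit.ci_low) and np.isnan(fit.ci_high)

    def test_equal_weights(self):
        fit = fit_fixed_effect(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]),
                               ci_method="wald")
        assert fit.estimate == pytest.approx(2.0, abs=1e-14)
        assert fit.se == pytest.approx(1 / np.sqrt(3), abs=1e-14)
        assert fit.k == 3

    def test_empty_rejected(self):
        with pytest.raises(EmptySetError):
            fit_fixed_effect(np.array([]), np.array([]))

    def test_diagonal_matches_inverse_variance_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 30))
            y = rng.normal(0, 1, k)
            v = rng.uniform(0.05, 2.0, k)
            fit = fit_fixed_effect(y, v, ci_method="wald")
            w = 1 / v
            assert fit.estimate == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-12)
            assert fit.se == pytest.approx(np.sqrt(1 / np.sum(w)), abs=1e-12)

    def test_full_v_matches_statsmodels_gls(self, rng):
        import statsmodels.api as sm

        for _ in range(30):
            k = int(rng.integers(3, 15))
            clusters = rng.integers(0, max(2, k // 2), k).astype(str)
            effects = [labeled_effect(rng.normal(), 0.0, cluster=f"g{c}")
                       for c in clusters]
            for e in effects:
                e.n_c = 5
                e.v = smd_variance(e.y, e.n_w, e.n_c)
            cov = build_vcov(effects)
            y = np.array([e.y for e in effects])
            fit = fit_fixed_effect(effects, cov, ci_method="wald")
            oracle = sm.GLS(y, np.ones((k, 1)), sigma=cov.V).fit()
            assert fit.estimate == pytest.approx(oracle.params[0], abs=1e-10)
            # unscale: statsmodels multiplies cov_params by its estimated scale
            assert fit.se == pytest.approx(oracle.bse[0] / np.sqrt(oracle.scale),
                                           abs=1e-10)

    def test_order_invariance(self, rng):
        y = rng.normal(0, 1, 12)
        v = rng.uniform(0.1, 1, 12)
        perm = rng.permutation(12)
        a = fit_fixed_effect(y, v, ci_method="wald")
        b = fit_fixed_effect(y[perm], v[perm], ci_method="wald")
        assert b.estimate == pytest.approx(a.estimate, abs=1e-12)
        assert b.se == pytest.approx(a.se, abs=1e-12)

    def test_duplication_with_halved_weights_invariance(self, rng):
        y = rng.normal(0, 1, 8)
        v = rng.uniform(0.1, 1, 8)
        base = fit_fixed_effect(y, v, ci_method="wald")
        doubled = fit_fixed_effect(np.tile(y, 2), np.tile(2 * v, 2), ci_method="wald")
        assert doubled.estimate == pytest.approx(base.estimate, abs=1e-12)
        assert doubled.se == pytest.approx(base.se, abs=1e-12)

    def test_singular_covariance_rejected(self):
        V = np.ones((3, 3))
        with pytest.raises(NumericalError):
            gls_pooled(np.array([1.0, 2.0, 3.0]), V)

    def test_z_and_p(self):
        fit = fit_fixed_effect(np.array([0.5, 0.5]), np.array([0.5, 0.5]),
                               ci_method="wald")
        assert fit.z == pytest.approx(0.5 / 0.5, abs=1e-12)
        assert fit.p == pytest.approx(2 * stats.norm.sf(abs(fit.z)), abs=1e-15)


class TestWaldCI:
    def test_standard_normal_quantile(self):
        lo, hi = wald_ci(0.0, 1.0)
        assert lo == pytest.approx(-1.95996, abs=5e-6)
        assert hi == pytest.approx(1.95996, abs=5e-6)

    def test_shifted_scaled(self):
        lo, hi = wald_ci(2.0, 0.5)
        assert lo == pytest.approx(1.02002, abs=5e-6)
        assert hi == pytest.approx(2.97998, abs=5e-6)

    @pytest.mark.parametrize("est, se", [(0, 1), (3.2, 0.01), (-5, 2)])
    def test_width_and_symmetry(self, est, se):
        lo, hi = wald_ci(est, se)
        z = stats.norm.ppf(0.975)
        assert hi - lo == pytest.approx(2 * z * se, rel=1e-12)
        assert (lo + hi) / 2 == pytest.approx(est, abs=1e-12)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_level(self, level):
        with pytest.raises(InvalidInputError):
            wald_ci(0, 1, level)


class TestBcaCI:
    def test_deterministic_for_fixed_seed(self, rng):
        y = rng.normal(0.5, 0.3, 8)
        v = np.full(8, 0.3)
        assert bca_ci(y, v, B=500, seed=7) == bca_ci(y, v, B=500, seed=7)
        assert bca_ci(y, v, B=500, seed=7) != bca_ci(y, v, B=500, seed=8)

    def test_degenerate_distribution_collapses(self):
        y = np.full(6, 0.42)
        v = np.full(6, 0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo, hi = bca_ci(y, v, B=200, seed=1)
        assert lo == hi == pytest.approx(0.42)

    def test_too_few_effects(self):
        with pytest.raises(InvalidInputError):
            bca_ci(np.array([1.0]), np.array([0.5]), B=200, seed=0)

    def test_too_few_resamples(self):
        with pytest.raises(InvalidInputError):
            bca_ci(np.array([1.0, 2.0]), np.array([0.5, 0.5]), B=50, seed=0)

    def test_matches_scipy_bca_for_plain_mean(self, rng):
        # equal variances make the pooled statistic the sample mean, which
        # scipy.stats.bootstrap can interval independently
        y = rng.normal(0.5, 0.6, 12)
        v = np.full(12, 0.36)
        lo, hi = bca_ci(y, v, B=4000, seed=3)
        res = stats.bootstrap((y,), np.mean, n_resamples=4000, method="BCa",
                              confidence_level=0.95,
                              random_state=np.random.default_rng(3))
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.02)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.02)

    def test_cluster_resampling_path_runs_and_is_deterministic(self, rng):
        effects = [labeled_effect(rng.normal(0.5, 0.3), 0.0,
                                  cluster=f"g{i % 3}") for i in range(9)]
        for e in effects:
            e.n_c = 5
            e.v = smd_variance(e.y, e.n_w, e.n_c)
        cov = build_vcov(effects)
        a = bca_ci(effects, cov, B=400, seed=5)
        assert a == bca_ci(effects, cov, B=400, seed=5)
        assert a[0] < a[1]

    def test_bca_and_wald_converge_for_symmetric_large_k(self, rng):
        k = 50
        y = rng.normal(0.4, 0.5, k)
        v = np.full(k, 0.25)
        fit = fit_fixed_effect(y, v, ci_method="wald")
        blo, bhi = bca_ci(y, v, B=2000, seed=11)
        width = fit.ci_high - fit.ci_low
        assert abs(blo - fit.ci_low) < 0.1 * width
        assert abs(bhi - fit.ci_high) < 0.1 * width


class TestCIMethodRules:
    @pytest.mark.parametrize("k, method", [
        (1, CIMethod.NONE), (2, CIMethod.BCA), (14, CIMethod.BCA),
        (15, CIMethod.WALD), (100, CIMethod.WALD),
    ])
    def test_study_count_rules(self, k, method):
        assert choose_ci_method(k) is method

    def test_auto_bca_requires_seed(self, rng):
        y = rng.normal(0, 1, 5)
        v = np.full(5, 0.4)
        with pytest.raises(InvalidInputError, match="seed"):
            fit_fixed_effect(y, v)  # auto -> BCA, no seed given
        fit = fit_fixed_effect(y, v, seed=1, B=500)
        assert fit.ci_method is CIMethod.BCA


class TestSignificance:
    @pytest.mark.parametrize("lo, hi, expected", [
        (0.1, 0.5, True),
        (-0.571, -0.173, True),   # printed moisture interval
        (1.144, 1.734, True),     # printed temperature interval
        (-0.2, 0.3, False),
    ])
    def test_ci_excludes_zero_rule(self, lo, hi, expected):
        fit = MetaFit(estimate=(lo + hi) / 2, se=0.1, ci_low=lo, ci_high=hi,
                      z=1.0, p=0.3, k=20, ci_method=CIMethod.WALD)
        assert significance(fit) is expected

    def test_not_evaluable_without_ci(self):
        fit = MetaFit(estimate=0.4, se=0.5, ci_low=float("nan"),
                      ci_high=float("nan"), z=0.8, p=0.4, k=1,
                      ci_method=CIMethod.NONE)
        assert significance(fit) is None


class TestSubgroupAnalysis:
    def test_single_biome_equals_overall(self, rng):
        effects = [labeled_effect(rng.normal(0.5, 0.2), 0.4) for _ in range(20)]
        fits = subgroup_analysis(effects, factor="biome", seed=1, B=500)
        assert len(fits) == 1
        overall = fit_fixed_effect(effects, ci_method="wald")
        assert fits[0].estimate == pytest.approx(overall.estimate, abs=1e-12)
        assert fits[0].stratum == "biome=TUNDRA"

    def test_threshold_suppresses_small_responses(self, rng):
        effects = [labeled_effect(rng.normal(), 0.4, response="DON")
                   for _ in range(8)]
        assert subgroup_analysis(effects, factor="biome", seed=1) == []

    def test_exception_list_overrides_threshold(self, rng):
        effects = [labeled_effect(rng.normal(), 0.4, response="N fixation")
                   for _ in range(8)]
        fits = subgroup_analysis(effects, factor="biome", seed=1, B=500)
        assert len(fits) == 1

    def test_unknown_depth_excluded_from_depth_contrasts_only(self, rng):
        effects = [labeled_effect(rng.normal(), 0.4) for _ in range(12)]
        effects[0].labels = StratumLabels(DepthBin.UNKNOWN, LatitudeBand.HIGH_N,
                                          Biome.TUNDRA)
        depth_fits = subgroup_analysis(effects, factor="depth_bin", seed=1, B=500)
        assert sum(f.k for f in depth_fits) == 11
        biome_fits = subgroup_analysis(effects, factor="biome", seed=2, B=500)
        assert sum(f.k for f in biome_fits) == 12

    def test_unknown_factor(self, rng):
        effects = [labeled_effect(rng.normal(), 0.4) for _ in range(12)]
        with pytest.raises(InvalidInputError):
            subgroup_analysis(effects, factor="elevation", seed=1)

    def test_per_biome_parameter_recovery(self, rng):
        truth = {Biome.TUNDRA: 0.8, Biome.GRASSLAND: -0.2}
        effects = []
        for biome, mu in truth.items():
            for _ in range(60):
                effects.append(labeled_effect(rng.normal(mu, np.sqrt(0.4)), 0.4,
                                              biome=biome))
        fits = subgroup_analysis(effects, factor="biome", seed=3)
        assert len(fits) == 2
        for fit in fits:
            biome = Biome(fit.stratum.split("=")[1])
            assert abs(fit.estimate - truth[biome]) < 2 * fit.se


def test_type_one_error_of_significance_rule(rng):
    hits = 0
    reps = 2000
    for _ in range(reps):
        v = rng.uniform(0.2, 0.6, 20)
        y = rng.normal(0, np.sqrt(v))
        fit = fit_fixed_effect(y, v, ci_method="wald")
        hits += bool(significance(fit))
    assert 0.035 <= hits / reps <= 0.065
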