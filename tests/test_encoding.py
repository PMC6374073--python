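"""Encoding fits: OLS recovery, elastic-net oracle equivalence, penalty
selection, phenotype classification, category fractions, calcium
decomposition."""
import itertools

import numpy as np
import pandas as pd
import pytest

from zfcereb.core import TimeSeries, SpikeTrain
from zfcereb.design import RegressorMatrix, KernelSpec
from zfcereb.encoding import (PenaltySpec, ElasticNetEncoder, fit_ols,
                              fit_elastic_net, select_lambda,
                              classify_phenotype, category_fraction,
                              decompose_calcium, elastic_net_objective,
                              EncodingFit)
from zfcereb.synth import GeneratorConfig, simulate_calcium, sample_poisson_train


def _matrix(arr, cats=None):
    arr = np.asarray(arr, dtype=float)
    names = [f"c{j}" for j in range(arr.shape[1])]
    cats = cats or {n: ("sensory", "motion_onset") for n in names}
    return RegressorMatrix(pd.DataFrame(arr, columns=names),
                           dict(zip(names, cats.values())) if isinstance(cats, dict) else cats,
                           100.0)


def _grid_search_en(A, y, alpha, lam, lo=-3.0, hi=3.0, steps=121):
    """Independent dense-grid minimizer of the elastic-net objective
    (intercept profiled out analytically at each grid point)."""
    best, best_obj = None, np.inf
    axes = [np.linspace(lo, hi, steps)] * A.shape[1]
    for beta in itertools.product(*axes):
        beta = np.asarray(beta)
        b0 = float(np.mean(y - A @ beta))
        obj = elastic_net_objective(A, y, beta, b0, alpha, lam)
        if obj < best_obj:
            best_obj, best = obj, beta
    return best, best_obj


class TestOLS:
    def test_exact_column_gives_unit_beta(self, rng):
        A = rng.normal(size=(200, 4))
        X = _matrix(A)
        y = A[:, 2].copy()
        fit = fit_ols(y, X)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        zc = fit.coefficients
        assert zc[2] == pytest.approx(1.0 * A[:, 2].std() / y.std(), abs=1e-8)
        assert np.allclose(np.delete(zc, 2), 0.0, atol=1e-8)

    def test_known_linear_combination_recovered(self, rng):
        A = rng.normal(size=(300, 3))
        y = 2.0 * A[:, 0] - 1.0 * A[:, 1]
        fit = fit_ols(y, _matrix(A))
        # on the z-scored scale betas are scaled by sd(x)/sd(y)
        expect = np.array([2.0 * A[:, 0].std(), -1.0 * A[:, 1].std(), 0.0]) / y.std()
        assert np.allclose(fit.coefficients, expect, atol=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_independent_noise_r2_near_zero(self, rng):
        A = rng.normal(size=(5000, 4))
        y = rng.normal(size=5000)
        fit = fit_ols(y, _matrix(A))
        assert fit.r_squared < 0.01

    def test_rank_deficiency_flagged(self, rng):
        a = rng.normal(size=200)
        A = np.column_stack([a, 2 * a, rng.normal(size=200)])
        fit = fit_ols(rng.normal(size=200), _matrix(A))
        assert fit.rank_deficient


class TestElasticNet:
    def test_full_shrinkage_at_large_lambda(self, rng):
        A = rng.normal(size=(100, 3))
        y = A @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=100)
        fit = fit_elastic_net(y, _matrix(A), PenaltySpec(alpha=0.2, lam=50.0))
        assert np.all(fit.coefficients == 0.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)  # z-scored y

    def test_lambda_zero_limit_matches_ols(self, rng):
        A = rng.normal(size=(150, 4))
        y = A @ np.array([1.0, 0.0, -0.5, 0.2]) + 0.1 * rng.normal(size=150)
        ols = fit_ols(y, _matrix(A))
        en = ElasticNetEncoder(alpha=0.2, lam=1e-10).fit(_matrix(A), y).summary_
        assert np.allclose(en.coefficients, ols.coefficients, atol=1e-6)

    @pytest.mark.parametrize("alpha,lam", [(0.2, 0.5), (0.9, 0.3), (1.0, 0.1)])
    def test_matches_dense_grid_oracle(self, alpha, lam, rng):
        """Solver beta matches a brute-force grid minimizer of the quoted
        objective on small systems, tol 1e-3."""
        A = rng.normal(size=(30, 2))
        A = (A - A.mean(0)) / A.std(0)
        y = A @ np.array([1.0, -0.7]) + 0.3 * rng.normal(size=30)
        y = (y - y.mean()) / y.std()
        enc = ElasticNetEncoder(alpha=alpha, lam=lam).fit(A, y)
        beta_star, obj_star = _grid_search_en(A, y, alpha, lam,
                                              lo=-1.5, hi=1.5, steps=301)
        obj_solver = elastic_net_objective(A, y, enc.coef_, enc.intercept_,
                                           alpha, lam)
        assert obj_solver <= obj_star + 1e-6
        assert np.allclose(enc.coef_, beta_star, atol=1.5e-2)

    def test_monotone_sparsity_in_lambda(self, rng):
        A = rng.normal(size=(120, 8))
        y = A @ rng.normal(size=8) + rng.normal(size=120)
        X = _matrix(A)
        nnz = [fit_elastic_net(y, X, PenaltySpec(0.2, lam)).nonzero_count
               for lam in (0.01, 0.05, 0.2, 0.5, 1.0, 3.0)]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_invalid_penalty_rejected(self):
        with pytest.raises(ValueError):
            PenaltySpec(alpha=0.0)
        with pytest.raises(ValueError):
            PenaltySpec(alpha=0.2, lam=-1.0)


class TestSelectLambda:
    def test_noiseless_signal_prefers_smallest(self, rng):
        A = rng.normal(size=(200, 3))
        y = A[:, 0].copy()
        lam = select_lambda([y], A, [1e-6, 10.0], penalty_alpha=0.2, seed=0)
        assert lam == 1e-6

    def test_pure_noise_prefers_largest(self, rng):
        signals = [rng.normal(size=200) for _ in range(4)]
        A = rng.normal(size=(200, 5))
        lam = select_lambda(signals, A, [1e-4, 0.1, 5.0], penalty_alpha=0.2, seed=0)
        assert lam == 5.0

    def test_singleton_grid(self, rng):
        y = rng.normal(size=50)
        assert select_lambda([y], rng.normal(size=(50, 2)), [0.7]) == 0.7

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            select_lambda([rng.normal(size=10)], rng.normal(size=(10, 2)), [])


def _fit_from_weights(weights: dict) -> EncodingFit:
    cats = {"onset_forward": ("sensory", "motion_onset"),
            "onset_left": ("sensory", "motion_onset"),
            "rot_cw": ("sensory", "rotation"),
            "rot_ccw": ("sensory", "rotation"),
            "lum_increase": ("sensory", "luminance"),
            "swim_vigor": ("motor", "swim"),
            "motion_forward": ("sensory", "motion_duration")}
    names = list(cats)
    coef = np.array([weights.get(n, 0.0) for n in names])
    return EncodingFit(names=names, coefficients=coef, intercept=0.0,
                       r_squared=0.5, categories=cats)


class TestClassifyPhenotype:
    def test_cw_velocity_dominant(self):
        fit = _fit_from_weights({"rot_cw": 0.9, "swim_vigor": 0.1})
        assert classify_phenotype(fit) == "rotational_velocity"

    def test_onset_directions_collapse(self):
        fit = _fit_from_weights({"onset_forward": 0.4, "onset_left": 0.4,
                                 "lum_increase": 0.1})
        assert classify_phenotype(fit) == "motion_onset"

    def test_tie_broken_by_summed_category_weight_and_flagged(self):
        fit = _fit_from_weights({"rot_cw": 0.4, "swim_vigor": 0.4,
                                 "rot_ccw": 0.2})
        assert classify_phenotype(fit) == "rotational_velocity"
        assert fit.ambiguous

    def test_all_zero_unclassified(self):
        fit = _fit_from_weights({})
        assert classify_phenotype(fit) == "unclassified"


class TestCategoryFraction:
    def test_single_motor_coefficient(self):
        fit = _fit_from_weights({"swim_vigor": 0.3})
        assert category_fraction(fit, "motor") == pytest.approx(1.0)
        assert category_fraction(fit, "sensory") == 0.0

    def test_equal_split(self):
        fit = _fit_from_weights({"swim_vigor": 0.5, "rot_cw": -0.5})
        assert category_fraction(fit, "motor") == pytest.approx(0.5)
        assert category_fraction(fit, "sensory") == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            category_fraction(_fit_from_weights({}), "motor")

    def test_fractions_sum_to_one_per_level(self):
        fit = _fit_from_weights({"swim_vigor": 0.5, "rot_cw": -0.4,
                                 "lum_increase": 0.2})
        fr = fit.category_fractions
        assert fr["motor"] + fr["sensory"] == pytest.approx(1.0)
        assert (fr["swim"] + fr["rotation"] + fr["luminance"]
                == pytest.approx(1.0))


class TestDecomposeCalcium:
    def test_cs_only_signal(self):
        cfg = GeneratorConfig(seed=0)
        cs = SpikeTrain(np.arange(5.0, 95.0, 4.0), "complex")
        dff = simulate_calcium(cs, SpikeTrain([], "simple"), cfg,
                               duration=100.0, noise=False)
        out = decompose_calcium(dff, cs, SpikeTrain([], "simple"))
        assert out["cs_percent"] == 100.0
        assert out["flagged"]

    def test_symmetric_sources_split_evenly(self, rng):
        """Equal-amplitude, equal-rate independent sources -> ~50/50."""
        cfg = GeneratorConfig(seed=0, ca_cs_share=0.5,
                              paired_cs_rate=2.0, paired_ss_rate=2.0)
        cs = SpikeTrain(sample_poisson_train(2.0, 400.0, rng), "complex")
        ss = SpikeTrain(sample_poisson_train(2.0, 400.0, rng), "simple")
        dff = simulate_calcium(cs, ss, cfg, duration=400.0, noise=False)
        out = decompose_calcium(dff, cs, ss)
        assert out["cs_percent"] == pytest.approx(50.0, abs=3.0)
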