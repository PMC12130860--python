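"""Identity-link Poisson fits, the grid-search oracle, bootstrap, batch LRT."""

import numpy as np
import pytest

import germdecomp as gd
from germdecomp.rate_regression import (
    RateRegression,
    SlopeUnidentifiableError,
    batch_effect_lrt,
    bootstrap_rates,
    fit_rate_regression,
    _loglik,
)

from conftest import make_trio


def grid_oracle(trios, rho, P, n=200, rounds=6):
    """Dense 2-D grid search of the identity-link Poisson likelihood.

    The window starts from data-driven bounds (overall rate scale) and is
    iteratively zoomed around the grid argmax; no information from the
    Newton fit enters.
    """
    U = np.array([t.n_mut_total for t in trios])
    L2 = 2.0 * np.array([t.callable_haploid_bp for t in trios])
    A = np.array(
        [
            gd.weighted_parental_age(t.paternal_age, t.maternal_age, rho, P)
            for t in trios
        ]
    )
    rate0 = np.sum(U) / np.sum(L2)
    a_range = (1e-15, 3.0 * rate0)
    b_range = (-3.0 * rate0, 3.0 * rate0)
    best = (-np.inf, rate0, 0.0)
    for _ in range(rounds):
        a_grid = np.linspace(*a_range, n)
        b_grid = np.linspace(*b_range, n)
        best = (-np.inf, best[1], best[2])
        for a in a_grid:
            means = L2[None, :] * (a + np.outer(b_grid, A))
            ok = np.all(means > 0, axis=1)
            lls = np.full(n, -np.inf)
            lls[ok] = np.sum(
                np.where(U > 0, U * np.log(means[ok]), 0.0) - means[ok], axis=1
            )
            j = int(np.argmax(lls))
            if lls[j] > best[0]:
                best = (lls[j], a, b_grid[j])
        # wide zoom: the (a, b) likelihood ridge is strongly anticorrelated,
        # so the coarse argmax can sit several cells from the optimum
        da = (a_range[1] - a_range[0]) / (n - 1)
        db = (b_range[1] - b_range[0]) / (n - 1)
        a_range = (max(best[1] - 12 * da, 1e-15), best[1] + 12 * da)
        b_range = (best[2] - 12 * db, best[2] + 12 * db)
    return best[1], best[2]


def test_two_point_fit_is_exact_interpolation():
    t1 = make_trio("a", AP=10.0, AM=10.0, U=30.0, L=2.5e9)
    t2 = make_trio("b", AP=20.0, AM=20.0, U=50.0, L=2.5e9)
    fit = fit_rate_regression([t1, t2], rho=0.5, puberty_age=10.0)
    assert fit.decomposition.mu_E == pytest.approx(6.0e-9, rel=1e-8)
    assert fit.decomposition.mu_OS == pytest.approx(4.0e-10, rel=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fit_matches_dense_grid_oracle_on_three_trios(seed):
    rng = np.random.default_rng(seed)
    trios = [
        make_trio(f"g{i}", AP=a, AM=a, U=u, L=2.5e9)
        for i, (a, u) in enumerate(
            zip(rng.uniform(15, 45, 3), rng.uniform(20, 90, 3))
        )
    ]
    est = RateRegression(rho=0.5, puberty_age=13.0).fit(trios)
    a_hat, b_hat = est.mu_E_, est.mu_OS_
    a_grid, b_grid = grid_oracle(trios, 0.5, 13.0)
    assert a_hat == pytest.approx(a_grid, rel=1e-3)
    assert b_hat == pytest.approx(b_grid, rel=1e-3, abs=1e-3 * a_hat)


def test_simulation_recovery_low_bias():
    """Mean relative bias of both estimates below 5% over 50 replicates."""
    rel = []
    for rep in range(50):
        cfg = gd.TrioSimConfig(n_trios=100, seed=6000 + rep)
        fit = fit_rate_regression(gd.simulate_trios(cfg), rho=0.75, puberty_age=13.0)
        rel.append(
            [
                fit.decomposition.mu_E / cfg.mu_E_regression - 1.0,
                fit.decomposition.mu_OS / cfg.mu_OS_regression - 1.0,
            ]
        )
    bias = np.abs(np.mean(rel, axis=0))
    assert np.all(bias < 0.05), bias


def test_all_zero_counts_hits_origin_boundary():
    trios = [make_trio(f"z{i}", AP=20.0 + i, AM=20.0 + i, U=0.0) for i in range(4)]
    fit = fit_rate_regression(trios, rho=0.5, puberty_age=10.0)
    assert fit.decomposition.mu_E == 0.0
    assert fit.decomposition.mu_OS == 0.0
    assert fit.boundary


def test_constant_age_raises_slope_unidentifiable():
    trios = [make_trio(f"c{i}", AP=25.0, AM=25.0, U=40.0 + i) for i in range(3)]
    with pytest.raises(SlopeUnidentifiableError):
        fit_rate_regression(trios, rho=0.5, puberty_age=10.0)


def test_estimates_invariant_to_trio_order(human_like_trios):
    fit1 = fit_rate_regression(human_like_trios, rho=0.75, puberty_age=13.0)
    fit2 = fit_rate_regression(human_like_trios[::-1], rho=0.75, puberty_age=13.0)
    assert fit1.decomposition.mu_E == pytest.approx(fit2.decomposition.mu_E, rel=1e-9)
    assert fit1.decomposition.mu_OS == pytest.approx(fit2.decomposition.mu_OS, rel=1e-9)


def test_model_nests_null(human_like_trios):
    fit = fit_rate_regression(human_like_trios, rho=0.75, puberty_age=13.0)
    assert fit.loglik >= fit.loglik_null
    assert 0.0 <= fit.pseudo_R2 < 1.0
    assert fit.pseudo_R2 == pytest.approx(1.0 - fit.loglik / fit.loglik_null)


def test_predict_returns_positive_means(human_like_trios):
    est = RateRegression(rho=0.75, puberty_age=13.0).fit(human_like_trios)
    mu = est.predict(human_like_trios)
    assert mu.shape == (len(human_like_trios),)
    assert np.all(mu > 0)


def test_sklearn_param_interface():
    est = RateRegression(rho=0.6, puberty_age=5.0)
    assert est.get_params() == {"rho": 0.6, "puberty_age": 5.0}
    est.set_params(rho=0.75)
    assert est.rho == 0.75


class TestBootstrap:
    def test_identical_trios_give_zero_width_interval(self):
        t = make_trio("a", AP=20.0, AM=20.0, U=40.0)
        s = make_trio("b", AP=30.0, AM=30.0, U=55.0)
        boot = bootstrap_rates([t, s, t, s], rho=0.5, puberty_age=10.0, B=1, seed=0)
        # With a single draw both percentile endpoints collapse onto it.
        assert boot.ci_muE[0] == boot.ci_muE[1]
        assert boot.B == 1

    def test_draws_anticorrelated(self, human_like_trios):
        boot = bootstrap_rates(
            human_like_trios, rho=0.75, puberty_age=13.0, B=200, seed=3
        )
        r = np.corrcoef(boot.draws.T)[0, 1]
        assert r < -0.3  # slope/intercept trade-off of the shared regression

    def test_seed_determinism(self, human_like_trios):
        b1 = bootstrap_rates(human_like_trios, rho=0.75, puberty_age=13.0, B=20, seed=9)
        b2 = bootstrap_rates(human_like_trios, rho=0.75, puberty_age=13.0, B=20, seed=9)
        assert np.array_equal(b1.draws, b2.draws)


class TestBatchEffect:
    def test_duplicated_dataset_gives_null_chi2(self, human_like_trios):
        chi2, df, p = batch_effect_lrt(
            [("one", human_like_trios), ("two", human_like_trios)],
            rho=0.75,
            puberty_age=13.0,
        )
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("k,expected_df", [(2, 2), (3, 4)])
    def test_degrees_of_freedom(self, k, expected_df):
        datasets = [
            (f"d{j}", gd.simulate_trios(gd.TrioSimConfig(n_trios=20, seed=j)))
            for j in range(k)
        ]
        _, df, _ = batch_effect_lrt(datasets, rho=0.75, puberty_age=13.0)
        assert df == expected_df

    def test_unfittable_dataset_is_named(self):
        good = gd.simulate_trios(gd.TrioSimConfig(n_trios=20, seed=1))
        bad = [make_trio("only", AP=20.0, AM=20.0, U=30.0)]
        with pytest.raises(ValueError, match="lonely"):
            batch_effect_lrt([("ok", good), ("lonely", bad)], rho=0.75, puberty_age=13.0)
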