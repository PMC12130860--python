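"""Phased-mutation likelihood, its MLE, and the rho grid search."""

import numpy as np
import pytest

import germdecomp as gd
from germdecomp.sex_specific import (
    RhoUnidentifiableError,
    SexSpecificMLE,
    SexSpecificParams,
    fit_sex_specific,
    filter_trios,
    grid_search_rho,
    phase_loglik,
)

from conftest import make_trio


def _unit_trio(UM, UP, UX, AM=5.0, AP=5.0):
    """A trio with L = 1 so per-genome parameters are the means directly."""
    return make_trio("u", AP=AP, AM=AM, U=UM + UP + UX, UP=UP, UM=UM, L=1.0)


class TestPhaseLoglik:
    def test_hand_computed_single_trio(self):
        # means m = 1, p = 2 at ages equal to puberty: UM log m + UP log p
        # + UX log(m+p) - (m+p) = 3 log 2 + log 3 - 3
        params = SexSpecificParams(1.0, 2.0, 0.0, 0.0, reference_L=1.0)
        trio = _unit_trio(UM=2.0, UP=3.0, UX=1.0)
        expected = 3 * np.log(2) + np.log(3) - 3
        assert phase_loglik(params, [trio], 5.0) == pytest.approx(expected)

    def test_zero_counts_leave_only_mean_penalty(self):
        params = SexSpecificParams(1.5, 2.5, 0.1, 0.2, reference_L=1.0)
        trios = [_unit_trio(0.0, 0.0, 0.0, AM=7.0, AP=9.0) for _ in range(3)]
        m = 1.5 + 0.2 * 2.0
        p = 2.5 + 0.1 * 4.0
        assert phase_loglik(params, trios, 5.0) == pytest.approx(-3 * (m + p))

    def test_count_doubling_doubles_data_terms(self):
        params = SexSpecificParams(1.0, 2.0, 0.3, 0.1, reference_L=1.0)
        t1 = _unit_trio(2.0, 3.0, 1.0, AM=8.0, AP=10.0)
        t2 = _unit_trio(4.0, 6.0, 2.0, AM=8.0, AP=10.0)
        m = 1.0 + 0.1 * 3.0
        p = 2.0 + 0.3 * 5.0
        ll1 = phase_loglik(params, [t1], 5.0) + (m + p)
        ll2 = phase_loglik(params, [t2], 5.0) + (m + p)
        assert ll2 == pytest.approx(2 * ll1)

    def test_nonpositive_mean_with_count_returns_neg_inf(self):
        params = SexSpecificParams(0.0, 2.0, 0.0, 0.0, reference_L=1.0)
        trio = _unit_trio(1.0, 0.0, 0.0)
        assert phase_loglik(params, [trio], 5.0) == -np.inf


class TestMLE:
    def test_loglik_at_mle_beats_truth(self):
        """The maximized likelihood dominates the generating parameters."""
        site = 1.0 / 2.68289e9
        for rep in range(5):
            cfg = gd.TrioSimConfig(
                n_trios=200,
                seed=100 + rep,
                true_muEM=3.0 * site,
                true_muEP=6.0 * site,
                true_muS=1.2 * site,
                true_muO=0.3 * site,
                paternal_age_range=(15.0, 33.0),
                maternal_age_range=(15.0, 33.0),
            )
            trios = gd.simulate_trios(cfg)
            res = fit_sex_specific(trios, puberty_age=13.0, seed=rep, reference_L=cfg.L)
            truth = SexSpecificParams(3.0, 6.0, 1.2, 0.3, reference_L=cfg.L)
            assert res.loglik >= phase_loglik(truth, trios, 13.0) - 1e-6

    def test_parameter_recovery_within_monte_carlo_error(self):
        site = 1.0 / 2.68289e9
        truth = np.array([3.0, 6.0, 1.2, 0.3])
        ests = []
        for rep in range(50):
            cfg = gd.TrioSimConfig(
                n_trios=200,
                seed=5000 + rep,
                true_muEM=truth[0] * site,
                true_muEP=truth[1] * site,
                true_muS=truth[2] * site,
                true_muO=truth[3] * site,
                paternal_age_range=(15.0, 33.0),
                maternal_age_range=(15.0, 33.0),
            )
            res = fit_sex_specific(
                gd.simulate_trios(cfg), puberty_age=13.0, seed=rep, reference_L=cfg.L
            )
            p = res.params
            ests.append([p.muEM_genome, p.muEP_genome, p.muS_genome, p.muO_genome])
        ests = np.asarray(ests)
        z = (ests.mean(axis=0) - truth) / (ests.std(axis=0) / np.sqrt(len(ests)))
        assert np.all(np.abs(z) < 3.0), z

    def test_purely_paternal_data_floors_maternal_slope(self):
        rng = np.random.default_rng(1)
        trios = [
            make_trio(
                f"p{i}",
                AP=float(a),
                AM=float(m),
                U=float(u),
                UP=float(u),
                UM=0.0,
                L=1.0,
            )
            for i, (a, m, u) in enumerate(
                zip(rng.uniform(15, 40, 50), rng.uniform(15, 40, 50), rng.poisson(8, 50) + 1)
            )
        ]
        res = fit_sex_specific(trios, puberty_age=13.0, seed=0, reference_L=1.0)
        assert res.boundary_flags["muO_genome"] or res.params.muO_genome < 1e-6
        assert res.rho > 0.9

    def test_maternal_biased_data_gives_rho_below_half(self):
        # aye-aye-like: oocyte rate exceeds spermatogonial rate
        cfg = gd.TrioSimConfig(
            n_trios=150,
            seed=77,
            true_muEM=1e-10,
            true_muEP=1e-10,
            true_muS=2e-10,
            true_muO=1.0e-9,
            puberty_age=3.0,
            paternal_age_range=(4.0, 20.0),
            maternal_age_range=(4.0, 20.0),
            L=2.279228391e9,
            phase_prob=0.5,
        )
        res = fit_sex_specific(gd.simulate_trios(cfg), puberty_age=3.0, seed=0)
        assert res.rho < 0.5

    def test_all_unphased_raises(self):
        trios = [make_trio(f"x{i}", AP=20.0 + i, AM=19.0 + i, U=30.0) for i in range(5)]
        with pytest.raises(RhoUnidentifiableError):
            fit_sex_specific(trios, puberty_age=13.0, seed=0)

    def test_estimator_params_roundtrip(self):
        est = SexSpecificMLE(puberty_age=13.0, n_starts=2, random_state=7)
        assert est.get_params()["puberty_age"] == 13.0
        est.set_params(n_starts=3)
        assert est.n_starts == 3


class TestGridSearch:
    def test_identical_parental_ages_flat_curve(self):
        rng = np.random.default_rng(2)
        trios = [
            make_trio(f"m{i}", AP=float(a), AM=float(a), U=float(u), L=2.2e9)
            for i, (a, u) in enumerate(
                zip(rng.uniform(0.3, 1.5, 20), rng.poisson(20, 20))
            )
        ]
        res = grid_search_rho(trios, puberty_age=0.15)
        assert res.no_power

    def test_recovers_strong_paternal_weighting(self):
        cfg = gd.TrioSimConfig(n_trios=300, seed=11)
        res = grid_search_rho(gd.simulate_trios(cfg), puberty_age=13.0)
        assert abs(res.rho_best - cfg.rho) < 0.1
        assert not res.no_power

    def test_purely_maternal_signal_maximized_at_zero(self):
        cfg = gd.TrioSimConfig(
            n_trios=300,
            seed=13,
            true_muS=0.0,
            true_muO=1.2e-9,
            true_muEM=2e-9,
            true_muEP=2e-9,
            paternal_age_range=(14.0, 45.0),
            maternal_age_range=(14.0, 45.0),
        )
        res = grid_search_rho(gd.simulate_trios(cfg), puberty_age=13.0)
        assert res.rho_best == 0.0

    def test_grid_and_mle_agree_on_well_powered_data(self):
        for rep in range(5):
            cfg = gd.TrioSimConfig(n_trios=300, seed=9000 + rep)
            trios = gd.simulate_trios(cfg)
            mle = fit_sex_specific(trios, puberty_age=13.0, seed=rep)
            grid = grid_search_rho(trios, puberty_age=13.0)
            assert abs(mle.rho - grid.rho_best) < 0.1

    def test_too_few_trios_raise(self):
        with pytest.raises(ValueError):
            grid_search_rho([make_trio("a"), make_trio("b")], puberty_age=10.0)


def test_filter_trios_predicate():
    trios = [make_trio(f"f{i}", AM=10.0 + i) for i in range(6)]
    young = filter_trios(trios, lambda t: t.maternal_age < 13.0)
    assert [t.trio_id for t in young] == ["f0", "f1", "f2"]
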