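"""Latent-state sampler, convergence diagnostics and fit statistics."""

import numpy as np
import pytest
from scipy.stats import kstest

from openscr.mcmc import (McmcConfig, PosteriorDraws, bayes_pvalue,
                          enumerate_trajectories, gelman_rubin, hpd_interval,
                          run_mcmc, sample_phi_gamma, trajectory_log_prior,
                          update_alive_states)
from openscr.model_nonspatial import NonSpatialModel
from openscr.simstudy import build_model
from openscr.simulate import ScenarioConfig, simulate_dataset

from conftest import FixedDetectionModel


class TestTrajectories:
    @pytest.mark.parametrize("T", [1, 2, 3, 5])
    def test_enumeration_counts_and_validity(self, T):
        traj = enumerate_trajectories(T)
        assert len(traj) == T * (T + 1) // 2 + 1
        assert len({tuple(r) for r in traj}) == len(traj)
        for row in traj:  # single contiguous run (no re-entry)
            on = np.flatnonzero(row)
            assert on.size == 0 or np.all(np.diff(on) == 1)

    def test_prior_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        T = 3
        traj = enumerate_trajectories(T)
        phi = rng.uniform(0.1, 0.9, T)
        gamma = rng.uniform(0.1, 0.9, T)
        lp = trajectory_log_prior(phi, gamma, traj)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-12)


class TestUpdateAliveStates:
    def test_detected_years_forced_alive(self):
        rng = np.random.default_rng(1)
        n, T = 20, 3
        detected = np.zeros((n, T), dtype=bool)
        detected[:, 1] = True
        ll = np.full((n, T), -1.0)
        z = update_alive_states(ll, detected, np.full(T, 0.5),
                                np.full(T, 0.3), rng)
        assert z[:, 1].all()

    def test_certain_survival_keeps_animals_alive(self):
        rng = np.random.default_rng(2)
        detected = np.array([[True, False, False]])
        ll = np.zeros((1, 3))
        for _ in range(50):
            z = update_alive_states(ll, detected, np.array([0.0, 1.0, 1.0]),
                                    np.full(3, 0.5), rng)
            assert z.all()

    def test_matches_exhaustive_enumeration(self):
        # 1 augmented animal, 2 years, fixed rates: 4 admissible states
        rng = np.random.default_rng(3)
        phi = np.array([0.0, 0.7])
        gamma = np.array([0.6, 0.4])
        p, K = 0.3, 4
        l_alive = K * np.log1p(-p)  # all-zero history given alive
        weights = {
            (0, 0): (1 - gamma[0]) * (1 - gamma[1]),
            (1, 0): gamma[0] * (1 - phi[1]) * np.exp(l_alive),
            (0, 1): (1 - gamma[0]) * gamma[1] * np.exp(l_alive),
            (1, 1): gamma[0] * phi[1] * np.exp(2 * l_alive),
        }
        total = sum(weights.values())
        expect = {k: v / total for k, v in weights.items()}
        ll = np.full((1, 2), l_alive)
        detected = np.zeros((1, 2), dtype=bool)
        counts = {k: 0 for k in weights}
        n_draw = 20000
        for _ in range(n_draw):
            z = update_alive_states(ll, detected, phi, gamma, rng)
            counts[tuple(int(v) for v in z[0])] += 1
        tv = 0.5 * sum(abs(counts[k] / n_draw - expect[k]) for k in weights)
        assert tv < 0.02


class TestPhiGammaConjugacy:
    def test_certain_counts_concentrate(self):
        rng = np.random.default_rng(4)
        z = np.zeros((400, 3), dtype=bool)
        z[:200] = True  # 200 alive all years, 200 never alive
        phis = np.array([sample_phi_gamma(z, rng)[0][1] for _ in range(200)])
        assert abs(phis.mean() - (201 / 202)) < 0.01  # Beta(201, 1) mean


class TestGelmanRubin:
    def test_identical_chains(self):
        x = np.random.default_rng(5).normal(size=1000)
        assert gelman_rubin(np.stack([x, x, x])) <= 1.0 + 1e-9

    def test_shifted_chains_flag_divergence(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(5, 1, 1000)
        assert gelman_rubin(np.stack([a, b])) > 2.0

    def test_constant_draws_define_unity(self):
        assert gelman_rubin(np.ones((3, 100))) == 1.0

    def test_formula_oracle(self):
        rng = np.random.default_rng(7)
        arr = rng.normal(size=(3, 50))
        C, N = arr.shape
        W = np.mean([np.var(c, ddof=1) for c in arr])
        B = N * np.var([c.mean() for c in arr], ddof=1)
        expect = np.sqrt(((N - 1) / N * W + B / N) / W)
        assert gelman_rubin(arr) == pytest.approx(expect, abs=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))


class TestHpd:
    def test_constant_samples(self):
        assert hpd_interval(np.full(50, 3.3)) == (3.3, 3.3)

    def test_uniform_width(self):
        x = np.random.default_rng(8).random(100000)
        lo, hi = hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_window_search(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.gamma(2.0, 1.0, 40))
        m = int(np.ceil(0.95 * x.size))
        best = min(((x[i + m - 1] - x[i], (x[i], x[i + m - 1]))
                    for i in range(x.size - m + 1)))
        assert hpd_interval(x, 0.95) == pytest.approx(best[1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([])


class TestRunMcmc:
    tiny = ScenarioConfig(density=0.5, g0=0.5, n_side=4, occasions=3)

    def _model(self, seed=0):
        ds, reg, _ = simulate_dataset(self.tiny, np.random.default_rng(seed))
        return build_model("cr", ds, reg, self.tiny.boundary, n_aug=30)

    def test_same_seed_bit_identical(self):
        cfg = McmcConfig(n_chains=2, n_iter=150, n_burnin=50)
        d1 = run_mcmc(self._model(), cfg, seed=9)
        d2 = run_mcmc(self._model(), cfg, seed=9)
        for k in d1.names:
            assert np.array_equal(d1.params[k], d2.params[k]), k

    def test_joint_z_rate_posterior_matches_enumeration(self):
        """One augmented animal, two years: the trajectory marginal after
        integrating phi/gamma over their uniform priors has a closed form
        (each monomial integrates to 1/2)."""
        p, k_occ = 0.3, 3
        model = FixedDetectionModel(p=p, k_occ=k_occ, T=2)
        cfg = McmcConfig(n_chains=2, n_iter=12000, n_burnin=500, pp_every=10 ** 9)
        draws = run_mcmc(model, cfg, seed=10)
        n1 = draws.stacked("N[1]")
        n2 = draws.stacked("N[2]")
        l1 = (1 - p) ** k_occ
        w = {(0, 0): 0.25, (1, 0): 0.25 * l1, (0, 1): 0.25 * l1,
             (1, 1): 0.25 * l1 * l1}
        tot = sum(w.values())
        freq = {s: np.mean((n1 == s[0]) & (n2 == s[1])) for s in w}
        tv = 0.5 * sum(abs(freq[s] - w[s] / tot) for s in w)
        assert tv < 0.02

    def test_prior_recovery_with_likelihood_off(self):
        """With the observation terms disabled the marginal posterior of each
        rate reproduces its Uniform(0,1) prior."""
        ds, reg, _ = simulate_dataset(self.tiny, np.random.default_rng(1))
        model = build_model("cr", ds, reg, self.tiny.boundary, n_aug=20)
        model.prior_only = True
        model.detected[:] = False  # empty data: no forced alive years
        cfg = McmcConfig(n_chains=2, n_iter=3000, n_burnin=200, pp_every=10 ** 9)
        draws = run_mcmc(model, cfg, seed=11)
        # thin to roughly independent draws before the i.i.d. KS test
        assert kstest(draws.stacked("phi[2]")[::10], "uniform").pvalue > 1e-3
        assert kstest(draws.stacked("gamma[2]")[::10], "uniform").pvalue > 1e-3


class TestBayesPvalue:
    def test_tail_probability_from_records(self):
        draws = PosteriorDraws(params={
            "_t_obs": np.array([[1.0, 5.0, 2.0, 7.0]]),
            "_t_rep": np.array([[2.0, 4.0, 1.0, 9.0]]),
        })
        assert bayes_pvalue(draws) == pytest.approx(0.5)

    def test_inflated_data_pushes_p_to_one(self):
        """Histories far denser than a fixed low detection probability give
        observed discrepancies exceeding the replicated ones."""
        n, K, T = 15, 5, 3
        y = np.ones((n, K, 1, T), dtype=np.uint8)  # every occasion a hit
        effort = np.full((K, 1, T), 1.0)
        model = NonSpatialModel(y=y, effort=effort,
                                reference_days=np.array([1.0]), n_aug=0,
                                model="cr")
        state = model.init_state(np.random.default_rng(13))
        state["beta"][:] = -2.0  # p ~ 0.12 while every cell is a hit
        z = np.ones((n, T), dtype=bool)
        rng = np.random.default_rng(14)
        wins = [model.posterior_predictive(state, z, rng) for _ in range(100)]
        p = np.mean([t_obs > t_rep for t_obs, t_rep in wins])
        assert p > 0.95
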