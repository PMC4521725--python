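"""Non-spatial detection model: effort scaling, covariates, likelihood."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.special import expit

from openscr.model_nonspatial import (NonSpatialModel, NonSpatialParams,
                                      cr_log_likelihood,
                                      cumulative_detection_p, detection_p,
                                      effort_scaled_p, impute_dedge,
                                      truncated_gamma_logpdf)


class TestEffortScaling:
    @pytest.mark.parametrize("p,days,ref,expect", [
        (0.3, 0, 42, 0.0),      # no effort, no detection
        (0.3, 42, 42, 0.3),     # reference effort recovers the baseline
        (0.5, 84, 42, 0.75),    # double effort: 1 - 0.5**2
    ])
    def test_values(self, p, days, ref, expect):
        assert effort_scaled_p(p, days, ref) == pytest.approx(expect)

    def test_saturates_towards_one(self):
        assert effort_scaled_p(0.3, 1e6, 42) == pytest.approx(1.0)

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            effort_scaled_p(1.2, 10, 42)

    @given(st.floats(0.01, 0.99), st.floats(0, 300), st.floats(0.1, 300))
    def test_monotone_in_effort_and_base(self, p, days, extra):
        ref = 42.0
        assert effort_scaled_p(p, days + extra, ref) >= effort_scaled_p(p, days, ref)
        p2 = min(p + 0.005, 1.0)
        assert effort_scaled_p(p2, days, ref) >= effort_scaled_p(p, days, ref)


class TestCumulativeDetection:
    @pytest.mark.parametrize("ps,expect", [
        ((0, 0, 0), 0.0),
        ((0.2, 0.5, 0), 0.6),
        ((0.3, 1.0, 0.2), 1.0),
    ])
    def test_values(self, ps, expect):
        assert cumulative_detection_p(ps) == pytest.approx(expect)


class TestDetectionP:
    def test_neutral_logit_gives_half(self):
        params = NonSpatialParams(beta=np.zeros((1, 1)),
                                  dedge=np.zeros(1))
        assert detection_p(params, 0, 0, 0, 42, 42) == pytest.approx(0.5)

    def test_closed_form_with_dedge(self):
        params = NonSpatialParams(beta=np.full((1, 1), -1.0), beta_dedge=-0.1,
                                  dedge=np.array([5.0]))
        expect = expit(-1.5)
        assert detection_p(params, 0, 0, 0, 42, 42) == pytest.approx(expect)
        assert expect == pytest.approx(0.1824, abs=1e-4)

    def test_negative_slope_is_decreasing_in_dedge(self):
        ps = []
        for d in (0.0, 2.0, 5.0, 10.0):
            params = NonSpatialParams(beta=np.zeros((1, 1)), beta_dedge=-0.3,
                                      dedge=np.array([d]))
            ps.append(detection_p(params, 0, 0, 0, 42, 42))
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestImputeDedge:
    def test_truncation_bound_respected(self):
        x = impute_dedge(4.0, 0.25, 2000, rng=1)
        assert np.all(x <= 18.5) and np.all(x >= 0)

    def test_truncated_mean_matches_numeric_integral(self):
        shape, rate, upper = 4.0, 1.0, 18.5
        x = impute_dedge(shape, rate, 40000, rng=2, upper=upper)
        dens = lambda v: np.exp(truncated_gamma_logpdf(v, shape, rate, upper))
        mean_true = quad(lambda v: v * dens(v), 0, upper)[0]
        norm = quad(dens, 0, upper)[0]
        assert norm == pytest.approx(1.0, abs=1e-6)
        assert x.mean() == pytest.approx(mean_true, abs=0.05)

    def test_extreme_truncation_falls_back_to_inversion(self):
        # nearly all mass beyond the bound: acceptance < 5% path
        x = impute_dedge(20.0, 0.2, 500, rng=3, upper=18.5)
        assert np.all(x <= 18.5)

    def test_seed_determinism(self):
        assert np.array_equal(impute_dedge(2.0, 0.5, 50, rng=4),
                              impute_dedge(2.0, 0.5, 50, rng=4))


def brute_force_cr_loglik(params, z, y, effort, ref):
    """Independent oracle: explicit product of Bernoulli terms."""
    n, K, M, T = y.shape
    total = 0.0
    for i in range(n):
        for t in range(T):
            if not z[i, t]:
                continue
            for m in range(M):
                for k in range(K):
                    if effort[k, m, t] <= 0:
                        continue
                    lp = params.beta[m, k]
                    if params.dedge is not None:
                        lp += params.beta_dedge * params.dedge[i]
                    p0 = 1 / (1 + np.exp(-lp))
                    p = 1 - (1 - p0) ** (effort[k, m, t] / ref[m])
                    total += np.log(p) if y[i, k, m, t] else np.log(1 - p)
    return total


class TestCrLogLikelihood:
    def _fixture(self, seed):
        rng = np.random.default_rng(seed)
        n, K, M, T = 5, 3, 2, 2
        z = rng.random((n, T)) < 0.7
        effort = rng.integers(0, 3, (K, M, T)) * 21.0
        params = NonSpatialParams(beta=rng.normal(-1, 0.5, (M, K)),
                                  beta_dedge=-0.1,
                                  dedge=rng.uniform(0, 10, n))
        y = np.zeros((n, K, M, T), dtype=np.uint8)
        mask = (rng.random((n, K, M, T)) < 0.3) & z[:, None, None, :] \
            & (effort > 0)[None, :, :, :]
        y[mask] = 1
        ref = np.array([162.0, 42.0])
        return params, z, y, effort, ref

    def test_all_dead_all_zero_is_zero(self):
        params = NonSpatialParams(beta=np.zeros((1, 2)))
        z = np.zeros((3, 2), dtype=bool)
        y = np.zeros((3, 2, 1, 2), dtype=np.uint8)
        effort = np.full((2, 1, 2), 42.0)
        assert cr_log_likelihood(params, z, y, effort, np.array([42.0])) == 0.0

    def test_single_detection_log_quarter(self):
        # logit(p) chosen so the effort-scaled p is exactly 0.25
        p0 = 0.25
        params = NonSpatialParams(beta=np.full((1, 1), np.log(p0 / (1 - p0))))
        z = np.ones((1, 1), dtype=bool)
        y = np.ones((1, 1, 1, 1), dtype=np.uint8)
        effort = np.full((1, 1, 1), 42.0)
        got = cr_log_likelihood(params, z, y, effort, np.array([42.0]))
        assert got == pytest.approx(np.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force(self, seed):
        params, z, y, effort, ref = self._fixture(seed)
        got = cr_log_likelihood(params, z, y, effort, ref)
        expect = brute_force_cr_loglik(params, z, y, effort, ref)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_impossible_state_rejected(self):
        params = NonSpatialParams(beta=np.zeros((1, 1)))
        z = np.zeros((1, 1), dtype=bool)
        y = np.ones((1, 1, 1, 1), dtype=np.uint8)
        with pytest.raises(ValueError, match="z = 0"):
            cr_log_likelihood(params, z, y, np.full((1, 1, 1), 42.0),
                              np.array([42.0]))

    def test_separable_across_trap_types(self):
        params, z, y, effort, ref = self._fixture(7)
        total = cr_log_likelihood(params, z, y, effort, ref)
        parts = 0.0
        for m in range(y.shape[2]):
            pm = NonSpatialParams(beta=params.beta[[m]],
                                  beta_dedge=params.beta_dedge,
                                  dedge=params.dedge)
            parts += cr_log_likelihood(pm, z, y[:, :, [m], :],
                                       effort[:, [m], :], ref[[m]])
        assert total == pytest.approx(parts, abs=1e-10)


class TestModelLoglik0:
    def test_vectorised_model_matches_reference(self):
        """The sampler's cell-based likelihood equals the reference op."""
        rng = np.random.default_rng(11)
        n_det, K, M, T = 4, 3, 2, 2
        effort = rng.integers(0, 3, (K, M, T)) * 21.0
        y = np.zeros((n_det, K, M, T), dtype=np.uint8)
        y[(rng.random(y.shape) < 0.4) & (effort > 0)[None]] = 1
        y[0, np.argmax(effort.sum((1, 2)) > 0)] = \
            y[0, np.argmax(effort.sum((1, 2)) > 0)]  # ensure >= 1 detection
        ref = np.array([162.0, 42.0])
        model = NonSpatialModel(y=y, effort=effort, reference_days=ref,
                                n_aug=2, model="cr")
        state = model.init_state(rng)
        ll = model.loglik0(state)
        # shared-occasion model: only the first occasion column is live
        params = NonSpatialParams(beta=np.repeat(state["beta"][:, :1], K, axis=1))
        z = np.ones((model.n_individuals, T), dtype=bool)
        yfull = np.zeros((model.n_individuals, K, M, T), dtype=np.uint8)
        yfull[:n_det] = y
        expect = brute_force_cr_loglik(params, z, yfull, effort, ref)
        assert (ll * z).sum() == pytest.approx(expect, abs=1e-9)
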