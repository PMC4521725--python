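"""Non-spatial capture-recapture observation models (CR and CR_dedge).

Detection of individual *i* at trap type *m* on occasion *k* in year *t* is
Bernoulli with a baseline probability on the logit scale,

    logit(p_ikm) = B_mk (+ male effect) (+ B_distedge * DEDGE_i),

scaled for survey effort with a proportional-hazard form,

    p_effort = 1 - (1 - p)^(NDays_kmt / ReferenceDays_m),

so that detection probability is 0 with no effort and approaches 1 as effort
grows.  The CR variant fixes the distance-to-edge slope at zero; CR_dedge
uses each detected animal's observed distance from its home-range centre to
the study-area edge and imputes a latent DEDGE for augmented (never-detected)
animals from a truncated Gamma(shape, rate) distribution whose parameters are
estimated from the observed animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammainc, gammaln, logit
from scipy.stats import gamma as gamma_dist

__all__ = [
    "NonSpatialParams",
    "effort_scaled_p",
    "cumulative_detection_p",
    "detection_p",
    "impute_dedge",
    "truncated_gamma_logpdf",
    "cr_log_likelihood",
    "NonSpatialModel",
]

_PCLIP = 1e-12


def effort_scaled_p(p_base, n_days, reference_days):
    """Proportional-hazard effort scaling of a detection probability.

    ``1 - (1 - p)**(n_days / reference_days)``: equals 0 when no trap-days
    were accumulated, ``p_base`` at the reference effort, and tends to 1 as
    effort grows without bound.  Vectorised over all arguments.
    """
    p = np.asarray(p_base, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_base must lie in [0, 1]")
    ref = np.asarray(reference_days, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference_days must be positive")
    n = np.asarray(n_days, dtype=float)
    if np.any(n < 0):
        raise ValueError("n_days must be nonnegative")
    out = 1.0 - (1.0 - p) ** (n / ref)
    return out if out.ndim else float(out)


def cumulative_detection_p(p_by_type):
    """Probability of detection by at least one trap type in an occasion.

    ``1 - prod(1 - p_m)`` over the per-type (effort-scaled) probabilities.
    """
    p = np.asarray(p_by_type, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


@dataclass
class NonSpatialParams:
    """Parameters of the CR / CR_dedge observation model.

    ``beta`` is indexed ``[trap_type, occasion]`` on the logit scale;
    ``beta_male`` is an additive male effect per trap type (combined-sex
    models only).  ``dedge`` holds one value per individual: observed (fixed)
    for detected animals, latent for augmented ones.
    """

    beta: np.ndarray
    beta_dedge: float = 0.0
    beta_male: np.ndarray | None = None
    shape_dedge: float = 1.0
    rate_dedge: float = 1.0
    dedge: np.ndarray | None = None
    is_male: np.ndarray | None = None
    p_male: float = 0.5
    dedge_max: float = 18.5

    def logit_p(self, i: int, k: int, m: int) -> float:
        v = self.beta[m, k]
        if self.beta_male is not None and self.is_male is not None and self.is_male[i]:
            v += self.beta_male[m]
        if self.dedge is not None:
            v += self.beta_dedge * self.dedge[i]
        return float(v)


def detection_p(params: NonSpatialParams, i: int, k: int, m: int,
                n_days: float, reference_days: float) -> float:
    """Effort-scaled detection probability for one individual/occasion/type."""
    return effort_scaled_p(expit(params.logit_p(i, k, m)), n_days, reference_days)


def truncated_gamma_logpdf(x, shape, rate, upper):
    """Log density of Gamma(shape, rate) truncated to [0, upper].

    Written with scipy.special ufuncs (regularised lower incomplete gamma for
    the normalisation) so it stays cheap inside tight MCMC loops.
    """
    x = np.asarray(x, dtype=float)
    norm = float(gammainc(shape, rate * upper))
    if norm <= 0:
        return np.full(x.shape, -np.inf) if x.ndim else -np.inf
    with np.errstate(divide="ignore"):
        lp = ((shape - 1.0) * np.log(x) - rate * x
              + shape * np.log(rate) - gammaln(shape) - np.log(norm))
    lp = np.where((x >= 0) & (x <= upper), lp, -np.inf)
    return lp if lp.ndim else float(lp)


def impute_dedge(shape: float, rate: float, n: int,
                 rng: np.random.Generator | int | None = None,
                 upper: float = 18.5) -> np.ndarray:
    """Draw ``n`` distance-to-edge values from a truncated gamma prior.

    Rejection sampling against the untruncated gamma; when the acceptance
    probability ``F(upper)`` is poor (< 5%) the draw falls back to inverting
    the CDF on [0, F(upper)], which is exact for any truncation point.
    """
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    accept_p = gamma_dist.cdf(upper, shape, scale=1.0 / rate)
    if accept_p < 0.05:
        u = rng.random(n) * accept_p
        return gamma_dist.ppf(u, shape, scale=1.0 / rate)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.gamma(shape, 1.0 / rate, size=max(n - filled, 16))
        keep = draw[draw <= upper]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _cell_log_bernoulli(y, p):
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    return np.where(y > 0, np.log(p), np.log1p(-p))


def cr_log_likelihood(params: NonSpatialParams, z: np.ndarray,
                      y: np.ndarray, effort: np.ndarray,
                      reference_days: np.ndarray) -> float:
    """Log-likelihood of the non-spatial detection histories.

    ``y`` is the binary ``(n, K, M, T)`` per-type view, ``z`` the ``(n, T)``
    alive indicators, ``effort[k, m, t]`` the active trap-days and
    ``reference_days[m]`` the per-type reference.  Individual-years with
    z = 0 contribute nothing; a positive detection in such a year is an
    impossible state and raises.  Cells with zero effort are excluded (their
    detection probability is identically zero).
    """
    y = np.asarray(y)
    z = np.asarray(z, dtype=bool)
    n, K, M, T = y.shape
    if np.any(y.astype(bool) & ~z[:, None, None, :]):
        raise ValueError("detection recorded in a year with z = 0")
    total = 0.0
    for m in range(M):
        for k in range(K):
            for t in range(T):
                if effort[k, m, t] <= 0:
                    continue
                for i in range(n):
                    if not z[i, t]:
                        continue
                    p = detection_p(params, i, k, m, effort[k, m, t],
                                    reference_days[m])
                    total += _cell_log_bernoulli(y[i, k, m, t], p)
    return float(total)


@dataclass
class NonSpatialModel:
    """Sampler-facing CR / CR_dedge model on flattened active cells.

    Wraps the detection history of the detected individuals plus ``n_aug``
    all-zero augmented rows.  Provides the per-individual-year log-likelihood
    used by the latent-state update, Metropolis updates for its own
    parameters, and posterior-predictive replication for goodness of fit.

    Parameters are held in a state dict so independent chains do not share
    mutable arrays.
    """

    y: np.ndarray  # (n_det, K, M, T) binary
    effort: np.ndarray  # (K, M, T) trap-days
    reference_days: np.ndarray  # (M,)
    n_aug: int
    model: str = "cr"  # "cr" | "cr_dedge"
    dedge_obs: np.ndarray | None = None  # (n_det,) observed DEDGE, km
    dedge_max: float = 18.5
    occasion_specific: bool = False
    sex_obs: np.ndarray | None = None  # (n_det,) bool male, enables sex terms
    prior_only: bool = False
    beta_bound: float = 10.0
    gamma_param_bound: float = 30.0

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.uint8)
        n_det, K, M, T = self.y.shape
        self.n_detected = n_det
        self.n_individuals = n_det + self.n_aug
        self.T = T
        act = np.asarray(self.effort) > 0
        self.cells = np.argwhere(act)  # rows (k, m, t)
        kk, mm, tt = self.cells.T
        self.cell_expo = (np.asarray(self.effort, float)[kk, mm, tt]
                          / np.asarray(self.reference_days, float)[mm])
        self.cell_year = tt
        self.cell_type = mm
        self.cell_occ = kk
        yfull = np.zeros((self.n_individuals, K, M, T), dtype=np.uint8)
        yfull[:n_det] = self.y
        self.y_cells = yfull[:, kk, mm, tt].astype(float)  # (n, C)
        self._year_ind = np.equal.outer(tt, np.arange(T)).astype(float)  # (C, T)
        self.detected = np.zeros((self.n_individuals, T), dtype=bool)
        self.detected[:n_det] = self.y.reshape(n_det, -1, T).any(axis=1)
        if self.prior_only:
            # prior-recovery mode: no data, so no z constraints either
            self.detected[:] = False
        if self.model == "cr_dedge" and self.dedge_obs is None:
            raise ValueError("cr_dedge requires observed DEDGE values")
        self.use_sex = self.sex_obs is not None
        self.n_free_beta = M * (K if self.occasion_specific else 1)

    # -- state -------------------------------------------------------------
    def init_state(self, rng: np.random.Generator) -> dict:
        K, M = self.y.shape[1], self.y.shape[2]
        crude = self.y_cells[: self.n_detected].mean() if self.n_detected else 0.1
        b0 = logit(np.clip(crude, 0.02, 0.5))
        beta = np.full((M, K), b0) + rng.normal(0, 0.2, (M, K))
        state = {
            "beta": beta,
            "beta_dedge": 0.0,
            "step_beta": np.full((M, K), 0.3),
            "step_dedge_slope": 0.1,
        }
        if self.use_sex:
            state["beta_male"] = rng.normal(0, 0.2, M)
            state["step_beta_male"] = np.full(M, 0.3)
            obs_male = np.asarray(self.sex_obs, dtype=bool)
            is_male = np.zeros(self.n_individuals, dtype=bool)
            is_male[: self.n_detected] = obs_male
            is_male[self.n_detected:] = rng.random(self.n_aug) < 0.5
            state["is_male"] = is_male
            state["p_male"] = 0.5
        if self.model == "cr_dedge":
            obs = np.asarray(self.dedge_obs, dtype=float)
            state["shape_dedge"] = 2.0 + rng.normal(0, 0.1)
            state["rate_dedge"] = max(state["shape_dedge"] / max(obs.mean(), 0.5), 0.05)
            dedge = np.empty(self.n_individuals)
            dedge[: self.n_detected] = obs
            dedge[self.n_detected:] = impute_dedge(
                state["shape_dedge"], state["rate_dedge"], self.n_aug, rng,
                upper=self.dedge_max)
            state["dedge"] = dedge
            state["beta_dedge"] = rng.normal(0, 0.05)
            state["step_dedge"] = np.full(self.n_aug, 2.0)
            state["step_shape"] = 0.3
            state["step_rate"] = 0.1
        return state

    def _logit_p_cells(self, state, rows=None) -> np.ndarray:
        """Logit baseline p per (individual, cell); rows selects individuals."""
        beta = state["beta"]
        occ = self.cell_occ if self.occasion_specific else np.zeros_like(self.cell_occ)
        base = beta[self.cell_type, occ]  # (C,)
        n = self.n_individuals if rows is None else len(rows)
        lp = np.broadcast_to(base, (n, base.size)).copy()
        if self.use_sex:
            male = state["is_male"] if rows is None else state["is_male"][rows]
            lp += male[:, None] * state["beta_male"][self.cell_type][None, :]
        if self.model == "cr_dedge":
            dedge = state["dedge"] if rows is None else state["dedge"][rows]
            lp += state["beta_dedge"] * dedge[:, None]
        return lp

    def _p_cells(self, state, rows=None, dedge_override=None) -> np.ndarray:
        lp = self._logit_p_cells(state, rows)
        if dedge_override is not None:
            base_dedge = state["dedge"] if rows is None else state["dedge"][rows]
            lp = lp + state["beta_dedge"] * (dedge_override - base_dedge)[:, None]
        p0 = expit(lp)
        return 1.0 - (1.0 - p0) ** self.cell_expo[None, :]

    def loglik0(self, state, rows=None, dedge_override=None) -> np.ndarray:
        """(n, T) log P(y_i,:,t | z_it = 1) summed over active cells."""
        n = self.n_individuals if rows is None else len(rows)
        if self.prior_only:
            return np.zeros((n, self.T))
        p = self._p_cells(state, rows, dedge_override)
        yc = self.y_cells if rows is None else self.y_cells[rows]
        terms = _cell_log_bernoulli(yc, p)
        return terms @ self._year_ind

    # -- parameter updates ---------------------------------------------------
    def _total_loglik(self, state, z) -> float:
        # cached across the sequential Metropolis updates of one iteration
        if state.get("_cur_ll") is None:
            state["_cur_ll"] = float((self.loglik0(state) * z).sum())
        return state["_cur_ll"]

    def update_params(self, state, z, rng, adapt: bool,
                      loglik0_current: np.ndarray | None = None) -> None:
        state["_cur_ll"] = None if loglik0_current is None else \
            float((loglik0_current * z).sum())
        self._update_betas(state, z, rng, adapt)
        if self.model == "cr_dedge":
            self._update_dedge_latent(state, z, rng, adapt)
            self._update_gamma_params(state, rng, adapt)
        if self.use_sex:
            self._update_sex(state, z, rng)
            state["_cur_ll"] = None

    def _mh_scalar(self, state, z, key, step_key, bound, rng, adapt,
                   index=None):
        cur = self._total_loglik(state, z)
        ref = state[key] if index is None else state[key][index]
        step = state[step_key] if index is None else state[step_key][index]
        prop = ref + rng.normal(0, step)
        if abs(prop) <= bound:
            if index is None:
                state[key] = prop
            else:
                state[key][index] = prop
            new = float((self.loglik0(state) * z).sum())
            if np.log(rng.random()) < new - cur:
                accepted = True
                state["_cur_ll"] = new
            else:
                accepted = False
                if index is None:
                    state[key] = ref
                else:
                    state[key][index] = ref
        else:
            accepted = False
        if adapt:
            fac = np.exp(0.05 if accepted else -0.02)
            if index is None:
                state[step_key] = float(np.clip(step * fac, 1e-3, 5.0))
            else:
                state[step_key][index] = np.clip(step * fac, 1e-3, 5.0)
        return accepted

    def _update_betas(self, state, z, rng, adapt):
        M, K = state["beta"].shape
        occs = range(K) if self.occasion_specific else (0,)
        for m in range(M):
            for k in occs:
                if self.occasion_specific and self.effort[k, m].max() <= 0:
                    continue
                self._mh_scalar(state, z, "beta", "step_beta",
                                self.beta_bound, rng, adapt, index=(m, k))
            if not self.occasion_specific:
                state["beta"][m, :] = state["beta"][m, 0]
        if self.use_sex:
            for m in range(M):
                self._mh_scalar(state, z, "beta_male", "step_beta_male",
                                self.beta_bound, rng, adapt, index=(m,))
        if self.model == "cr_dedge":
            self._mh_scalar(state, z, "beta_dedge", "step_dedge_slope",
                            self.beta_bound, rng, adapt)

    def _update_dedge_latent(self, state, z, rng, adapt):
        """Metropolis update of latent DEDGE for augmented individuals."""
        if self.n_aug == 0:
            return
        rows = np.arange(self.n_detected, self.n_individuals)
        cur = state["dedge"][rows]
        prop = _reflect(cur + rng.normal(0, state["step_dedge"]),
                        0.0, self.dedge_max)
        shape, rate = state["shape_dedge"], state["rate_dedge"]
        lp_prior = (truncated_gamma_logpdf(prop, shape, rate, self.dedge_max)
                    - truncated_gamma_logpdf(cur, shape, rate, self.dedge_max))
        if self.prior_only:
            dlik = np.zeros(len(rows))
        else:
            ll_new = self.loglik0(state, rows=rows, dedge_override=prop)
            ll_old = self.loglik0(state, rows=rows)
            dlik = ((ll_new - ll_old) * z[rows]).sum(axis=1)
        acc = np.log(rng.random(len(rows))) < lp_prior + dlik
        state["dedge"][rows[acc]] = prop[acc]
        if state.get("_cur_ll") is not None and not self.prior_only:
            state["_cur_ll"] += float(((ll_new - ll_old)[acc] * z[rows[acc]]).sum())
        if adapt:
            state["step_dedge"] *= np.where(acc, np.exp(0.05), np.exp(-0.02))
            np.clip(state["step_dedge"], 0.05, self.dedge_max, out=state["step_dedge"])

    def _update_gamma_params(self, state, rng, adapt):
        """Metropolis on (shape, rate) of the truncated-gamma DEDGE prior.

        Observed DEDGE values are fixed data contributing to this likelihood
        alongside the latent values of the augmented animals.
        """
        x = state["dedge"]
        for key, step_key in (("shape_dedge", "step_shape"),
                              ("rate_dedge", "step_rate")):
            cur = state[key]
            prop = cur + rng.normal(0, state[step_key])
            accepted = False
            if 0.0 < prop <= self.gamma_param_bound:
                args_cur = (state["shape_dedge"], state["rate_dedge"])
                args_new = (prop if key == "shape_dedge" else args_cur[0],
                            prop if key == "rate_dedge" else args_cur[1])
                ll_cur = truncated_gamma_logpdf(x, *args_cur, self.dedge_max).sum()
                ll_new = truncated_gamma_logpdf(x, *args_new, self.dedge_max).sum()
                if np.log(rng.random()) < ll_new - ll_cur:
                    state[key] = float(prop)
                    accepted = True
            if adapt:
                state[step_key] = float(np.clip(
                    state[step_key] * np.exp(0.05 if accepted else -0.02),
                    1e-3, 10.0))

    def _update_sex(self, state, z, rng):
        """Gibbs draw of augmented sexes and conjugate update of p_male."""
        if self.n_aug:
            rows = np.arange(self.n_detected, self.n_individuals)
            aug_mask = np.zeros(self.n_individuals, dtype=bool)
            aug_mask[rows] = True
            state_f = dict(state, is_male=np.where(aug_mask, False, state["is_male"]))
            state_m = dict(state, is_male=np.where(aug_mask, True, state["is_male"]))
            if self.prior_only:
                ll_f = ll_m = np.zeros(len(rows))
            else:
                ll_f = (self.loglik0(state_f, rows=rows) * z[rows]).sum(axis=1)
                ll_m = (self.loglik0(state_m, rows=rows) * z[rows]).sum(axis=1)
            pm = state["p_male"]
            logit_post = np.log(pm) - np.log1p(-pm) + ll_m - ll_f
            state["is_male"][rows] = rng.random(len(rows)) < expit(logit_post)
        n_male = int(state["is_male"].sum())
        state["p_male"] = float(rng.beta(1 + n_male,
                                         1 + self.n_individuals - n_male))

    # -- recording and fit ---------------------------------------------------
    def record(self, state, z) -> dict:
        out = {}
        M, K = state["beta"].shape
        occs = range(K) if self.occasion_specific else (0,)
        for m in range(M):
            for k in occs:
                out[f"beta[{m},{k}]"] = float(state["beta"][m, k])
        if self.model == "cr_dedge":
            out["beta_dedge"] = float(state["beta_dedge"])
            out["shape_dedge"] = float(state["shape_dedge"])
            out["rate_dedge"] = float(state["rate_dedge"])
        if self.use_sex:
            out["p_male"] = float(state["p_male"])
        return out

    def posterior_predictive(self, state, z, rng) -> tuple[float, float]:
        """Freeman-Tukey discrepancies for observed and replicated data.

        Cells are individual x trap-type x occasion x year restricted to
        currently-alive individual-years.
        """
        p = self._p_cells(state)
        alive = z[:, self.cell_year].astype(bool)
        pa = np.clip(p[alive], _PCLIP, 1 - _PCLIP)
        ya = self.y_cells[alive]
        t_obs = float(((np.sqrt(ya) - np.sqrt(pa)) ** 2).sum())
        yrep = (rng.random(pa.shape) < pa).astype(float)
        t_rep = float(((np.sqrt(yrep) - np.sqrt(pa)) ** 2).sum())
        return t_obs, t_rep


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (symmetric proposal preserving)."""
    width = hi - lo
    x = np.mod(np.asarray(x, dtype=float) - lo, 2 * width)
    x = np.where(x > width, 2 * width - x, x)
    return x + lo
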