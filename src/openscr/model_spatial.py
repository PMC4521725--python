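"""Spatial capture-recapture (SCR) observation model.

Each individual carries a latent activity centre s_i on a rectangular state
space (the trap array buffered outward).  Detection of individual *i* at trap
*j* on occasion *k* is Bernoulli with the bivariate half-normal kernel

    p_ijk = g0_km * exp(-d_ij**2 / (2 * sigma**2)),

where d_ij is the distance between the centre and the trap, g0 the detection
probability at distance zero (logit-linear in trap type, occasion and sex)
and sigma the movement scale (optionally sex-specific).  Effort enters as a
binary trap-occasion activity mask; occasions with identical detection
probability are pooled into binomial cells for speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "SpatialParams",
    "halfnormal_p",
    "scr_log_likelihood",
    "propose_centre",
    "SpatialModel",
]

_PCLIP = 1e-12


def halfnormal_p(distance, g0, sigma):
    """Half-normal detection probability ``g0 * exp(-d^2 / (2 sigma^2))``."""
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    g0 = np.asarray(g0, dtype=float)
    if np.any(g0 < 0) or np.any(g0 > 1):
        raise ValueError("g0 must lie in [0, 1]")
    d = np.asarray(distance, dtype=float)
    out = g0 * np.exp(-(d ** 2) / (2.0 * np.asarray(sigma, float) ** 2))
    return out if out.ndim else float(out)


@dataclass
class SpatialParams:
    """Parameters of the SCR observation model.

    ``g0_logit`` is indexed ``[trap_type, occasion]``; ``sigma`` maps sex
    label to the movement scale in km; ``centres`` holds one activity centre
    per (real + augmented) individual.
    """

    g0_logit: np.ndarray
    sigma: float | np.ndarray
    centres: np.ndarray
    state_space: tuple  # (xmin, xmax, ymin, ymax)
    g0_male: np.ndarray | None = None
    is_male: np.ndarray | None = None

    def sigma_of(self, i: int) -> float:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim == 0:
            return float(s)
        return float(s[1 if self.is_male is not None and self.is_male[i] else 0])

    def g0_of(self, i: int, k: int, m: int) -> float:
        v = self.g0_logit[m, k]
        if self.g0_male is not None and self.is_male is not None and self.is_male[i]:
            v += self.g0_male[m]
        return float(expit(v))


def scr_log_likelihood(params: SpatialParams, z: np.ndarray, y: np.ndarray,
                       trap_coords: np.ndarray, trap_type_index: np.ndarray,
                       activity_mask: np.ndarray) -> float:
    """Log-likelihood of spatial detection histories.

    ``y`` is the binary ``(n, J, K, T)`` per-trap view, ``activity_mask``
    boolean ``(J, K, T)`` marking trap-occasions with effort.  Alive
    individual-years contribute Bernoulli terms at every active trap-occasion
    (including all-zero histories); a detection at an inactive cell or in a
    year with z = 0 raises.
    """
    y = np.asarray(y)
    z = np.asarray(z, dtype=bool)
    n, J, K, T = y.shape
    if np.any(y.astype(bool) & ~activity_mask[None, :, :, :]):
        raise ValueError("detection at an inactive trap-occasion")
    if np.any(y.astype(bool) & ~z[:, None, None, :]):
        raise ValueError("detection recorded in a year with z = 0")
    total = 0.0
    for i in range(n):
        si = params.centres[i]
        sig = params.sigma_of(i)
        for j in range(J):
            d = float(np.hypot(si[0] - trap_coords[j, 0], si[1] - trap_coords[j, 1]))
            m = int(trap_type_index[j])
            for k in range(K):
                for t in range(T):
                    if not activity_mask[j, k, t] or not z[i, t]:
                        continue
                    p = halfnormal_p(d, params.g0_of(i, k, m), sig)
                    p = min(max(p, _PCLIP), 1 - _PCLIP)
                    total += np.log(p) if y[i, j, k, t] else np.log1p(-p)
    return float(total)


def propose_centre(current: np.ndarray, step: float, state_space: tuple,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Symmetric random-walk proposal for activity centres, reflected at the
    state-space rectangle so the uniform prior is the invariant distribution.

    ``current`` may be a single point or an ``(n, 2)`` array.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cur = np.asarray(current, dtype=float)
    pts = cur.reshape(-1, 2).copy()
    xmin, xmax, ymin, ymax = state_space
    if step > 0:
        pts = pts + rng.normal(0.0, step, pts.shape)
    pts[:, 0] = _reflect(pts[:, 0], xmin, xmax)
    pts[:, 1] = _reflect(pts[:, 1], ymin, ymax)
    return pts.reshape(cur.shape)


def _reflect(x, lo, hi):
    width = hi - lo
    x = np.mod(np.asarray(x, dtype=float) - lo, 2 * width)
    x = np.where(x > width, 2 * width - x, x)
    return x + lo


@dataclass
class SpatialModel:
    """Sampler-facing SCR model over pooled binomial detection cells.

    Occasions sharing a detection class (trap type, or trap type x occasion
    when ``occasion_specific``) are pooled: cell (j, c, t) has ``trials``
    active occasions and a binomial count for each individual.  This is exact
    because p is constant within a class.
    """

    y: np.ndarray  # (n_det, J, K, T) binary
    trap_coords: np.ndarray  # (J, 2)
    trap_type_index: np.ndarray  # (J,) index into trap classes' type axis
    activity_mask: np.ndarray  # (J, K, T) bool
    state_space: tuple  # (xmin, xmax, ymin, ymax)
    n_aug: int
    occasion_specific: bool = False
    sex_obs: np.ndarray | None = None  # (n_det,) bool male -> sex-specific sigma
    sigma_bound: float = 15.0
    beta_bound: float = 10.0
    prior_only: bool = False
    obs_centres: np.ndarray | None = None  # (n_det, 2) initial centres

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.uint8)
        n_det, J, K, T = self.y.shape
        self.n_detected = n_det
        self.n_individuals = n_det + self.n_aug
        self.T = T
        self.J = J
        self.n_types = int(np.max(self.trap_type_index)) + 1 if J else 1
        if self.occasion_specific:
            self.classes = [(m, k) for m in range(self.n_types) for k in range(K)]
        else:
            self.classes = [(m, None) for m in range(self.n_types)]
        C = len(self.classes)
        self.trials = np.zeros((J, C, T))
        yfull = np.zeros((self.n_individuals, J, K, T), dtype=np.uint8)
        yfull[:n_det] = self.y
        self.counts = np.zeros((self.n_individuals, J, C, T))
        for c, (m, k) in enumerate(self.classes):
            sel_j = self.trap_type_index == m
            occ = slice(None) if k is None else slice(k, k + 1)
            self.trials[sel_j, c, :] = self.activity_mask[sel_j, occ, :].sum(axis=1)
            self.counts[:, sel_j, c, :] = yfull[:, sel_j, occ, :].sum(axis=2)
        if np.any(self.counts > self.trials[None]):
            raise ValueError("detection at an inactive trap-occasion")
        self.detected = np.zeros((self.n_individuals, T), dtype=bool)
        self.detected[:n_det] = self.y.reshape(n_det, -1, T).any(axis=1)
        if self.prior_only:
            # prior-recovery mode: no data, so no z constraints either
            self.detected[:] = False
        self.sigma_by_sex = self.sex_obs is not None
        self.K = K
        # sparse positive counts: detection matrices are overwhelmingly zero,
        # so the likelihood is the all-zero mass plus corrections here
        nz = np.nonzero(self.counts)
        self._nz = tuple(ax.copy() for ax in nz)
        self._nz_vals = self.counts[nz]

    # -- state -------------------------------------------------------------
    def init_state(self, rng: np.random.Generator) -> dict:
        xmin, xmax, ymin, ymax = self.state_space
        centres = np.column_stack([
            rng.uniform(xmin, xmax, self.n_individuals),
            rng.uniform(ymin, ymax, self.n_individuals),
        ])
        if self.obs_centres is not None and self.n_detected:
            centres[: self.n_detected] = self.obs_centres
        span = max(xmax - xmin, ymax - ymin)
        state = {
            "g0_logit": np.full(len(self.classes), logit(0.1))
            + rng.normal(0, 0.2, len(self.classes)),
            "centres": centres,
            "step_centre": np.full(self.n_individuals, span / 20.0),
            "step_g0": np.full(len(self.classes), 0.3),
            "step_sigma": 0.2,
        }
        if self.sigma_by_sex:
            state["sigma"] = np.array([
                rng.uniform(0.2, 0.8) * self.sigma_bound / 2,
                rng.uniform(0.2, 0.8) * self.sigma_bound / 2,
            ])
            is_male = np.zeros(self.n_individuals, dtype=bool)
            is_male[: self.n_detected] = np.asarray(self.sex_obs, bool)
            is_male[self.n_detected:] = rng.random(self.n_aug) < 0.5
            state["is_male"] = is_male
            state["p_male"] = 0.5
        else:
            state["sigma"] = np.array([rng.uniform(0.2, 0.8) * self.sigma_bound / 2])
        return state

    def _sigma_vec(self, state, rows=None) -> np.ndarray:
        if self.sigma_by_sex:
            male = state["is_male"] if rows is None else state["is_male"][rows]
            return state["sigma"][male.astype(int)]
        n = self.n_individuals if rows is None else len(rows)
        return np.full(n, state["sigma"][0])

    def _kernel(self, state, centres=None, rows=None) -> np.ndarray:
        """exp(-d^2 / (2 sigma^2)) as an (n, J) matrix."""
        c = state["centres"] if centres is None else centres
        if rows is not None and centres is None:
            c = c[rows]
        d2 = ((c[:, None, :] - self.trap_coords[None, :, :]) ** 2).sum(axis=2)
        sig = self._sigma_vec(state, rows)
        return np.exp(-d2 / (2.0 * sig[:, None] ** 2))

    def loglik0(self, state, rows=None, centres=None) -> np.ndarray:
        """(n, T) log P(y_i,:,:,t | z_it = 1).

        The all-zero binomial mass ``trials * log(1 - p)`` is a dense tensor
        contraction; positive counts (sparse) contribute the correction
        ``count * (log p - log(1 - p))``.
        """
        n = self.n_individuals if rows is None else len(rows)
        if self.prior_only:
            return np.zeros((n, self.T))
        kern = self._kernel(state, centres=centres, rows=rows)
        g0 = expit(state["g0_logit"])
        p = np.clip(kern[:, :, None] * g0[None, None, :], _PCLIP, 1 - _PCLIP)
        log1mp = np.log1p(-p)
        out = np.tensordot(log1mp, self.trials, axes=([1, 2], [0, 1]))
        ii, jj, cc, tt = self._nz
        if ii.size:
            if rows is None:
                ir = ii
                keep = slice(None)
            else:
                rows = np.asarray(rows)
                keep = np.isin(ii, rows)
                if not keep.any():
                    return out
                ir = np.searchsorted(rows, ii[keep])
            lp = np.log(p[ir, jj[keep], cc[keep]])
            l1 = log1mp[ir, jj[keep], cc[keep]]
            np.add.at(out, (ir, tt[keep]), self._nz_vals[keep] * (lp - l1))
        return out

    # -- parameter updates ---------------------------------------------------
    def update_params(self, state, z, rng, adapt: bool,
                      loglik0_current: np.ndarray | None = None) -> None:
        state["_cur_ll"] = None if loglik0_current is None else \
            float((loglik0_current * z).sum())
        self._update_centres(state, z, rng, adapt, loglik0_current)
        self._update_g0(state, z, rng, adapt)
        self._update_sigma(state, z, rng, adapt)
        if self.sigma_by_sex:
            self._update_sex(state, z, rng)
            state["_cur_ll"] = None

    def _total_loglik(self, state, z) -> float:
        if self.prior_only:
            return 0.0
        if state.get("_cur_ll") is None:
            state["_cur_ll"] = float((self.loglik0(state) * z).sum())
        return state["_cur_ll"]

    def _update_centres(self, state, z, rng, adapt, loglik0_current=None):
        cur = state["centres"]
        steps = state["step_centre"][:, None]
        cand = cur + rng.normal(0, 1, cur.shape) * steps
        xmin, xmax, ymin, ymax = self.state_space
        cand[:, 0] = _reflect(cand[:, 0], xmin, xmax)
        cand[:, 1] = _reflect(cand[:, 1], ymin, ymax)
        if self.prior_only:
            delta = np.zeros(self.n_individuals)
        else:
            ll_new = self.loglik0(state, centres=cand)
            ll_old = loglik0_current if loglik0_current is not None \
                else self.loglik0(state)
            delta = ((ll_new - ll_old) * z).sum(axis=1)
        acc = np.log(rng.random(self.n_individuals)) < delta
        cur[acc] = cand[acc]
        if state.get("_cur_ll") is not None and not self.prior_only:
            state["_cur_ll"] += float(delta[acc].sum())
        if adapt:
            state["step_centre"] *= np.where(acc, np.exp(0.05), np.exp(-0.02))
            span = max(xmax - xmin, ymax - ymin)
            np.clip(state["step_centre"], span / 200, span, out=state["step_centre"])

    def _update_g0(self, state, z, rng, adapt):
        for c in range(len(state["g0_logit"])):
            if self.trials[:, c, :].max() <= 0:
                continue
            cur_ll = self._total_loglik(state, z)
            old = state["g0_logit"][c]
            prop = old + rng.normal(0, state["step_g0"][c])
            accepted = False
            if abs(prop) <= self.beta_bound:
                state["g0_logit"][c] = prop
                new_ll = float((self.loglik0(state) * z).sum()) \
                    if not self.prior_only else 0.0
                if np.log(rng.random()) < new_ll - cur_ll:
                    accepted = True
                    state["_cur_ll"] = new_ll
                else:
                    state["g0_logit"][c] = old
            if adapt:
                state["step_g0"][c] = np.clip(
                    state["step_g0"][c] * np.exp(0.05 if accepted else -0.02),
                    1e-3, 5.0)

    def _update_sigma(self, state, z, rng, adapt):
        for s in range(state["sigma"].size):
            cur_ll = self._total_loglik(state, z)
            old = state["sigma"][s]
            prop = old + rng.normal(0, state["step_sigma"])
            accepted = False
            if 0.0 < prop <= self.sigma_bound:
                state["sigma"][s] = prop
                new_ll = float((self.loglik0(state) * z).sum()) \
                    if not self.prior_only else 0.0
                if np.log(rng.random()) < new_ll - cur_ll:
                    accepted = True
                    state["_cur_ll"] = new_ll
                else:
                    state["sigma"][s] = old
            if adapt:
                state["step_sigma"] = float(np.clip(
                    state["step_sigma"] * np.exp(0.05 if accepted else -0.02),
                    1e-3, self.sigma_bound / 2))

    def _update_sex(self, state, z, rng):
        if self.n_aug:
            rows = np.arange(self.n_detected, self.n_individuals)
            male = state["is_male"]
            state_m = dict(state, is_male=np.ones_like(male))
            state_f = dict(state, is_male=np.zeros_like(male))
            if self.prior_only:
                ll_m = ll_f = np.zeros(len(rows))
            else:
                ll_m = (self.loglik0(state_m, rows=rows) * z[rows]).sum(axis=1)
                ll_f = (self.loglik0(state_f, rows=rows) * z[rows]).sum(axis=1)
            pm = state["p_male"]
            post = expit(np.log(pm) - np.log1p(-pm) + ll_m - ll_f)
            male[rows] = rng.random(len(rows)) < post
        n_male = int(state["is_male"].sum())
        state["p_male"] = float(rng.beta(1 + n_male,
                                         1 + self.n_individuals - n_male))

    # -- recording and fit ---------------------------------------------------
    def record(self, state, z) -> dict:
        out = {}
        for c, (m, k) in enumerate(self.classes):
            name = f"g0_logit[{m}]" if k is None else f"g0_logit[{m},{k}]"
            out[name] = float(state["g0_logit"][c])
        if self.sigma_by_sex:
            out["sigma_f"] = float(state["sigma"][0])
            out["sigma_m"] = float(state["sigma"][1])
            out["p_male"] = float(state["p_male"])
        else:
            out["sigma"] = float(state["sigma"][0])
        return out

    def posterior_predictive(self, state, z, rng) -> tuple[float, float]:
        """Freeman-Tukey discrepancy over individual x trap x occasion x year
        cells (binomial pooling over occasions within a detection class),
        restricted to alive individual-years."""
        kern = self._kernel(state)
        g0 = expit(state["g0_logit"])
        p = np.clip(kern[:, :, None] * g0[None, None, :], _PCLIP, 1 - _PCLIP)
        alive = z.astype(bool)  # (n, T)
        # expand alive over (J, C)
        w = alive[:, None, None, :] & (self.trials[None] > 0)
        pa = np.broadcast_to(p[..., None], self.counts.shape)[w]
        ya = self.counts[w]
        na = np.broadcast_to(self.trials[None], self.counts.shape)[w]
        # per-cell Freeman-Tukey on the underlying binary occasions:
        # y occasions with outcome 1 contribute (1-sqrt(p))^2, the rest p
        t_obs = float((ya * (1 - np.sqrt(pa)) ** 2 + (na - ya) * pa).sum())
        yrep = rng.binomial(na.astype(int), pa)
        t_rep = float((yrep * (1 - np.sqrt(pa)) ** 2 + (na - yrep) * pa).sum())
        return t_obs, t_rep
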