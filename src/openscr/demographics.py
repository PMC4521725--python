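"""Derived demographic quantities from posterior draws.

Per retained iteration the sampler records annual abundance N_t (individuals
with z_it = 1), first-time entries B_t and apparent survival phi_t.  From
these the package derives per-capita recruitment R_t = B_t / N_{t-1},
population growth lambda_t = phi_t + R_t (an exact per-draw identity), and
study-average rates as the geometric mean of the year-transition values.
Density is abundance divided by the state-space area, reported per
1000 km^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws, gelman_rubin, hpd_interval

__all__ = ["DemographicDraws", "derive_demographics", "summarize_posterior"]


@dataclass
class DemographicDraws:
    """Per-iteration demographic quantities; arrays are chain-stacked (C*N,)."""

    samples: dict = field(default_factory=dict)
    n_years: int = 0
    area_km2: float | None = None

    def __getitem__(self, key):
        return self.samples[key]

    def __contains__(self, key):
        return key in self.samples

    @property
    def names(self):
        return list(self.samples)


def _geomean(cols: list[np.ndarray]) -> np.ndarray:
    arr = np.column_stack(cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.exp(np.log(arr).mean(axis=1))


def derive_demographics(draws: PosteriorDraws,
                        area_km2: float | None = None) -> DemographicDraws:
    """Derive R_t, lambda_t, averaged rates and density from sampler output.

    ``R_t`` is recorded as missing (NaN) for draws with ``N_{t-1} = 0``
    rather than dividing by zero.  Averages are geometric means over the
    T - 1 year transitions; the averaged abundance ``N`` is the per-draw
    arithmetic mean of the annual abundances.  Density needs ``area_km2``.
    """
    years = sorted(int(k[2:-1]) for k in draws.names if k.startswith("N["))
    T = len(years)
    if T < 2:
        raise ValueError("need at least two years of draws")
    out = {}
    N = {t: draws.stacked(f"N[{t}]") for t in years}
    for t in years:
        out[f"N[{t}]"] = N[t]
    lam_cols, r_cols, phi_cols = [], [], []
    for t in years[1:]:
        phi_t = draws.stacked(f"phi[{t}]")
        B_t = draws.stacked(f"entries[{t}]")
        prev = N[t - 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            R_t = np.where(prev > 0, B_t / np.where(prev > 0, prev, 1), np.nan)
        lam_t = phi_t + R_t
        out[f"phi[{t}]"] = phi_t
        out[f"R[{t}]"] = R_t
        out[f"lambda[{t}]"] = lam_t
        phi_cols.append(phi_t)
        r_cols.append(R_t)
        lam_cols.append(lam_t)
    out["phi"] = _geomean(phi_cols)
    out["R"] = _geomean(r_cols)
    out["lambda"] = _geomean(lam_cols)
    out["N"] = np.column_stack([N[t] for t in years]).mean(axis=1)
    if area_km2 is not None:
        for t in years:
            out[f"D[{t}]"] = N[t] / area_km2 * 1000.0
        out["D"] = out["N"] / area_km2 * 1000.0
    return DemographicDraws(samples=out, n_years=T, area_km2=area_km2)


def summarize_posterior(samples, mass: float = 0.95,
                        chains: dict | None = None) -> pd.DataFrame:
    """Posterior summary table: median, HPD interval and CV per parameter.

    ``samples`` maps parameter name to a 1-D array of draws (a
    :class:`DemographicDraws` works directly).  CV is the posterior standard
    deviation over the mean, in percent.  When per-chain arrays are supplied
    via ``chains`` a Gelman-Rubin column is added.
    """
    if isinstance(samples, DemographicDraws):
        samples = samples.samples
    rows = []
    for name, x in samples.items():
        x = np.asarray(x, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size == 0:
            continue
        lo, hi = hpd_interval(x, mass)
        mean = x.mean()
        cv = float(100.0 * x.std(ddof=1) / mean) if x.size > 1 and mean != 0 else 0.0
        row = {
            "parameter": name,
            "median": float(np.median(x)),
            "hpd_lower": lo,
            "hpd_upper": hi,
            "cv_pct": cv,
        }
        if chains is not None and name in chains:
            row["rhat"] = gelman_rubin(np.asarray(chains[name]))
        rows.append(row)
    return pd.DataFrame(rows)
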