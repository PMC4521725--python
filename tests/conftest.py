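"""Shared fixtures: tiny on-disk datasets and a minimal sampler model."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def write_tiny_files(tmp_path, detections, traps, effort):
    """Write detection/trap/effort CSVs from row lists; returns the paths."""
    det_path = tmp_path / "detections.csv"
    trap_path = tmp_path / "traps.csv"
    eff_path = tmp_path / "effort.csv"
    det_path.write_text(
        "individual_id,sex,year,occasion,trap_id\n"
        + "\n".join(",".join(map(str, r)) for r in detections) + "\n")
    trap_path.write_text(
        "trap_id,trap_type,x_km,y_km\n"
        + "\n".join(",".join(map(str, r)) for r in traps) + "\n")
    eff_path.write_text(
        "trap_id,year,occasion,days\n"
        + "\n".join(",".join(map(str, r)) for r in effort) + "\n")
    return det_path, trap_path, eff_path


@pytest.fixture
def two_trap_files(tmp_path):
    """Two hair traps, one bear detected at both in the same occasion."""
    traps = [("A", "hair_trap", 0.0, 0.0), ("B", "hair_trap", 2.0, 2.0)]
    effort = [(t, y, k, 14) for t in ("A", "B") for y in (1, 2) for k in (1, 2)]
    detections = [("bear1", "F", 1, 2, "A"), ("bear1", "F", 1, 2, "B")]
    return write_tiny_files(tmp_path, detections, traps, effort)


class FixedDetectionModel:
    """Minimal sampler-protocol model: fixed all-zero-history likelihood.

    One augmented individual, no detections, no free detection parameters;
    the year-history likelihood given alive is (1 - p)^k_occasions.  Used to
    check the latent-state machinery against exact enumeration.
    """

    def __init__(self, p=0.3, k_occ=3, T=2, n=1):
        self.T = T
        self.n_individuals = n
        self.detected = np.zeros((n, T), dtype=bool)
        self._ll = float(k_occ * np.log1p(-p))

    def init_state(self, rng):
        return {}

    def loglik0(self, state, **kw):
        return np.full((self.n_individuals, self.T), self._ll)

    def update_params(self, state, z, rng, adapt, loglik0_current=None):
        pass

    def record(self, state, z):
        return {}

    def posterior_predictive(self, state, z, rng):
        return 0.0, 0.0
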