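"""Detection-history data structures, file I/O and descriptive summaries.

Capture-recapture data arrive as a table of detection events (one row per
individual x trap x occasion x year), a trap registry with planar coordinates
and trap types, and a per-occasion effort table (active trap-days).  Two
binary views of the detection history are maintained:

* ``y_spatial[i, j, k, t]`` -- detection of individual *i* at trap *j* on
  occasion *k* in year *t*; consumed by the spatial model.
* ``y_nonspatial[i, k, m, t]`` -- detection of individual *i* at *any* trap of
  type *m* on occasion *k* in year *t*; consumed by the non-spatial models.

All coordinates are planar kilometres (x east, y north); geographic data must
be projected before entering the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon

__all__ = [
    "TRAP_TYPES",
    "DEFAULT_REFERENCE_DAYS",
    "TrapRegistry",
    "DetectionDataset",
    "ObservedCentre",
    "read_dataset",
    "write_dataset",
    "observed_centre",
    "distance_to_edge",
    "observed_centres",
    "tabulate_detections",
]

#: Recognised detector types.  ``generic`` is used by the square-grid
#: simulation design where all traps are identical.
TRAP_TYPES = ("bear_rub", "hair_trap", "highway_crossing", "generic")

#: Median active trap-days per detector type used as the reference point of
#: the proportional-hazard effort scaling (days).
DEFAULT_REFERENCE_DAYS = {
    "bear_rub": 162.0,
    "hair_trap": 42.0,
    "highway_crossing": 20.0,
    "generic": 1.0,
}


@dataclass
class TrapRegistry:
    """Registry of detectors: ids, types, coordinates and effort.

    Parameters
    ----------
    trap_ids
        Unique trap identifiers, one per trap (length ``J``).
    trap_type
        Detector type per trap; each entry must be one of :data:`TRAP_TYPES`.
    coords
        ``(J, 2)`` planar coordinates in km.
    active_days
        ``(J, K, T)`` active trap-days per trap, occasion and year.  A zero
        encodes "trap not deployed" for that occasion; occasion structure may
        therefore be ragged across trap types.
    reference_days
        Reference active days per trap type for effort scaling.
    """

    trap_ids: list
    trap_type: np.ndarray
    coords: np.ndarray
    active_days: np.ndarray
    reference_days: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_DAYS)
    )

    def __post_init__(self) -> None:
        self.trap_type = np.asarray(self.trap_type, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.active_days = np.asarray(self.active_days, dtype=float)
        if len(self.trap_ids) != len(set(self.trap_ids)):
            raise ValueError("duplicate trap ids")
        if self.coords.shape != (len(self.trap_ids), 2):
            raise ValueError("coords must be (n_traps, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trap coordinates must be finite")
        if self.active_days.shape[0] != len(self.trap_ids):
            raise ValueError("active_days first axis must match trap count")
        if np.any(self.active_days < 0):
            raise ValueError("active_days must be nonnegative")
        for m in np.unique(self.trap_type):
            if m not in TRAP_TYPES:
                raise ValueError(f"unknown trap type {m!r}")
            if self.reference_days.get(m, 0) <= 0:
                raise ValueError(f"reference_days must be positive for {m!r}")

    @property
    def n_traps(self) -> int:
        return len(self.trap_ids)

    @property
    def n_occasions(self) -> int:
        return self.active_days.shape[1]

    @property
    def n_years(self) -> int:
        return self.active_days.shape[2]

    @property
    def types_present(self) -> tuple:
        """Trap types present, in :data:`TRAP_TYPES` order."""
        present = set(self.trap_type.tolist())
        return tuple(m for m in TRAP_TYPES if m in present)

    def type_effort(self, types: Sequence[str] | None = None) -> np.ndarray:
        """Total active trap-days per (occasion, type, year).

        Returns ``NDays[k, m, t]``, the aggregate effort entering the
        non-spatial proportional-hazard scaling.
        """
        types = tuple(types) if types is not None else self.types_present
        out = np.zeros((self.n_occasions, len(types), self.n_years))
        for m, name in enumerate(types):
            sel = self.trap_type == name
            out[:, m, :] = self.active_days[sel].sum(axis=0)
        return out

    def index(self, trap_id) -> int:
        return self.trap_ids.index(trap_id)


@dataclass
class DetectionDataset:
    """Binary detection histories of the detected individuals.

    ``y_spatial`` has shape ``(n, J, K, T)`` and ``y_nonspatial`` shape
    ``(n, K, M, T)`` where ``M`` indexes ``trap_types``.  The non-spatial view
    is always the OR-collapse of the spatial view over traps of each type.
    """

    individual_ids: list
    sex: np.ndarray  # elements 'F' or 'M'
    years: list
    y_spatial: np.ndarray
    y_nonspatial: np.ndarray
    trap_types: tuple
    study_boundary: Polygon | None = None

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, dtype=object)
        self.y_spatial = np.asarray(self.y_spatial, dtype=np.uint8)
        self.y_nonspatial = np.asarray(self.y_nonspatial, dtype=np.uint8)
        n = len(self.individual_ids)
        if self.sex.shape != (n,):
            raise ValueError("sex must have one entry per individual")
        if not set(self.sex.tolist()) <= {"F", "M"}:
            raise ValueError("sex labels must be 'F' or 'M'")
        if self.y_spatial.shape[0] != n or self.y_nonspatial.shape[0] != n:
            raise ValueError("detection arrays must match individual count")
        if list(self.years) != sorted(self.years):
            raise ValueError("years must be ascending")
        if n and self.y_spatial.reshape(n, -1).max(axis=1).min() == 0:
            raise ValueError("every individual must have >= 1 detection")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def detected_in_year(self) -> np.ndarray:
        """Boolean ``(n, T)``: any detection of individual i in year t."""
        n = self.n_individuals
        return self.y_spatial.reshape(n, -1, self.n_years).any(axis=1)

    @staticmethod
    def collapse_types(y_spatial: np.ndarray, trap_type: np.ndarray,
                       types: Sequence[str]) -> np.ndarray:
        """OR-collapse a spatial history over traps within each type."""
        n, _, K, T = y_spatial.shape
        out = np.zeros((n, K, len(types), T), dtype=np.uint8)
        for m, name in enumerate(types):
            sel = np.asarray(trap_type) == name
            if sel.any():
                out[:, :, m, :] = y_spatial[:, sel].any(axis=1)
        return out


@dataclass(frozen=True)
class ObservedCentre:
    """Observed home-range centre of a detected individual.

    ``dedge`` is the distance (km) from the centre to the study-area edge,
    used as a detection covariate in the non-spatial model.
    """

    individual_id: object
    x: float
    y: float
    n_traps_used: int
    dedge: float


def observed_centre(trap_points: Sequence[Sequence[float]]) -> tuple:
    """Home-range centre from the traps where an individual was detected.

    One trap: the trap location.  Two traps: the midpoint.  Three or more
    non-collinear traps: the area centroid of the 100% minimum convex polygon
    around the traps.  Collinear traps degenerate to the mean of the unique
    locations.
    """
    pts = np.asarray(trap_points, dtype=float)
    if pts.size == 0:
        raise ValueError("observed_centre requires at least one point")
    pts = pts.reshape(-1, 2)
    uniq = np.unique(pts, axis=0)
    if len(uniq) == 1:
        return (float(uniq[0, 0]), float(uniq[0, 1]))
    if len(uniq) == 2:
        mid = uniq.mean(axis=0)
        return (float(mid[0]), float(mid[1]))
    hull = MultiPoint([tuple(p) for p in uniq]).convex_hull
    if isinstance(hull, Polygon):
        c = hull.centroid
        return (float(c.x), float(c.y))
    # collinear degenerate case
    mean = uniq.mean(axis=0)
    return (float(mean[0]), float(mean[1]))


def distance_to_edge(point: Sequence[float], boundary: Polygon) -> float:
    """Euclidean distance (km) from a point inside the study area to its edge.

    Raises ``ValueError`` if the point lies outside the boundary, which
    signals a centre/boundary mismatch.
    """
    p = Point(point[0], point[1])
    if not boundary.covers(p):
        raise ValueError(f"point {tuple(point)} lies outside the study boundary")
    return float(p.distance(boundary.exterior))


def observed_centres(dataset: DetectionDataset,
                     registry: TrapRegistry) -> list[ObservedCentre]:
    """Observed centre and DEDGE for every detected individual."""
    if dataset.study_boundary is None:
        raise ValueError("dataset has no study boundary")
    out = []
    for i, ind in enumerate(dataset.individual_ids):
        used = dataset.y_spatial[i].reshape(registry.n_traps, -1).any(axis=1)
        pts = registry.coords[used]
        cx, cy = observed_centre(pts)
        d = distance_to_edge((cx, cy), dataset.study_boundary)
        out.append(ObservedCentre(ind, cx, cy, int(used.sum()), d))
    return out


def _resolve_boundary(boundary_spec, coords: np.ndarray) -> Polygon:
    if isinstance(boundary_spec, Polygon):
        return boundary_spec
    if isinstance(boundary_spec, str):
        if not boundary_spec.startswith("buffer:"):
            raise ValueError(f"unrecognised boundary spec {boundary_spec!r}")
        km = float(boundary_spec.split(":", 1)[1])
        return MultiPoint([tuple(p) for p in coords]).convex_hull.buffer(km)
    return Polygon([tuple(v) for v in boundary_spec])


def read_dataset(detections_path, traps_path, effort_path,
                 boundary_spec) -> tuple[DetectionDataset, TrapRegistry]:
    """Read the delimited detection/trap/effort files into package objects.

    ``detections`` columns: individual_id, sex, year, occasion, trap_id (one
    row per detection event; duplicates collapse to a binary history).
    ``traps`` columns: trap_id, trap_type, x_km, y_km.  ``effort`` columns:
    trap_id, year, occasion, days (zero days = trap not deployed).
    ``boundary_spec`` is a vertex list, a shapely polygon, or ``"buffer:<km>"``
    to buffer the convex hull of the traps.

    Every detection must reference a known trap at a positive-effort
    trap-occasion; violations are rejected with the offending row number.
    """
    traps = pd.read_csv(traps_path, sep=None, engine="python")
    effort = pd.read_csv(effort_path, sep=None, engine="python")
    det = pd.read_csv(detections_path, sep=None, engine="python")

    trap_ids = traps["trap_id"].tolist()
    trap_type = traps["trap_type"].to_numpy(dtype=object)
    coords = traps[["x_km", "y_km"]].to_numpy(dtype=float)

    years = sorted(set(effort["year"]).union(det["year"]))
    K = int(max(effort["occasion"].max(), det["occasion"].max() if len(det) else 1))
    year_ix = {y: t for t, y in enumerate(years)}
    trap_ix = {tid: j for j, tid in enumerate(trap_ids)}

    active = np.zeros((len(trap_ids), K, len(years)))
    for row in effort.itertuples():
        if row.trap_id not in trap_ix:
            raise ValueError(f"effort row {row.Index}: unknown trap_id {row.trap_id!r}")
        active[trap_ix[row.trap_id], int(row.occasion) - 1, year_ix[row.year]] = row.days
    registry = TrapRegistry(trap_ids, trap_type, coords, active)

    det = det.sort_values("individual_id", kind="stable")
    ind_ids = list(dict.fromkeys(det["individual_id"]))
    ind_ix = {iid: i for i, iid in enumerate(ind_ids)}
    sex = np.empty(len(ind_ids), dtype=object)
    y = np.zeros((len(ind_ids), len(trap_ids), K, len(years)), dtype=np.uint8)
    for row in det.itertuples():
        if row.trap_id not in trap_ix:
            raise ValueError(
                f"detections row {row.Index}: unknown trap_id {row.trap_id!r}")
        j = trap_ix[row.trap_id]
        k = int(row.occasion) - 1
        t = year_ix[row.year]
        if active[j, k, t] <= 0:
            raise ValueError(
                f"detections row {row.Index}: detection at trap {row.trap_id!r}, "
                f"occasion {row.occasion}, year {row.year} has zero effort")
        y[ind_ix[row.individual_id], j, k, t] = 1
        sex[ind_ix[row.individual_id]] = row.sex

    types = registry.types_present
    dataset = DetectionDataset(
        individual_ids=ind_ids,
        sex=sex,
        years=years,
        y_spatial=y,
        y_nonspatial=DetectionDataset.collapse_types(y, trap_type, types),
        trap_types=types,
        study_boundary=_resolve_boundary(boundary_spec, coords),
    )
    return dataset, registry


def write_dataset(dataset: DetectionDataset, registry: TrapRegistry,
                  out_dir) -> dict:
    """Write the standard detections/traps/effort files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": out / "detections.csv",
        "traps": out / "traps.csv",
        "effort": out / "effort.csv",
    }
    pd.DataFrame({
        "trap_id": registry.trap_ids,
        "trap_type": registry.trap_type,
        "x_km": registry.coords[:, 0],
        "y_km": registry.coords[:, 1],
    }).to_csv(paths["traps"], index=False)

    j, k, t = np.nonzero(registry.active_days)
    pd.DataFrame({
        "trap_id": [registry.trap_ids[x] for x in j],
        "year": [dataset.years[x] for x in t],
        "occasion": k + 1,
        "days": registry.active_days[j, k, t],
    }).to_csv(paths["effort"], index=False)

    i, j, k, t = np.nonzero(dataset.y_spatial)
    pd.DataFrame({
        "individual_id": [dataset.individual_ids[x] for x in i],
        "sex": [dataset.sex[x] for x in i],
        "year": [dataset.years[x] for x in t],
        "occasion": k + 1,
        "trap_id": [registry.trap_ids[x] for x in j],
    }).to_csv(paths["detections"], index=False)
    return paths


def tabulate_detections(dataset: DetectionDataset,
                        registry: TrapRegistry | None = None) -> pd.DataFrame:
    """Descriptive summary: individuals detected, detection rates, recaptures.

    One row per year, per trap type, and a total row.  ``mean_detections`` is
    detections (trap-occasion events) per detected animal per year and
    ``pct_gt1`` the percentage of animal-years with more than one detection;
    year rows combine into the total (and trap-type rows) with animal-year
    weighting.  When ``registry`` is omitted the per-type rows count at most
    one detection per occasion (the non-spatial view loses trap multiplicity).
    """
    if dataset.n_individuals == 0:
        raise ValueError("empty dataset")
    n, J, K, T = dataset.y_spatial.shape
    counts = dataset.y_spatial.reshape(n, -1, T).sum(axis=1)  # detections (i, t)
    male = dataset.sex == "M"
    rows = []

    def _row(label, cnt):  # cnt: (n, T) detection counts restricted to a slice
        det = cnt > 0
        animal_years = det.sum()
        any_det = det.any(axis=1)
        rows.append({
            "group": label,
            "n_individuals": int(any_det.sum()),
            "n_female": int((any_det & ~male).sum()),
            "n_male": int((any_det & male).sum()),
            "mean_detections": float(cnt.sum() / animal_years) if animal_years else 0.0,
            "pct_gt1": float(100.0 * (cnt > 1).sum() / animal_years) if animal_years else 0.0,
        })

    for t, year in enumerate(dataset.years):
        _row(year, counts[:, [t]])
    for name in dataset.trap_types:
        _row(name, _type_counts(dataset, registry, name))
    _row("Total", counts)
    return pd.DataFrame(rows)


def _type_counts(dataset: DetectionDataset, registry: TrapRegistry | None,
                 type_name: str) -> np.ndarray:
    if registry is not None:
        sel = registry.trap_type == type_name
        n, _, _, T = dataset.y_spatial.shape
        return dataset.y_spatial[:, sel].reshape(n, -1, T).sum(axis=1)
    m = dataset.trap_types.index(type_name)
    return dataset.y_nonspatial[:, :, m, :].sum(axis=1)
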