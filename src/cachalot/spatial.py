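"""Geodesy, the 1 km aggregation rule, and habitat attributes from rasters.

An "aggregation" is a group of sperm whales observed within 1 km of each
other on one survey day that could be distinguished acoustically.  "Within
1 km of each other" is implemented as single-linkage connected components
(chaining allowed) because the field protocol merged nearby GPS points taken
for sub-groups into a single aggregation; complete linkage is available as
an option.

Habitat attributes per GPS point: depth (m, positive down, bilinear from a
regular grid), distance to the densified coastline (m, accurate to better
than 100 m), and seabed slope over a ~500 m window, classed light (< 10 %),
medium (10–20 %) or steep (>= 20 %).  On a shelf edge where the two
half-window slopes point in opposite directions no single slope exists and
the class is "undefined".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "EARTH_RADIUS_M",
    "GeoPoint",
    "BathymetryGrid",
    "HabitatPoint",
    "Aggregation",
    "haversine",
    "cluster_aggregations",
    "depth_at",
    "slope_at",
    "distance_to_coast",
    "classify_slope",
]

#: mean Earth radius of the spherical model, metres.
EARTH_RADIUS_M = 6_371_000.0

SLOPE_CLASSES = ("light", "medium", "steep", "undefined")


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"invalid coordinates ({self.lat}, {self.lon})")


@dataclass
class BathymetryGrid:
    """A regular depth grid, metres positive below the surface.

    Row 0 is the northernmost row (image convention).  ``lat0``/``lon0`` are
    the coordinates of the centre of cell (0, 0); ``dlat``/``dlon`` the cell
    sizes in degrees (``dlat`` > 0, rows go south).  Land cells are NaN.
    """

    depths: np.ndarray
    lat0: float
    lon0: float
    dlat: float
    dlon: float

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 2 or min(self.depths.shape) < 2:
            raise ValueError("depth grid must be 2-D with at least 2 rows and columns")
        if self.dlat <= 0 or self.dlon <= 0:
            raise ValueError("cell sizes must be positive")
        with np.errstate(invalid="ignore"):
            if np.any(self.depths[np.isfinite(self.depths)] < 0):
                raise ValueError("sea depths must be non-negative (land is NaN)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depths.shape

    def fractional_index(self, p: GeoPoint) -> tuple[float, float]:
        """(row, col) as floats; row grows southward from ``lat0``."""
        return (self.lat0 - p.lat) / self.dlat, (p.lon - self.lon0) / self.dlon

    def contains(self, p: GeoPoint) -> bool:
        r, c = self.fractional_index(p)
        nr, nc = self.shape
        return 0.0 <= r <= nr - 1 and 0.0 <= c <= nc - 1


@dataclass(frozen=True)
class HabitatPoint:
    """Habitat attributes extracted at one GPS point."""

    depth_m: float
    dist_coast_m: float
    slope_pct: float | None
    slope_class: str

    def __post_init__(self) -> None:
        if self.slope_class not in SLOPE_CLASSES:
            raise ValueError(f"unknown slope class {self.slope_class!r}")


@dataclass
class Aggregation:
    """Co-located individuals treated as one social/behavioural unit."""

    members: list[GeoPoint]
    individual_ids: list[str] = field(default_factory=list)
    date: str | None = None
    size: int | None = None
    mean_length_m: float | None = None
    has_immature: bool | None = None
    behaviours: object | None = None
    habitat: HabitatPoint | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("aggregation must have at least one member")
        if self.size is None:
            self.size = len(self.members)

    @property
    def centroid(self) -> GeoPoint:
        return GeoPoint(
            float(np.mean([p.lat for p in self.members])),
            float(np.mean([p.lon for p in self.members])),
        )


# ---------------------------------------------------------------------------
# geodesy
# ---------------------------------------------------------------------------

def haversine(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in metres on a sphere of radius 6,371 km."""
    la1, lo1, la2, lo2 = map(np.radians, (a.lat, a.lon, b.lat, b.lon))
    s = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(s)))


def _pairwise_distances(points: Sequence[GeoPoint]) -> np.ndarray:
    lat = np.radians([p.lat for p in points])
    lon = np.radians([p.lon for p in points])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    s = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


def cluster_aggregations(
    sightings: Sequence[GeoPoint],
    radius_m: float = 1000.0,
    ids: Sequence[str] | None = None,
    linkage: str = "single",
    date: str | None = None,
) -> list[Aggregation]:
    """Group same-day sightings into aggregations by the 1 km rule.

    ``single`` linkage (default) takes connected components of the graph
    linking points within ``radius_m``; ``complete`` requires every pair in a
    group to be within ``radius_m`` (greedy agglomeration).  Aggregations are
    returned ordered by first member.
    """
    if linkage not in ("single", "complete"):
        raise ValueError("linkage must be 'single' or 'complete'")
    if not sightings:
        return []
    if ids is None:
        ids = [str(i) for i in range(len(sightings))]
    d = _pairwise_distances(sightings)

    if linkage == "single":
        adjacency = csr_matrix(d <= radius_m)
        _, labels = connected_components(adjacency, directed=False)
    else:
        labels = np.full(len(sightings), -1, dtype=int)
        n_groups = 0
        for i in range(len(sightings)):
            if labels[i] >= 0:
                continue
            labels[i] = n_groups
            for j in range(i + 1, len(sightings)):
                if labels[j] < 0 and np.all(d[j, labels == n_groups] <= radius_m):
                    labels[j] = n_groups
            n_groups += 1

    aggregations = []
    for lbl in sorted(set(labels), key=lambda l: int(np.argmax(labels == l))):
        idx = np.flatnonzero(labels == lbl)
        aggregations.append(
            Aggregation(
                members=[sightings[i] for i in idx],
                individual_ids=[ids[i] for i in idx],
                date=date,
            )
        )
    return aggregations


# ---------------------------------------------------------------------------
# raster habitat attributes
# ---------------------------------------------------------------------------

def depth_at(grid: BathymetryGrid, p: GeoPoint) -> float:
    """Bilinear depth at ``p``; NaN neighbours degrade to the nearest cell."""
    if not grid.contains(p):
        raise ValueError(f"point ({p.lat}, {p.lon}) outside the bathymetry grid extent")
    r, c = grid.fractional_index(p)
    nr, nc = grid.shape
    r0, c0 = min(int(np.floor(r)), nr - 2), min(int(np.floor(c)), nc - 2)
    fr, fc = r - r0, c - c0
    corners = grid.depths[r0:r0 + 2, c0:c0 + 2]
    if np.all(np.isfinite(corners)):
        w = np.array([[(1 - fr) * (1 - fc), (1 - fr) * fc], [fr * (1 - fc), fr * fc]])
        return float(np.sum(w * corners))
    nearest = grid.depths[int(round(r)), int(round(c))]
    if not np.isfinite(nearest):
        raise ValueError(f"point ({p.lat}, {p.lon}) falls on land")
    return float(nearest)


def classify_slope(slope_pct: float | None) -> str:
    """light < 10 %; medium in [10, 20); steep >= 20 %; None → undefined."""
    if slope_pct is None:
        return "undefined"
    if slope_pct < 10.0:
        return "light"
    if slope_pct < 20.0:
        return "medium"
    return "steep"


def _offset(p: GeoPoint, north_m: float, east_m: float) -> GeoPoint:
    dlat = np.degrees(north_m / EARTH_RADIUS_M)
    dlon = np.degrees(east_m / (EARTH_RADIUS_M * np.cos(np.radians(p.lat))))
    return GeoPoint(p.lat + dlat, p.lon + dlon)


def slope_at(
    grid: BathymetryGrid,
    p: GeoPoint,
    window_m: float = 500.0,
    shelf_threshold_pct: float = 5.0,
) -> tuple[float | None, str]:
    """Seabed slope (percent) over a ``window_m`` window, with its class.

    Central differences over ±window/2 in the north-south and east-west
    directions give the gradient; the slope is 100·|∇depth| along the
    maximum-gradient direction.  Shelf rule: if along either axis the two
    half-window slopes both exceed ``shelf_threshold_pct`` with opposite
    signs (a plateau between opposing inclines), no single slope exists and
    ``(None, "undefined")`` is returned.
    """
    h = window_m / 2.0
    samples = {}
    for name, (dn, de) in {
        "n": (h, 0.0), "s": (-h, 0.0), "e": (0.0, h), "w": (0.0, -h), "c": (0.0, 0.0),
    }.items():
        q = _offset(p, dn, de)
        if not grid.contains(q):
            raise ValueError(f"slope window around ({p.lat}, {p.lon}) exits the grid")
        samples[name] = depth_at(grid, q)

    for plus, minus in (("n", "s"), ("e", "w")):
        s_plus = 100.0 * (samples[plus] - samples["c"]) / h
        s_minus = 100.0 * (samples["c"] - samples[minus]) / h
        if (
            abs(s_plus) > shelf_threshold_pct
            and abs(s_minus) > shelf_threshold_pct
            and np.sign(s_plus) != np.sign(s_minus)
        ):
            return None, "undefined"

    gy = (samples["n"] - samples["s"]) / window_m
    gx = (samples["e"] - samples["w"]) / window_m
    slope_pct = 100.0 * float(np.hypot(gx, gy))
    return slope_pct, classify_slope(slope_pct)


def distance_to_coast(
    p: GeoPoint,
    coastline: Sequence[GeoPoint],
    densify_step_m: float = 50.0,
) -> float:
    """Minimum distance from ``p`` to a coastline polyline, metres.

    Each segment is densified to vertices at most ``densify_step_m`` apart
    before the minimum haversine distance is taken, so the result is accurate
    to better than 100 m regardless of the original vertex spacing.
    """
    if not coastline:
        raise ValueError("coastline must contain at least one vertex")
    lats, lons = [], []
    for a, b in zip(coastline, list(coastline)[1:]):
        n = max(1, int(np.ceil(haversine(a, b) / densify_step_m)))
        t = np.linspace(0.0, 1.0, n + 1)
        lats.append(a.lat + t * (b.lat - a.lat))
        lons.append(a.lon + t * (b.lon - a.lon))
    if lats:
        lat = np.concatenate(lats)
        lon = np.concatenate(lons)
    else:
        lat = np.array([coastline[0].lat])
        lon = np.array([coastline[0].lon])

    la1, lo1 = np.radians(p.lat), np.radians(p.lon)
    la2, lo2 = np.radians(lat), np.radians(lon)
    s = np.sin((la2 - la1) / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    return float(np.min(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(s))))
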