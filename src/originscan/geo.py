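"""Spherical geometry on a geographic lattice.

All coordinates are decimal degrees (WGS84-style spherical interpretation,
no projection). Distances are great-circle distances on a sphere of mean
Earth radius 6371.0088 km, which is accurate to well under 0.5% of the
ellipsoidal distance — immaterial at the 500-km kernel scale this package
works at.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

EARTH_RADIUS_KM = 6371.0088


class GeoPoint(NamedTuple):
    """A point on the sphere in decimal degrees."""

    latitude: float
    longitude: float

    def validate(self) -> "GeoPoint":
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        return self


def haversine_km(a, b) -> np.ndarray | float:
    """Great-circle distance in km between points ``a`` and ``b``.

    Accepts GeoPoints or (lat, lon) array-likes; broadcasts like numpy, so a
    single point against an (n, 2) array yields n distances.
    """
    lat1, lon1 = np.radians(np.asarray(a, dtype=float)).reshape(-1, 2).T
    lat2, lon2 = np.radians(np.asarray(b, dtype=float)).reshape(-1, 2).T
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    if np.ndim(a) <= 1 and np.ndim(b) <= 1:
        return float(d[0])
    return d


def pairwise_haversine_km(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Full (n, m) distance matrix between two (·, 2) lat/lon arrays."""
    pa = np.radians(np.asarray(points_a, dtype=float))
    pb = np.radians(np.asarray(points_b, dtype=float))
    lat1 = pa[:, 0][:, None]
    lon1 = pa[:, 1][:, None]
    lat2 = pb[:, 0][None, :]
    lon2 = pb[:, 1][None, :]
    h = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


@dataclass(frozen=True)
class GeoGrid:
    """A node-registered lat/lon lattice.

    Nodes sit at ``min + k * resolution`` for integer k ≥ 0, inclusive of the
    lower bound and never exceeding the upper bound. Degenerate bounds
    (min == max) give a single node on that axis.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float

    lats: np.ndarray = field(init=False, repr=False, compare=False)
    lons: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("grid resolution must be positive")
        if self.lat_min > self.lat_max or self.lon_min > self.lon_max:
            raise ValueError("grid bounds must satisfy min <= max on both axes")
        object.__setattr__(self, "lats", _axis(self.lat_min, self.lat_max, self.resolution))
        object.__setattr__(self, "lons", _axis(self.lon_min, self.lon_max, self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lats), len(self.lons))

    @property
    def n_nodes(self) -> int:
        return len(self.lats) * len(self.lons)

    def node_coords(self) -> np.ndarray:
        """All nodes as an (n_nodes, 2) lat/lon array, lat-major order."""
        lat, lon = np.meshgrid(self.lats, self.lons, indexing="ij")
        return np.column_stack([lat.ravel(), lon.ravel()])


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    # inclusive of lo; never exceeds hi (tolerate float fuzz of half a step ppm)
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    ax = lo + step * np.arange(n)
    return ax[ax <= hi + step * 1e-9]


def build_grid(
    lat_min: float, lat_max: float, lon_min: float, lon_max: float, resolution: float
) -> GeoGrid:
    """Construct the node lattice covering the stated bounds."""
    return GeoGrid(lat_min, lat_max, lon_min, lon_max, resolution)
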