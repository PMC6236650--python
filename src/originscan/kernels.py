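"""Geographic sample kernels.

A *kernel* is a grid node together with the genetic samples lying within a
fixed great-circle radius of it. A node is *accepted* when at least
``min_samples`` samples fall inside its disc (boundary-inclusive); local
genetic diversity is then measured on the accepted kernels. The defaults —
500 km radius, 5 samples — are the standard rule for this analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import GeoGrid, GeoPoint, pairwise_haversine_km
from .io import SampleTable, geolocated_subset

DEFAULT_RADIUS_KM = 500.0
DEFAULT_MIN_SAMPLES = 5


@dataclass(frozen=True)
class Kernel:
    """An accepted grid node with its member samples.

    ``member_idx`` indexes rows of the geolocated table the kernel set was
    built from. ``multiplicity`` is a case weight for downstream correlation
    (1 for kernels produced by :func:`accept_kernels`, which keeps every
    node; callers constructing collapsed kernel lists by hand may weight
    them).
    """

    center: GeoPoint
    member_idx: tuple[int, ...]
    member_ids: tuple[str, ...]
    multiplicity: int = 1

    @property
    def n_members(self) -> int:
        return len(self.member_idx)


@dataclass
class KernelSet:
    """All accepted kernels of a grid, plus the member-set grouping.

    Neighbouring nodes often hold exactly the same samples; ``group_index``
    maps each kernel to its distinct-member-set group so that statistics
    needing per-member-set quantities (kernel diversity inside a permutation
    loop, say) can compute one value per group and fan it back out. Every
    node keeps its own center and distance, so grouping never changes a
    downstream result — only how fast it is obtained.
    """

    kernels: list[Kernel]
    radius_km: float
    min_samples: int
    grid: GeoGrid
    group_index: np.ndarray = field(default=None, repr=False)
    table: SampleTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.group_index is None:
            seen: dict[tuple[int, ...], int] = {}
            gi = [seen.setdefault(k.member_idx, len(seen)) for k in self.kernels]
            self.group_index = np.asarray(gi, dtype=int)

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def n_groups(self) -> int:
        return int(self.group_index.max()) + 1 if len(self.kernels) else 0

    def centers(self) -> np.ndarray:
        return np.array([[k.center.latitude, k.center.longitude] for k in self.kernels])

    def multiplicities(self) -> np.ndarray:
        return np.array([k.multiplicity for k in self.kernels], dtype=float)

    def membership_matrix(self, n_samples: int) -> np.ndarray:
        """(n_kernels, n_samples) 0/1 matrix of kernel membership."""
        m = np.zeros((len(self.kernels), n_samples))
        for i, k in enumerate(self.kernels):
            m[i, list(k.member_idx)] = 1.0
        return m

    def group_membership_matrix(self, n_samples: int) -> np.ndarray:
        """(n_groups, n_samples) matrix with one row per distinct member set."""
        m = np.zeros((self.n_groups, n_samples))
        for i, k in enumerate(self.kernels):
            m[self.group_index[i], list(k.member_idx)] = 1.0
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "latitude": [k.center.latitude for k in self.kernels],
                "longitude": [k.center.longitude for k in self.kernels],
                "n_members": [k.n_members for k in self.kernels],
                "member_set_group": self.group_index,
                "member_ids": [";".join(k.member_ids) for k in self.kernels],
            }
        )


def accept_kernels(
    table: SampleTable,
    grid: GeoGrid,
    radius_km: float = DEFAULT_RADIUS_KM,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> KernelSet:
    """Accept every grid node whose disc holds at least ``min_samples`` samples.

    Membership is boundary-inclusive (distance ≤ radius). Samples without
    coordinates are dropped first; co-located samples all count.
    """
    geo = geolocated_subset(table)
    if geo.n_samples == 0:
        warnings.warn("no geolocated samples: empty kernel set", stacklevel=2)
        return KernelSet([], radius_km, min_samples, grid, None, geo)
    nodes = grid.node_coords()
    dists = pairwise_haversine_km(nodes, geo.coords())
    inside = dists <= radius_km
    counts = inside.sum(axis=1)
    ids = np.array(geo.sample_ids)
    kernels: list[Kernel] = []
    for node_i in np.where(counts >= min_samples)[0]:
        members = tuple(int(j) for j in np.where(inside[node_i])[0])
        lat, lon = nodes[node_i]
        kernels.append(Kernel(GeoPoint(float(lat), float(lon)), members, tuple(ids[list(members)])))
    return KernelSet(kernels, radius_km, min_samples, grid, None, geo)
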