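"""Serial-founder range-expansion simulator.

Generates georeferenced microsatellite tables with the statistical structure
the origin scan assumes: a radial expansion across a deme lattice in which
each newly colonised deme is founded by a small sample of its parent deme,
so expected heterozygosity declines monotonically with colonisation distance
from the origin.

Model: demes sit on a regular lat/lon lattice and are colonised breadth-first
(rook adjacency) from the origin deme, wave by wave. Each deme holds
``deme_capacity`` individuals; landraces are strongly selfing, so an
individual is a single allele copy per locus and loci stay linked within
individuals. A new deme is founded by ``founder_copies`` individuals drawn
without replacement from the pooled copies of all its already-colonised rook
neighbours (gene flow along the wavefront, without which neighbouring
lineages drift apart and pooled kernel diversity stops declining with
distance), grown back to capacity by resampling with replacement, then
iterated for ``generations_per_step`` Wright–Fisher generations with
stepwise mutation (allele ±1 repeat unit with probability ``mutation_rate``
per copy per generation, reflecting at the repeat-length bounds). With zero
mutation the expected unbiased heterozygosity of a deme founded from a
single parent shrinks by the factor

    (1 - 1/founder_copies) * (1 - 1/deme_capacity) ** generations_per_step

per colonisation step. Demes are frozen once their children are founded; the
decline along any colonisation path is then exactly geometric, which is the
idealised signal the inference targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import GeoGrid, GeoPoint, build_grid
from .io import MISSING, SampleTable, make_table


@dataclass(frozen=True)
class ExpansionConfig:
    """Simulator parameters; defaults give a strong, desk-scale expansion
    over a 20°×10° domain with 200 sampled landraces at 16 loci."""

    origin: GeoPoint = GeoPoint(34.0, 100.0)
    lat_min: float = 30.0
    lat_max: float = 40.0
    lon_min: float = 95.0
    lon_max: float = 115.0
    deme_lattice_step: float = 1.0
    founder_copies: int = 8
    deme_capacity: int = 100
    generations_per_step: int = 1
    mutation_rate: float = 5e-4
    n_loci: int = 16
    ancestral_allele_range: tuple[int, int] = (8, 40)
    n_samples: int = 200
    sampling: str = "uniform"  # or "clustered"
    missing_rate: float = 0.02
    jitter_deg: float = 0.0
    seed: int = 0

    def validate(self) -> "ExpansionConfig":
        if not (self.lat_min <= self.origin.latitude <= self.lat_max):
            raise ValueError("origin latitude outside domain")
        if not (self.lon_min <= self.origin.longitude <= self.lon_max):
            raise ValueError("origin longitude outside domain")
        if not (1 <= self.founder_copies <= self.deme_capacity):
            raise ValueError("need 1 <= founder_copies <= deme_capacity")
        for name in ("mutation_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.ancestral_allele_range[0] >= self.ancestral_allele_range[1]:
            raise ValueError("ancestral_allele_range must be (low, high) with low < high")
        if self.sampling not in ("uniform", "clustered"):
            raise ValueError("sampling must be 'uniform' or 'clustered'")
        return self

    @property
    def per_step_h_factor(self) -> float:
        """Expected multiplicative loss of unbiased h per colonisation step
        at zero mutation."""
        return (1.0 - 1.0 / self.founder_copies) * (
            1.0 - 1.0 / self.deme_capacity
        ) ** self.generations_per_step

    def deme_grid(self) -> GeoGrid:
        return build_grid(
            self.lat_min, self.lat_max, self.lon_min, self.lon_max, self.deme_lattice_step
        )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated expansion."""

    origin: GeoPoint  # origin deme center (lattice-snapped)
    demes: pd.DataFrame  # latitude, longitude, depth, expected_h_rel
    colonisation_order: list[int]  # deme indices in founding order
    config: ExpansionConfig


def simulate_expansion(config: ExpansionConfig) -> tuple[SampleTable, SyntheticTruth]:
    """Run one expansion and sample a landrace table from it.

    Deterministic for a fixed config (the seed is part of the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = config.deme_grid()
    lats, lons = grid.lats, grid.lons
    n_lat, n_lon = grid.shape
    n_demes = n_lat * n_lon
    lo, hi = config.ancestral_allele_range

    # origin deme = nearest lattice node (degrees suffice for snapping)
    oi = int(np.argmin(np.abs(lats - config.origin.latitude)))
    oj = int(np.argmin(np.abs(lons - config.origin.longitude)))
    origin_idx = oi * n_lon + oj

    states = [None] * n_demes  # (capacity, n_loci) int arrays
    depth = np.full(n_demes, -1, dtype=int)
    states[origin_idx] = rng.integers(lo, hi + 1, size=(config.deme_capacity, config.n_loci))
    depth[origin_idx] = 0
    order = [origin_idx]
    frontier = [origin_idx]
    while frontier:
        # synchronous wave: every empty deme adjacent to the colonised region
        # is founded from the pooled copies of all its colonised rook
        # neighbours (gene flow along the wavefront keeps neighbouring
        # lineages from diverging apart)
        wave: dict[int, list[int]] = {}
        for idx in np.where(depth >= 0)[0]:
            i, j = divmod(int(idx), n_lon)
            for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                if 0 <= ni < n_lat and 0 <= nj < n_lon:
                    nidx = ni * n_lon + nj
                    if depth[nidx] < 0:
                        wave.setdefault(nidx, []).append(int(idx))
        if not wave:
            break
        step = int(depth.max()) + 1
        for nidx in sorted(wave):
            pool = np.concatenate([states[p] for p in wave[nidx]], axis=0)
            states[nidx] = _found_deme(pool, config, rng)
            depth[nidx] = step
            order.append(nidx)
        frontier = sorted(wave)

    # sample landraces
    if config.sampling == "uniform":
        weights = np.full(n_demes, 1.0 / n_demes)
    else:
        weights = rng.dirichlet(np.full(n_demes, 0.3))
    sample_demes = rng.choice(n_demes, size=config.n_samples, p=weights)
    records = []
    for s, d in enumerate(sample_demes):
        individual = states[d][rng.integers(config.deme_capacity)]
        i, j = divmod(int(d), n_lon)
        lat, lon = float(lats[i]), float(lons[j])
        if config.jitter_deg > 0:
            lat += float(rng.uniform(-config.jitter_deg, config.jitter_deg))
            lon += float(rng.uniform(-config.jitter_deg, config.jitter_deg))
        rec = {
            "sample_id": f"SIM{s:04d}",
            "region": f"deme_{d}",
            "latitude": lat,
            "longitude": lon,
        }
        for l in range(config.n_loci):
            call = str(int(individual[l]))
            if rng.random() < config.missing_rate:
                call = MISSING
            rec[f"locus_{l + 1:02d}"] = call
        records.append(rec)
    table = make_table(records, [f"locus_{l + 1:02d}" for l in range(config.n_loci)])

    lat_g, lon_g = np.meshgrid(lats, lons, indexing="ij")
    demes = pd.DataFrame(
        {
            "latitude": lat_g.ravel(),
            "longitude": lon_g.ravel(),
            "depth": depth,
            "expected_h_rel": config.per_step_h_factor ** depth.astype(float),
        }
    )
    truth = SyntheticTruth(
        GeoPoint(float(lats[oi]), float(lons[oj])), demes, order, config
    )
    return table, truth


def _found_deme(parent: np.ndarray, config: ExpansionConfig, rng: np.random.Generator) -> np.ndarray:
    cap = config.deme_capacity
    founders = parent[rng.choice(len(parent), size=config.founder_copies, replace=False)]
    state = founders[rng.integers(config.founder_copies, size=cap)]
    for _ in range(config.generations_per_step):
        state = state[rng.integers(cap, size=cap)]
        state = _mutate(state, config, rng)
    return state


def _mutate(state: np.ndarray, config: ExpansionConfig, rng: np.random.Generator) -> np.ndarray:
    if config.mutation_rate == 0.0:
        return state
    lo, hi = config.ancestral_allele_range
    hits = rng.random(state.shape) < config.mutation_rate
    if not hits.any():
        return state
    steps = rng.choice((-1, 1), size=int(hits.sum()))
    state = state.copy()
    state[hits] = state[hits] + steps
    # reflect at the repeat-length bounds
    state[state < lo] = lo + (lo - state[state < lo])
    state[state > hi] = hi - (state[state > hi] - hi)
    return state


def null_shuffle(table: SampleTable, seed: int = 0) -> SampleTable:
    """Structureless negative control: genotype vectors randomly reassigned
    to sample coordinates; the allele pool is untouched."""
    rng = np.random.default_rng(seed)
    return table.with_genotypes_permuted(rng.permutation(table.n_samples))


def paint_gbssi(table: SampleTable, boundary_lon: float = 110.0, seed: int = 0) -> SampleTable:
    """Paint synthetic GBSSI-S/L genotypes onto a table for map testing.

    West of ``boundary_lon`` the wild-type S0 and LC alleles predominate,
    east of it the waxy S-15/LY/Lf alleles do — a cartoon of the east–west
    cline in the real crop. Purely decorative; carries no fitness effect.
    """
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    lons = df["longitude"].to_numpy(dtype=float)
    s_geno, l_geno = [], []
    for lon in lons:
        west = not np.isfinite(lon) or lon < boundary_lon
        p_s0 = 0.8 if west else 0.2
        a1, a2 = rng.random(2) < p_s0
        s_geno.append({2: "S0/S0", 1: "S0/S-15", 0: "S-15/S-15"}[int(a1) + int(a2)])
        p_l = (0.6, 0.2, 0.2) if west else (0.05, 0.35, 0.6)
        alleles = sorted(rng.choice(("LC", "LY", "Lf"), size=2, p=p_l),
                         key=("LC", "LY", "Lf").index)
        l_geno.append("/".join(alleles))
    df["gbssi_s"] = s_geno
    df["gbssi_l"] = l_geno
    return SampleTable(df, list(table.locus_names), table.copies_per_sample)
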