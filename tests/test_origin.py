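import numpy as np
import pytest

from originscan import (
    GeoPoint,
    accept_kernels,
    build_grid,
    compare_origins,
    correlation_surface,
    geolocated_subset,
    haversine_km,
    interpolate_surface,
    kernel_set_diversity,
    make_table,
    null_shuffle,
    site_correlation,
)
from originscan.diversity import KernelDiversity, weighted_pearson_r
from originscan.kernels import Kernel
from originscan.origin import OriginSurface

from conftest import spherical_law_of_cosines_km


def _diversities(centers, h_values):
    out = []
    for (lat, lon), h in zip(centers, h_values):
        k = Kernel(GeoPoint(lat, lon), (0,), ("x",))
        out.append(KernelDiversity(k, np.array([h]), h))
    return out


class TestSiteCorrelation:
    def test_perfect_gradient_gives_minus_one(self):
        origin = GeoPoint(0.0, 0.0)
        centers = [(0.0, lon) for lon in (5.0, 10.0, 15.0, 20.0)]
        dists = [haversine_km(origin, GeoPoint(*c)) for c in centers]
        h = [1.0 - d / 25000.0 for d in dists]  # strictly decreasing in distance
        assert site_correlation(origin, _diversities(centers, h)) == pytest.approx(-1.0)

    def test_constant_diversity_undefined(self):
        divs = _diversities([(0, 5), (0, 10), (0, 15)], [0.4, 0.4, 0.4])
        assert np.isnan(site_correlation(GeoPoint(0, 0), divs))

    def test_fewer_than_two_usable_kernels_warns(self):
        divs = _diversities([(0, 5)], [0.4])
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert np.isnan(site_correlation(GeoPoint(0, 0), divs))

    def test_composition_of_distance_and_correlation_oracles(self):
        rng = np.random.default_rng(11)
        centers = [(float(la), float(lo)) for la, lo in
                   zip(rng.uniform(20, 50, 30), rng.uniform(80, 120, 30))]
        h = rng.uniform(0.1, 0.9, 30)
        origin = GeoPoint(35.0, 100.0)
        got = site_correlation(origin, _diversities(centers, h))
        d = [spherical_law_of_cosines_km(origin, GeoPoint(*c)) for c in centers]
        assert got == pytest.approx(np.corrcoef(d, h)[0, 1], abs=1e-6)

    def test_multiplicity_equals_replication(self):
        rng = np.random.default_rng(12)
        centers = [(float(la), float(lo)) for la, lo in
                   zip(rng.uniform(20, 50, 8), rng.uniform(80, 120, 8))]
        h = rng.uniform(0.1, 0.9, 8)
        mult = rng.integers(1, 4, 8)
        divs = []
        replicated = []
        for (lat, lon), hv, m in zip(centers, h, mult):
            k = Kernel(GeoPoint(lat, lon), (0,), ("x",), multiplicity=int(m))
            divs.append(KernelDiversity(k, np.array([hv]), float(hv)))
            replicated.extend([( (lat, lon), hv )] * int(m))
        origin = GeoPoint(35.0, 100.0)
        flat = site_correlation(
            origin,
            _diversities([c for c, _ in replicated], [hv for _, hv in replicated]),
        )
        assert site_correlation(origin, divs) == pytest.approx(flat, abs=1e-12)


class TestCorrelationSurface:
    def test_recovers_simulated_origin(self, default_expansion, default_grid):
        table, truth = default_expansion
        surf = correlation_surface(table, default_grid)
        best = surf.best_origin()
        assert haversine_km(best, truth.origin) <= 500.0
        assert np.nanmin(surf.r_values) < -0.5

    def test_shuffled_genotypes_flatten_the_surface(self, default_expansion, default_grid):
        table, _ = default_expansion
        structured = correlation_surface(table, default_grid)
        shuffled = correlation_surface(null_shuffle(table, seed=1), default_grid)
        assert np.nanmin(shuffled.r_values) > np.nanmin(structured.r_values)
        assert np.nanmean(np.abs(shuffled.r_values)) < np.nanmean(np.abs(structured.r_values))
        # and the argmin wanders across reshuffles
        argmins = set()
        for seed in (1, 2, 3):
            s = correlation_surface(null_shuffle(table, seed=seed), default_grid)
            argmins.add(s.best_origin())
        assert len(argmins) > 1

    def test_single_kernel_is_an_error(self):
        t = make_table(
            [
                {"sample_id": f"s{i}", "latitude": 0.0, "longitude": 0.0, "locus_1": str(i)}
                for i in range(5)
            ],
            ["locus_1"],
        )
        g = build_grid(0, 0, 0, 0, 1.0)
        with pytest.raises(ValueError, match="kernel"):
            correlation_surface(t, g)


class TestCompareOrigins:
    def test_coincident_sites_give_zero_delta_and_p_one(self, default_expansion, default_grid):
        table, truth = default_expansion
        cmp = compare_origins(table, truth.origin, truth.origin, default_grid,
                              n_perm=49, seed=5)
        assert cmp.observed_delta_r == 0.0
        assert cmp.p_two_tailed == 1.0

    def test_site_swap_negates_delta_and_keeps_p(self, default_expansion, default_grid):
        table, truth = default_expansion
        far = GeoPoint(38.0, 114.0)
        ab = compare_origins(table, truth.origin, far, default_grid, n_perm=99, seed=5)
        ba = compare_origins(table, far, truth.origin, default_grid, n_perm=99, seed=5)
        assert ab.observed_delta_r == pytest.approx(-ba.observed_delta_r, abs=1e-12)
        assert ab.p_two_tailed == ba.p_two_tailed
        np.testing.assert_allclose(ab.null_delta_r, -ba.null_delta_r, atol=1e-12)

    def test_null_matches_full_recomputation_per_permutation(self, default_grid):
        """Memberships are fixed by coordinates, so permuting genotypes and
        re-running the whole kernel pipeline from scratch must give the same
        null deltas as the fast path."""
        from originscan import ExpansionConfig, simulate_expansion

        table, truth = simulate_expansion(ExpansionConfig(n_samples=80, seed=21))
        site_a, site_b = truth.origin, GeoPoint(38.0, 114.0)
        n_perm, seed = 5, 99
        cmp = compare_origins(table, site_a, site_b, default_grid,
                              n_perm=n_perm, seed=seed)
        geo = geolocated_subset(table)
        rng = np.random.default_rng(seed)
        for i in range(n_perm):
            perm = rng.permutation(geo.n_samples)
            permuted = geo.with_genotypes_permuted(perm)
            ks = accept_kernels(permuted, default_grid)
            divs = kernel_set_diversity(ks)
            delta = site_correlation(site_a, divs) - site_correlation(site_b, divs)
            assert cmp.null_delta_r[i] == pytest.approx(delta, abs=1e-10)

    def test_undefined_site_correlation_is_reported(self):
        # constant genotypes -> zero-variance diversity at every kernel
        t = make_table(
            [
                {"sample_id": f"s{i}", "latitude": 30.0 + i * 0.1, "longitude": 100.0,
                 "locus_1": "10"}
                for i in range(12)
            ],
            ["locus_1"],
        )
        g = build_grid(30, 31, 100, 100, 0.5)
        with pytest.raises(ValueError, match="site_a"):
            compare_origins(t, GeoPoint(30, 100), GeoPoint(31, 100), g, n_perm=9, seed=0)


class TestInterpolation:
    def _surface(self, values, lat_max=1.0, lon_max=1.0, res=1.0):
        grid = build_grid(0.0, lat_max, 0.0, lon_max, res)
        return OriginSurface(grid, np.asarray(values, dtype=float), None)

    def test_factor_one_is_identity(self):
        surf = self._surface([[0.1, 0.2], [0.3, 0.4]])
        lats, lons, vals = interpolate_surface(surf, 1)
        np.testing.assert_array_equal(vals, surf.r_values)

    def test_bilinear_midpoint_is_corner_mean(self):
        surf = self._surface([[0.0, 1.0], [2.0, 3.0]])
        _, _, vals = interpolate_surface(surf, 2)
        assert vals.shape == (3, 3)
        assert vals[1, 1] == pytest.approx((0.0 + 1.0 + 2.0 + 3.0) / 4)

    def test_nodes_reproduced_exactly(self):
        rng = np.random.default_rng(4)
        surf = self._surface(rng.uniform(-1, 1, (4, 5)), lat_max=3.0, lon_max=4.0)
        _, _, vals = interpolate_surface(surf, 3)
        np.testing.assert_allclose(vals[::3, ::3], surf.r_values, atol=1e-12)

    def test_factor_below_one_rejected(self):
        surf = self._surface([[0.0, 1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            interpolate_surface(surf, 0)
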