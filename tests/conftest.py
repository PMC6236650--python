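import numpy as np
import pytest

from originscan import ExpansionConfig, GeoPoint, build_grid, make_table, simulate_expansion


@pytest.fixture
def tiny_table():
    """Three geolocated samples, two loci, no missing data."""
    return make_table(
        [
            {"sample_id": "a", "region": "X", "latitude": 35.0, "longitude": 105.0,
             "locus_1": "10", "locus_2": "20"},
            {"sample_id": "b", "region": "X", "latitude": 36.0, "longitude": 106.0,
             "locus_1": "12", "locus_2": "20"},
            {"sample_id": "c", "region": "Y", "latitude": 37.0, "longitude": 107.0,
             "locus_1": "10", "locus_2": "22"},
        ],
        ["locus_1", "locus_2"],
    )


@pytest.fixture
def random_table():
    """50 samples scattered over a few-degree box, 4 loci with missing calls."""
    rng = np.random.default_rng(42)
    loci = [f"locus_{l}" for l in range(1, 5)]
    records = []
    for i in range(50):
        rec = {
            "sample_id": f"s{i:02d}",
            "region": "sim",
            "latitude": float(rng.uniform(30, 40)),
            "longitude": float(rng.uniform(100, 112)),
        }
        for name in loci:
            rec[name] = "NA" if rng.random() < 0.1 else str(int(rng.integers(8, 14)))
        records.append(rec)
    return make_table(records, loci)


@pytest.fixture(scope="session")
def default_expansion():
    """One expansion at default parameters, shared across tests."""
    return simulate_expansion(ExpansionConfig(seed=7))


@pytest.fixture(scope="session")
def default_grid():
    cfg = ExpansionConfig()
    return build_grid(cfg.lat_min, cfg.lat_max, cfg.lon_min, cfg.lon_max, 0.5)


def spherical_law_of_cosines_km(a: GeoPoint, b: GeoPoint) -> float:
    """Independent closed-form great-circle distance for cross-checks."""
    la1, lo1, la2, lo2 = map(np.radians, [a.latitude, a.longitude, b.latitude, b.longitude])
    cosc = np.sin(la1) * np.sin(la2) + np.cos(la1) * np.cos(la2) * np.cos(lo2 - lo1)
    return 6371.0088 * float(np.arccos(np.clip(cosc, -1.0, 1.0)))
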