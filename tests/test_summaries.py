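import numpy as np
import pandas as pd
import pytest

from originscan import (
    delta_k,
    gbssi_summary,
    genotype_matrix,
    make_table,
    optimal_k,
    pca,
    read_cluster_runs,
    synthetic_cluster_log,
)


class TestGenotypeMatrix:
    def test_two_samples_one_biallelic_locus(self):
        t = make_table(
            [
                {"sample_id": "a", "latitude": 0.0, "longitude": 0.0, "locus_1": "A"},
                {"sample_id": "b", "latitude": 0.0, "longitude": 0.0, "locus_1": "B"},
            ],
            ["locus_1"],
        )
        m = genotype_matrix(t)
        assert m.columns == [("locus_1", "A"), ("locus_1", "B")]
        np.testing.assert_array_equal(m.values, [[1.0, 0.0], [0.0, 1.0]])

    def test_missing_locus_imputed_with_column_mean(self):
        t = make_table(
            [
                {"sample_id": "a", "latitude": 0.0, "longitude": 0.0, "locus_1": "A"},
                {"sample_id": "b", "latitude": 0.0, "longitude": 0.0, "locus_1": "A"},
                {"sample_id": "c", "latitude": 0.0, "longitude": 0.0, "locus_1": "B"},
                {"sample_id": "d", "latitude": 0.0, "longitude": 0.0, "locus_1": "NA"},
            ],
            ["locus_1"],
        )
        m = genotype_matrix(t)
        np.testing.assert_allclose(m.values[3], [2 / 3, 1 / 3])

    def test_complete_rows_sum_to_one_per_locus(self, random_table):
        m = genotype_matrix(random_table)
        start = 0
        for locus in random_table.locus_names:
            cols = [i for i, (l, _) in enumerate(m.columns) if l == locus]
            sums = m.values[:, cols].sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestPCA:
    def test_single_informative_direction_takes_all_variance(self):
        t = make_table(
            [
                {"sample_id": f"s{i}", "latitude": 0.0, "longitude": 0.0,
                 "locus_1": g, "locus_2": g.lower()}
                for i, g in enumerate(["A", "A", "B", "B", "A", "B"])
            ],
            ["locus_1", "locus_2"],
        )
        res = pca(genotype_matrix(t), n_components=2)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_match_dense_eigendecomposition(self, random_table):
        m = genotype_matrix(random_table)
        res = pca(m, n_components=4)
        x = m.values[:, m.values.std(axis=0) > 0]
        xc = x - x.mean(axis=0)
        evals = np.linalg.eigh(np.cov(xc, rowvar=False))[0][::-1]
        np.testing.assert_allclose(res.variance_fraction, evals[:4] / evals.sum(), atol=1e-8)
        assert (np.diff(res.variance_fraction) <= 1e-12).all()
        assert res.variance_fraction.sum() <= 1.0 + 1e-12

    def test_row_order_invariance(self, random_table):
        m = genotype_matrix(random_table)
        shuffled = make_table(
            random_table.df.iloc[::-1].to_dict("records"), random_table.locus_names
        )
        m2 = genotype_matrix(shuffled)
        np.testing.assert_allclose(
            pca(m, 3).variance_fraction, pca(m2, 3).variance_fraction, atol=1e-10
        )

    def test_excess_components_truncated_with_warning(self):
        t = make_table(
            [
                {"sample_id": "a", "latitude": 0.0, "longitude": 0.0, "locus_1": "A"},
                {"sample_id": "b", "latitude": 0.0, "longitude": 0.0, "locus_1": "B"},
            ],
            ["locus_1"],
        )
        with pytest.warns(UserWarning, match="exceeds"):
            res = pca(genotype_matrix(t), n_components=5)
        assert res.scores.shape[1] == 1


class TestDeltaK:
    def test_linear_likelihood_gives_near_zero(self):
        rng = np.random.default_rng(0)
        rows = [
            (k, run, -5000.0 + 100.0 * k + rng.normal(0, 1.0))
            for k in range(1, 7)
            for run in range(10)
        ]
        dk = delta_k(pd.DataFrame(rows, columns=["K", "run", "lnP"]))
        interior = dk.dropna(subset=["delta_K"])
        assert (interior["delta_K"] < 5).all()

    def test_constructed_elbow_recovered_at_three(self):
        runs = synthetic_cluster_log(k_true=3, k_range=(1, 8), n_runs=10, seed=1)
        dk = delta_k(runs)
        assert optimal_k(dk) == 3
        assert np.isnan(dk.loc[dk["K"] == 1, "delta_K"]).all()
        assert np.isnan(dk.loc[dk["K"] == 8, "delta_K"]).all()

    def test_identical_replicates_undefined_not_infinite(self):
        rows = [(k, run, -100.0 * k) for k in range(1, 5) for run in range(3)]
        dk = delta_k(pd.DataFrame(rows, columns=["K", "run", "lnP"]))
        assert dk["delta_K"].isna().all()

    def test_shift_and_scale_invariance(self):
        runs = synthetic_cluster_log(seed=2)
        base = delta_k(runs)["delta_K"]
        shifted = runs.assign(lnP=runs["lnP"] + 1234.5)
        scaled = runs.assign(lnP=runs["lnP"] * 3.0)
        np.testing.assert_allclose(delta_k(shifted)["delta_K"], base, atol=1e-9)
        np.testing.assert_allclose(delta_k(scaled)["delta_K"], base, atol=1e-9)

    def test_roundtrip_through_log_file(self, tmp_path):
        runs = synthetic_cluster_log(seed=3)
        path = tmp_path / "runs.csv"
        runs.to_csv(path, index=False)
        assert read_cluster_runs(path).equals(pd.read_csv(path))

    def test_short_or_gapped_k_range_rejected(self):
        rows = [(k, run, -1.0) for k in (1, 2, 4) for run in range(3)]
        with pytest.raises(ValueError):
            delta_k(pd.DataFrame(rows, columns=["K", "run", "lnP"]))


class TestGBSSI:
    def _table(self, genotypes):
        return make_table(
            [
                {"sample_id": f"s{i}", "latitude": 0.0, "longitude": 0.0,
                 "locus_1": "10", "gbssi_s": s, "gbssi_l": l, "region": reg}
                for i, (s, l, reg) in enumerate(genotypes)
            ],
            ["locus_1"],
        )

    def test_all_wildtype_homozygotes(self):
        t = self._table([("S0/S0", "LC/LC", "w")] * 4)
        s = gbssi_summary(t)
        assert s.allele_freqs.loc["all", "gbssi_s:S0"] == 1.0
        assert (s.phenotypes["phenotype"] == "wild-type").all()

    def test_heterozygote_is_phenotypically_wildtype(self):
        s = gbssi_summary(self._table([("S0/S-15", "LY/Lf", "x")]))
        assert s.phenotypes["phenotype"].iloc[0] == "wild-type"

    def test_waxy_classes_follow_l_locus_rule(self):
        t = self._table([("S-15/S-15", "LY/Lf", "x"), ("S-15/S-15", "LC/Lf", "x")])
        pheno = gbssi_summary(t).phenotypes["phenotype"]
        assert pheno.tolist() == ["waxy (full)", "waxy (partial)"]
        # and with the rescue rule disabled both are simply full waxy
        pheno2 = gbssi_summary(t, lc_rescues_waxy=False).phenotypes["phenotype"]
        assert pheno2.tolist() == ["waxy (full)", "waxy (full)"]

    def test_mixed_fixture_matches_hand_tally(self):
        t = self._table(
            [
                ("S0/S0", "LC/LY", "west"),
                ("S0/S-15", "LC/LC", "west"),
                ("S-15/S-15", "Lf/Lf", "east"),
                ("NA", "LY/Lf", "east"),
            ]
        )
        s = gbssi_summary(t, grouping="region")
        # west: S alleles S0,S0,S0,S-15 -> 3/4; L alleles LC,LY,LC,LC -> LC 3/4
        assert s.allele_freqs.loc["west", "gbssi_s:S0"] == pytest.approx(0.75)
        assert s.allele_freqs.loc["west", "gbssi_l:LC"] == pytest.approx(0.75)
        # east: S counted only for the scored sample; missing excluded
        assert s.allele_freqs.loc["east", "gbssi_s:S-15"] == pytest.approx(1.0)
        assert s.allele_freqs.loc["east", "gbssi_l:Lf"] == pytest.approx(0.75)

    def test_frequencies_invariant_to_sample_order(self):
        rows = [("S0/S0", "LC/LY", "a"), ("S0/S-15", "LY/Lf", "a"), ("S-15/S-15", "Lf/Lf", "a")]
        f1 = gbssi_summary(self._table(rows)).allele_freqs
        f2 = gbssi_summary(self._table(rows[::-1])).allele_freqs
        pd.testing.assert_frame_equal(f1, f2)

    def test_table_without_gbssi_columns_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            gbssi_summary(tiny_table)
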