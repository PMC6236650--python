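#!/usr/bin/env python
"""Secondary analyses on the simulated table: PCA, ΔK and GBSSI maps.

Runs the genotype PCA, computes the Evanno ΔK statistic on a synthetic
clustering log with a known elbow, paints cartoon GBSSI genotypes on the
simulated samples to exercise the allele-frequency summary and maps, and
draws per-sample ancestry pies from k-means clusters of the PCA scores.
"""

import argparse
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from originscan import (
    delta_k,
    gbssi_summary,
    genotype_matrix,
    optimal_k,
    paint_gbssi,
    pca,
    read_samples,
    synthetic_cluster_log,
)
from originscan.plotting import render_gbssi_map, render_pie_map


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--samples", type=Path, default=Path("results/synthetic_samples.csv"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    fig_dir = args.out_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)

    table = read_samples(args.samples)

    # PCA of the allele-indicator matrix
    m = genotype_matrix(table)
    res = pca(m, n_components=2)
    np.savetxt(
        args.out_dir / "pca_scores.csv",
        np.column_stack([res.scores]), delimiter=",", header="PC1,PC2", comments="",
    )
    print(f"PC1/PC2 variance: {res.variance_fraction[0]*100:.1f}% / "
          f"{res.variance_fraction[1]*100:.1f}%")

    # ancestry-style pies from k-means on the scores (hard assignments)
    km = KMeans(n_clusters=3, n_init=10, random_state=args.seed).fit(res.scores)
    memberships = np.eye(3)[km.labels_]
    render_pie_map(table, memberships, path=fig_dir / "ancestry_pies.png")

    # Evanno delta-K on a synthetic clustering log with an elbow at K = 3
    runs = synthetic_cluster_log(k_true=3, k_range=(1, 8), n_runs=10, seed=args.seed)
    dk = delta_k(runs)
    dk.to_csv(args.out_dir / "delta_k.csv", index=False)
    print(f"delta-K optimum: K = {optimal_k(dk)}")

    # GBSSI summaries on painted genotypes (synthetic, for map testing only)
    painted = paint_gbssi(table, boundary_lon=105.0, seed=args.seed)
    summary = gbssi_summary(painted, grouping="region")
    summary.allele_freqs.to_csv(args.out_dir / "gbssi_frequencies.csv")
    counts = summary.phenotypes["phenotype"].value_counts()
    print("GBSSI phenotype counts:", dict(counts))
    render_gbssi_map(painted, "gbssi_s", path=fig_dir / "gbssi_s_map.png")
    render_gbssi_map(painted, "gbssi_l", path=fig_dir / "gbssi_l_map.png")
    print(f"wrote pca_scores.csv, delta_k.csv, gbssi_frequencies.csv and figures/")


if __name__ == "__main__":
    main()
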