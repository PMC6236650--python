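"""Secondary analyses: genotype PCA, the Evanno ΔK model-selection
statistic over external Bayesian-clustering logs, and GBSSI allele /
phenotype summaries.

Bayesian clustering itself (STRUCTURE/InStruct-style Gibbs sampling) is out
of scope here: :func:`delta_k` consumes a plain delimited log with columns
``K, run, lnP`` — the per-run log-probability of the data — however those
runs were produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .io import MISSING, SampleTable


# ---------------------------------------------------------------------------
# PCA on the allele-indicator encoding
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Allele-indicator encoding of a sample table.

    One column per (locus, allele) pair holding the fraction of the sample's
    scored copies at that locus carrying the allele, so complete rows sum to
    1 within each locus. Missing loci are imputed with the column mean.
    """

    values: np.ndarray  # samples × indicator columns, imputed, not centred
    columns: list[tuple[str, str]]  # (locus, allele) per column
    sample_ids: list[str]


@dataclass
class PCAResult:
    scores: np.ndarray  # samples × components
    variance_fraction: np.ndarray  # per-component fraction of total variance


def genotype_matrix(table: SampleTable) -> GenotypeMatrix:
    """Encode genotypes as allele copy-fraction indicators."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    codes, labels = table.allele_codes()
    p = table.copies_per_sample
    cols: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for l, name in enumerate(table.locus_names):
        k = len(labels[l])
        block = np.full((table.n_samples, k), np.nan)
        locus_codes = codes[:, l * p : (l + 1) * p]
        scored = (locus_codes >= 0).sum(axis=1)
        has = scored > 0
        if k:
            onehot = np.zeros((table.n_samples, k))
            for j in range(p):
                c = locus_codes[:, j]
                ok = c >= 0
                onehot[np.where(ok)[0], c[ok]] += 1.0
            block[has] = onehot[has] / scored[has, None]
        # column-mean imputation for samples missing the whole locus
        if has.any():
            block[~has] = np.nanmean(block[has], axis=0)
        else:
            block[:] = 0.0
        blocks.append(block)
        cols.extend((name, lab) for lab in labels[l])
    x = np.hstack(blocks) if blocks else np.zeros((table.n_samples, 0))
    return GenotypeMatrix(x, cols, table.sample_ids)


def pca(matrix: GenotypeMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the centred indicator matrix.

    ``variance_fraction[i]`` is the i-th eigenvalue of the column covariance
    over the total variance of all (non-constant) columns. Zero-variance
    columns are dropped first; requesting more components than the matrix
    rank truncates with a warning.
    """
    x = matrix.values
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)", stacklevel=2)
    x = x[:, keep]
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x - x.mean(axis=0))
    return PCAResult(scores, model.explained_variance_ratio_.copy())


# ---------------------------------------------------------------------------
# Evanno ΔK
# ---------------------------------------------------------------------------


def read_cluster_runs(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a clustering log table with columns K, run, lnP."""
    df = pd.read_csv(path, sep=delimiter)
    missing = {"K", "run", "lnP"} - set(df.columns)
    if missing:
        raise ValueError(f"cluster run table lacks column(s) {sorted(missing)}")
    return df


def delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Evanno ΔK per interior K from replicate log-probabilities.

    For each interior K, replicate runs (paired by run index) give second
    differences L(K+1) − 2L(K) + L(K−1); ΔK is the mean of their absolute
    values divided by the standard deviation (ddof=1) of L(K) across
    replicates. ΔK is NaN at the boundary K values and wherever that
    standard deviation is zero.
    """
    ks = np.array(sorted(runs["K"].unique()))
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need >= 3 consecutive K values")
    piv = runs.pivot_table(index="run", columns="K", values="lnP")
    if piv.isna().any().any() or len(piv) < 2:
        raise ValueError("need >= 2 replicates at every K (paired by run index)")
    l = piv.to_numpy()  # runs × K
    out = []
    for idx, k in enumerate(ks):
        if idx == 0 or idx == len(ks) - 1:
            out.append((k, np.nan))
            continue
        second = l[:, idx + 1] - 2.0 * l[:, idx] + l[:, idx - 1]
        sd = l[:, idx].std(ddof=1)
        out.append((k, float(np.mean(np.abs(second)) / sd) if sd > 0 else np.nan))
    return pd.DataFrame(out, columns=["K", "delta_K"])


def optimal_k(dk: pd.DataFrame) -> int:
    """Interior K with the largest ΔK."""
    interior = dk.dropna(subset=["delta_K"])
    if interior.empty:
        raise ValueError("delta_K undefined at every interior K")
    return int(interior.loc[interior["delta_K"].idxmax(), "K"])


def synthetic_cluster_log(
    k_true: int = 3,
    k_range: tuple[int, int] = (1, 8),
    n_runs: int = 10,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a clustering log with a likelihood elbow at ``k_true``:
    lnP rises steeply up to the true K, then nearly plateaus."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(k_range[0], k_range[1] + 1):
        base = -10000.0 + 400.0 * min(k, k_true) + 10.0 * max(0, k - k_true)
        for run in range(n_runs):
            rows.append((k, run, base + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["K", "run", "lnP"])


# ---------------------------------------------------------------------------
# GBSSI summaries
# ---------------------------------------------------------------------------


@dataclass
class GBSSISummary:
    allele_freqs: pd.DataFrame  # group × allele frequency (per locus, sums to 1)
    phenotypes: pd.DataFrame  # per-sample phenotype classes


def gbssi_summary(
    table: SampleTable,
    grouping: str | None = None,
    lc_rescues_waxy: bool = True,
) -> GBSSISummary:
    """Allele frequencies and starch phenotypes from the GBSSI genotypes.

    The functional S0 allele is dominant: any sample carrying S0 is
    phenotypically wild type (non-waxy). Among S-15 homozygotes the L locus
    decides the degree: with ``lc_rescues_waxy`` (the default, interpretive
    rule) a sample with no LC allele is classed fully waxy, with an LC allele
    partially waxy. Missing genotypes are excluded from every denominator.

    ``grouping`` names a column of the table (e.g. ``region``) to tally
    frequencies by; None pools all samples.
    """
    df = table.df
    if "gbssi_s" not in df.columns and "gbssi_l" not in df.columns:
        raise ValueError("table has no GBSSI columns")
    groups = df[grouping] if grouping else pd.Series(["all"] * len(df), index=df.index)

    rows = []
    for gname, sub in df.groupby(groups, sort=True):
        rec: dict = {"group": gname}
        for col, alleles in (("gbssi_s", ("S0", "S-15")), ("gbssi_l", ("LC", "LY", "Lf"))):
            tally = {a: 0 for a in alleles}
            total = 0
            if col in sub.columns:
                for cell in sub[col]:
                    if cell and cell != MISSING:
                        for a in str(cell).split("/"):
                            tally[a] += 1
                            total += 1
            for a in alleles:
                rec[f"{col}:{a}"] = tally[a] / total if total else np.nan
        rows.append(rec)
    freqs = pd.DataFrame(rows).set_index("group")

    pheno = []
    for _, row in df.iterrows():
        s = row.get("gbssi_s", MISSING)
        l = row.get("gbssi_l", MISSING)
        if not s or s == MISSING:
            cls = "unknown"
        elif "S0" in str(s).split("/"):
            cls = "wild-type"  # S0 dominant
        elif lc_rescues_waxy and l and l != MISSING and "LC" in str(l).split("/"):
            cls = "waxy (partial)"
        else:
            cls = "waxy (full)" if l and l != MISSING else "waxy"
        pheno.append({"sample_id": row["sample_id"], "phenotype": cls})
    return GBSSISummary(freqs, pd.DataFrame(pheno))
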