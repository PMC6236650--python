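"""Unbiased gene diversity and correlation primitives.

The diversity measure is Nei's unbiased heterozygosity (gene diversity)

    h = n/(n-1) * (1 - sum_i p_i^2),    n = non-missing allele copies,

the probability that two allele copies drawn *without replacement* differ.
It is undefined for n < 2. Kernel diversity averages h over loci with a
defined value; loci where fewer than two copies were scored among the
kernel's members are excluded from the mean rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import SampleTable
from .kernels import Kernel, KernelSet


def unbiased_h(counts: Mapping[str, int] | Sequence[int]) -> float:
    """Nei's unbiased gene diversity from allele counts at one locus.

    Returns NaN (undefined) when fewer than 2 copies were scored.
    """
    vals = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else list(counts), dtype=float
    )
    if np.any(vals < 0):
        raise ValueError("allele counts must be non-negative")
    n = vals.sum()
    if n < 2:
        return float("nan")
    p = vals / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN if either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx <= _variance_floor(x) or sy <= _variance_floor(y):
        return float("nan")
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def _variance_floor(v: np.ndarray, w: np.ndarray | None = None) -> float:
    # constant vectors can acquire O(eps) spread through the mean subtraction;
    # anything at rounding scale counts as zero variance
    n = v.size if w is None else float(np.sum(w))
    return 1e-10 * np.sqrt(n) * max(1.0, float(np.max(np.abs(v))))


def weighted_pearson_r(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Pearson r with non-negative case weights (kernel multiplicities)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    wsum = w.sum()
    mx = np.sum(w * x) / wsum
    my = np.sum(w * y) / wsum
    cov = np.sum(w * (x - mx) * (y - my))
    sx = np.sqrt(np.sum(w * (x - mx) ** 2))
    sy = np.sqrt(np.sum(w * (y - my) ** 2))
    if sx <= _variance_floor(x, w) or sy <= _variance_floor(y, w):
        return float("nan")
    return float(np.clip(cov / (sx * sy), -1.0, 1.0))


@dataclass
class KernelDiversity:
    """Per-locus and mean diversity for one kernel."""

    kernel: Kernel
    h_by_locus: np.ndarray  # NaN where undefined (n_copies < 2)
    h_mean: float  # NaN when every locus is undefined


# ---------------------------------------------------------------------------
# Vectorised machinery: one-hot allele encoding shared by the permutation
# loop, which must recompute kernel diversities hundreds of thousands of
# times without re-walking the table.
# ---------------------------------------------------------------------------


@dataclass
class AlleleOneHot:
    """One-hot allele-copy encoding of a table's genotypes.

    ``x`` has one row per sample and one column per (locus, allele) pair; a
    call contributes 1 to its allele column (P copy columns collapse onto the
    same allele columns). Missing calls contribute nothing. ``locus_slices``
    delimits each locus's columns.
    """

    x: np.ndarray
    locus_slices: list[slice]

    @classmethod
    def from_table(cls, table: SampleTable) -> "AlleleOneHot":
        codes, labels = table.allele_codes()
        p = table.copies_per_sample
        n = table.n_samples
        sizes = [max(len(lab), 1) for lab in labels]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        x = np.zeros((n, int(offsets[-1])))
        for l in range(table.n_loci):
            for j in range(p):
                col = codes[:, l * p + j]
                ok = col >= 0
                x[np.where(ok)[0], offsets[l] + col[ok]] += 1.0
        slices = [slice(int(offsets[l]), int(offsets[l + 1])) for l in range(table.n_loci)]
        return cls(x, slices)

    def kernel_h(self, membership: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus h and across-locus mean for each kernel row of
        ``membership`` (kernels × samples 0/1), given the current row order
        of ``x``. Returns ``(h_by_locus, h_mean)``."""
        counts = membership @ self.x  # kernels × allele columns
        n_k = len(membership)
        h = np.full((n_k, len(self.locus_slices)), np.nan)
        for l, sl in enumerate(self.locus_slices):
            c = counts[:, sl]
            n = c.sum(axis=1)
            ok = n >= 2
            if np.any(ok):
                ssq = np.sum(c[ok] ** 2, axis=1)
                nn = n[ok]
                h[ok, l] = nn / (nn - 1.0) * (1.0 - ssq / nn**2)
        with np.errstate(invalid="ignore"):
            h_mean = np.nanmean(h, axis=1)
        return h, h_mean


def kernel_diversity(kernel: Kernel, table: SampleTable) -> KernelDiversity:
    """Diversity of one kernel: per-locus unbiased h over the member samples'
    allele calls (missing calls excluded per locus), and the mean over loci
    with a defined value."""
    onehot = AlleleOneHot.from_table(table)
    membership = np.zeros((1, table.n_samples))
    membership[0, list(kernel.member_idx)] = 1.0
    h, h_mean = onehot.kernel_h(membership)
    return KernelDiversity(kernel, h[0], float(h_mean[0]))


def kernel_set_diversity(kernel_set: KernelSet, table: SampleTable | None = None) -> list[KernelDiversity]:
    """Diversities for every kernel in a set (one shared encoding pass)."""
    table = table if table is not None else kernel_set.table
    if table is None:
        raise ValueError("kernel set carries no table; pass one explicitly")
    onehot = AlleleOneHot.from_table(table)
    membership = kernel_set.membership_matrix(table.n_samples)
    h, h_mean = onehot.kernel_h(membership)
    return [
        KernelDiversity(k, h[i], float(h_mean[i])) for i, k in enumerate(kernel_set.kernels)
    ]
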