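"""Map rendering on plain equirectangular axes.

Figures are drawn with matplotlib on lat/lon axes (no projection machinery:
computation upstream is spherical already, and at the scales drawn here an
equirectangular display is the conventional choice). All renderers are
deterministic given fixed inputs and style arguments.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .geo import GeoPoint
from .io import MISSING, SampleTable
from .origin import OriginSurface, interpolate_surface


def _base_axes(ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 5))
    ax.set_xlabel("longitude (°E)")
    ax.set_ylabel("latitude (°N)")
    ax.set_aspect("equal", adjustable="datalim")
    return ax


def _sample_points(ax, table: SampleTable, **kw) -> int:
    """Scatter geolocated samples; returns the number skipped."""
    coords = table.coords()
    ok = ~np.isnan(coords).any(axis=1)
    kw.setdefault("s", 12)
    kw.setdefault("color", "forestgreen")
    kw.setdefault("zorder", 3)
    ax.scatter(coords[ok, 1], coords[ok, 0], **kw)
    return int((~ok).sum())


def render_surface_map(
    surface: OriginSurface,
    table: SampleTable | None = None,
    sites: Mapping[str, GeoPoint] | None = None,
    upsample: int = 4,
    path=None,
    ax=None,
):
    """Candidate-origin correlation surface: red = negative r (more plausible
    origin), blue = positive, with sample dots and starred candidate sites."""
    ax = _base_axes(ax)
    lats, lons, vals = interpolate_surface(surface, upsample)
    vmax = float(np.nanmax(np.abs(vals))) or 1.0
    mesh = ax.pcolormesh(
        lons, lats, vals, cmap="RdBu", vmin=-vmax, vmax=vmax, shading="nearest"
    )
    plt.colorbar(mesh, ax=ax, label="Pearson r (distance vs diversity)")
    skipped = 0
    if table is not None:
        skipped = _sample_points(ax, table)
        if skipped:
            ax.set_title(f"{skipped} sample(s) without coordinates not shown")
    for i, (name, pt) in enumerate(sorted((sites or {}).items())):
        ax.plot(pt.longitude, pt.latitude, marker="*", ms=16, mec="black", mfc="white", zorder=4)
        ax.annotate(f"{i + 1}", (pt.longitude, pt.latitude), textcoords="offset points",
                    xytext=(6, 6), fontsize=9)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def render_pie_map(
    table: SampleTable,
    memberships: np.ndarray,
    colors: Sequence[str] | None = None,
    pie_radius_deg: float = 0.4,
    path=None,
    ax=None,
):
    """Per-sample ancestry pies: ``memberships`` is samples × K, rows summing
    to 1; each sample is drawn as a pie at its location."""
    memberships = np.asarray(memberships, dtype=float)
    if memberships.shape[0] != table.n_samples:
        raise ValueError("memberships rows must match sample count")
    ax = _base_axes(ax)
    k = memberships.shape[1]
    colors = list(colors) if colors else [plt.get_cmap("tab10")(i % 10) for i in range(k)]
    coords = table.coords()
    skipped = 0
    for row, (lat, lon) in zip(memberships, coords):
        if np.isnan(lat) or np.isnan(lon):
            skipped += 1
            continue
        start = 0.0
        for frac, col in zip(row, colors):
            if frac <= 0:
                continue
            wedge = matplotlib.patches.Wedge(
                (lon, lat), pie_radius_deg, 360 * start, 360 * (start + frac),
                facecolor=col, edgecolor="black", linewidth=0.2,
            )
            ax.add_patch(wedge)
            start += frac
    ax.autoscale_view()
    if skipped:
        ax.set_title(f"{skipped} sample(s) without coordinates not shown")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


GBSSI_S_COLORS = {"S0/S0": "green", "S0/S-15": "cyan", "S-15/S-15": "darkblue"}
GBSSI_L_COLORS = {
    "LC/LC": "red", "LY/LY": "darkblue", "Lf/Lf": "gold",
    "LC/LY": "cyan", "LC/Lf": "orange", "LY/Lf": "green",
}


def render_gbssi_map(table: SampleTable, locus: str = "gbssi_s", path=None, ax=None):
    """Samples coloured by GBSSI genotype at the chosen locus."""
    if locus not in ("gbssi_s", "gbssi_l"):
        raise ValueError("locus must be 'gbssi_s' or 'gbssi_l'")
    if locus not in table.df.columns:
        raise ValueError(f"table has no {locus} column")
    palette = GBSSI_S_COLORS if locus == "gbssi_s" else GBSSI_L_COLORS
    ax = _base_axes(ax)
    coords = table.coords()
    skipped = 0
    for geno, color in palette.items():
        sel = (table.df[locus] == geno).to_numpy() & ~np.isnan(coords).any(axis=1)
        if sel.any():
            ax.scatter(coords[sel, 1], coords[sel, 0], s=14, color=color, label=geno, zorder=3)
    skipped = int((np.isnan(coords).any(axis=1) | (table.df[locus] == MISSING)).sum())
    if skipped:
        ax.set_title(f"{skipped} sample(s) missing coordinates or genotype not shown")
    ax.legend(fontsize=7, loc="best")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
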