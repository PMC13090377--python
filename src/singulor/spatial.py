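"""Spatial analyses for imaging-based (MERFISH-style) cell tables.

Cells arrive as a segmented cell-by-gene count matrix with x/y centroids
in µm.  Cells with fewer than 12 detected transcripts are removed, the
remainder are projected onto a user-supplied epithelial axis polyline and
assigned to 50 equal-arc-length bins, from which cell-type occupancy and
gene-expression profiles are computed.  A 2-D OR transcript density map
and a per-type count of strongly dominant cells (dominance score above a
threshold, default 3) summarize receptor expression in space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CountMatrix, NormalizedMatrix

__all__ = [
    "DensityMap",
    "filter_low_count_cells",
    "project_to_axis",
    "bin_axis",
    "cell_type_bin_matrix",
    "gene_bin_profile",
    "or_density_map",
    "spatial_high_dominance_summary",
]


@dataclass
class DensityMap:
    grid: np.ndarray  # 2-D, summed OR transcripts per pixel
    x_edges: np.ndarray
    y_edges: np.ndarray
    pixel_size: float
    bandwidth: float | None


def filter_low_count_cells(
    cm: CountMatrix, min_transcripts: int = 12
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove cells with fewer than ``min_transcripts`` total transcripts.

    The boundary is inclusive on the keep side: a 12-transcript cell stays.
    Returns the filtered matrix and a per-cell report (total, kept).
    """
    totals = cm.cell_totals()
    kept = totals >= min_transcripts
    report = pd.DataFrame({"cell_id": cm.cell_ids, "total_transcripts": totals, "kept": kept})
    return cm.subset_cells(kept), report


def project_to_axis(positions: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Normalized arc length s in [0, 1] of each cell's nearest axis point.

    ``polyline`` is an ordered (m, 2) array of vertices in µm.  Each
    position is projected onto every segment; the closest foot wins, ties
    going to the lower-s segment.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
        raise ValueError("polyline must be an (m, 2) array with m >= 2")
    seg = np.diff(poly, axis=0)  # (m-1, 2)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total == 0:
        raise ValueError("degenerate polyline with zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    # (n, m-1) projections of each point on each segment
    rel = positions[:, None, :] - poly[None, :-1, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(
            seg_len[None, :] > 0,
            (rel * seg[None, :, :]).sum(-1) / (seg_len[None, :] ** 2),
            0.0,
        )
    t = np.clip(t, 0.0, 1.0)
    feet = poly[None, :-1, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((positions[:, None, :] - feet) ** 2).sum(-1)
    best = np.argmin(d2, axis=1)  # argmin takes the first (lower-s) tie
    rows = np.arange(len(positions))
    arc = cum[best] + t[rows, best] * seg_len[best]
    return arc / total


def bin_axis(s: np.ndarray, n_bins: int = 50) -> np.ndarray:
    """1-based equal-width bin index over [0, 1]; the last bin is closed."""
    s = np.asarray(s, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if np.any((s < 0) | (s > 1)) or np.any(np.isnan(s)):
        raise ValueError("axis coordinates must lie in [0, 1]")
    idx = np.floor(s * n_bins).astype(int)
    idx[idx == n_bins] = n_bins - 1  # s == 1.0 joins the last bin
    return idx + 1


def cell_type_bin_matrix(
    bin_indices: np.ndarray,
    cell_types: np.ndarray,
    n_bins: int = 50,
    row_scale: bool = True,
    scale: str = "max",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Cell-type occupancy per bin: raw counts and an optional scaled copy.

    Rows are cell types, columns bins 1..n_bins.  ``scale="max"`` divides
    each row by its maximum (all-zero rows stay zero); ``scale="z"``
    z-scores each row instead.
    """
    bin_indices = np.asarray(bin_indices)
    cell_types = np.asarray(cell_types, dtype=object)
    types = sorted(set(cell_types))
    raw = pd.DataFrame(0, index=types, columns=range(1, n_bins + 1), dtype=int)
    for t in types:
        idx, counts = np.unique(bin_indices[cell_types == t], return_counts=True)
        raw.loc[t, idx] = counts
    if not row_scale:
        return raw, None
    if scale == "max":
        m = raw.max(axis=1).replace(0, 1)
        scaled = raw.div(m, axis=0).astype(float)
    elif scale == "z":
        mu = raw.mean(axis=1)
        sd = raw.std(axis=1).replace(0, 1)
        scaled = raw.sub(mu, axis=0).div(sd, axis=0)
    else:
        raise ValueError("scale must be 'max' or 'z'")
    return raw, scaled


def gene_bin_profile(
    norm: NormalizedMatrix,
    bin_indices: np.ndarray,
    gene_ids: list[str],
    n_bins: int = 50,
) -> pd.DataFrame:
    """Mean expression per bin for each requested gene (genes x bins).

    Bins containing no cells yield NaN rather than zero so that empty
    territory is distinguishable from silent territory.
    """
    cols = norm.gene_index(gene_ids)
    bin_indices = np.asarray(bin_indices)
    out = pd.DataFrame(np.nan, index=list(gene_ids), columns=range(1, n_bins + 1))
    sub = np.asarray(norm.values[:, cols].todense())
    for b in range(1, n_bins + 1):
        mask = bin_indices == b
        if mask.any():
            out[b] = np.asarray(sub[mask].mean(axis=0)).ravel()
    return out


def or_density_map(
    positions: np.ndarray,
    or_totals: np.ndarray,
    pixel_size: float,
    bandwidth: float | None = None,
) -> DensityMap:
    """2-D histogram of summed OR transcripts, optionally Gaussian-smoothed.

    ``bandwidth`` is the Gaussian sigma in µm.  The unsmoothed grid
    conserves the total OR transcript count exactly; smoothing conserves it
    up to boundary truncation.
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    or_totals = np.asarray(or_totals, dtype=float)
    x, y = positions[:, 0], positions[:, 1]
    x_edges = np.arange(x.min(), x.max() + 2 * pixel_size, pixel_size)
    y_edges = np.arange(y.min(), y.max() + 2 * pixel_size, pixel_size)
    grid, x_edges, y_edges = np.histogram2d(x, y, bins=[x_edges, y_edges], weights=or_totals)
    if bandwidth is not None:
        grid = ndimage.gaussian_filter(grid, sigma=bandwidth / pixel_size, mode="constant")
    return DensityMap(grid, x_edges, y_edges, pixel_size, bandwidth)


def spatial_high_dominance_summary(
    summary: pd.DataFrame,
    cell_types: np.ndarray,
    domain_mask: np.ndarray | None = None,
    threshold: float = 3.0,
) -> pd.Series:
    """Cells with dominance score strictly above ``threshold``, per type.

    ``summary`` is a per-cell dominance table aligned with ``cell_types``;
    ``domain_mask`` restricts the count to cells inside a spatial domain
    (e.g. the olfactory + respiratory epithelium).
    """
    d = summary["dominance_score"].to_numpy()
    cell_types = np.asarray(cell_types, dtype=object)
    if len(d) != len(cell_types):
        raise ValueError("summary and cell_types length mismatch")
    mask = d > threshold
    if domain_mask is not None:
        mask &= np.asarray(domain_mask, dtype=bool)
    types = sorted(set(cell_types))
    out = pd.Series(0, index=types, dtype=int, name="n_high_dominance")
    for t in types:
        out[t] = int((mask & (cell_types == t)).sum())
    return out
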