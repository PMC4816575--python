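"""Global spatial autocorrelation: Moran's I, Geary's C, correlograms.

Moran's I ranges roughly [-1, 1] with null expectation -1/(N-1); Geary's
C has null expectation 1, values below 1 indicating positive
autocorrelation.  Model predictions on interpolated climate surfaces
inherit the surfaces' smoothness, so comparing I/C between candidate
models diagnoses artificially inflated spatial structure.

Weights are explicit: binary rook/queen contiguity on a grid, or a
great-circle distance band between sites.  Correlograms evaluate Moran's
I per distance bin with binary membership weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GeoGrid
from .validation import haversine_km


@dataclass
class SpatialWeights:
    """Sparse symmetric weights as directed pair lists (both directions)."""

    i: np.ndarray
    j: np.ndarray
    w: np.ndarray
    style: str = "custom"
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, int)
        self.j = np.asarray(self.j, int)
        self.w = np.asarray(self.w, float)
        if np.any(self.i == self.j):
            raise ValueError("self-weights w_ii are not allowed")
        if self.w.size == 0 or not np.any(self.w != 0):
            raise ValueError("at least one nonzero weight required")
        if self.n_sites == 0:
            self.n_sites = int(max(self.i.max(), self.j.max())) + 1

    @property
    def total(self) -> float:
        return float(self.w.sum())


def grid_contiguity(grid_or_mask, style: str = "queen") -> tuple[SpatialWeights, np.ndarray]:
    """Binary contiguity weights over the unmasked cells of a grid.

    Returns ``(weights, site_index)`` where site_index maps each unmasked
    cell (row-major order) to its (row, col).
    """
    mask = (grid_or_mask.mask if isinstance(grid_or_mask, GeoGrid)
            else np.asarray(grid_or_mask, bool))
    nr, nc = mask.shape
    idx = -np.ones(mask.shape, dtype=int)
    sites = np.argwhere(~mask)
    idx[~mask] = np.arange(len(sites))
    if style == "rook":
        offsets = [(0, 1), (1, 0)]
    elif style == "queen":
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
    else:
        raise ValueError(f"unknown contiguity style {style!r}")
    ii, jj = [], []
    for dr, dc in offsets:
        r, c = sites[:, 0] + dr, sites[:, 1] + dc
        ok = (r >= 0) & (r < nr) & (c >= 0) & (c < nc)
        ok[ok] &= ~mask[r[ok], c[ok]]
        a = idx[sites[ok, 0], sites[ok, 1]]
        b = idx[r[ok], c[ok]]
        ii.extend([a, b])
        jj.extend([b, a])
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    return (SpatialWeights(i=i, j=j, w=np.ones(len(i)),
                           style=f"binary_{style}", n_sites=len(sites)),
            sites)


def distance_band_weights(lon: np.ndarray, lat: np.ndarray,
                          d_lo: float, d_hi: float) -> SpatialWeights:
    """Binary weights linking site pairs whose great-circle distance lies
    in (d_lo, d_hi] km."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    n = len(lon)
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    sel = (d > d_lo) & (d <= d_hi)
    np.fill_diagonal(sel, False)
    i, j = np.nonzero(sel)
    return SpatialWeights(i=i, j=j, w=np.ones(len(i)),
                          style=f"distance_band({d_lo},{d_hi}]", n_sites=n)


def morans_i(values: np.ndarray, weights: SpatialWeights) -> float:
    """Moran's I = (N / sum w) * sum_ij w_ij (x_i - xbar)(x_j - xbar)
    / sum_i (x_i - xbar)^2.  NaN (with a warning) for constant values."""
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("need at least 3 sites")
    dev = x - x.mean()
    denom = np.sum(dev**2)
    if denom == 0:
        warnings.warn("zero variance: Moran's I undefined")
        return np.nan
    num = np.sum(weights.w * dev[weights.i] * dev[weights.j])
    return float(len(x) / weights.total * num / denom)


def gearys_c(values: np.ndarray, weights: SpatialWeights) -> float:
    """Geary's C = ((N-1) / (2 sum w)) * sum_ij w_ij (x_i - x_j)^2
    / sum_i (x_i - xbar)^2."""
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("need at least 3 sites")
    dev = x - x.mean()
    denom = np.sum(dev**2)
    if denom == 0:
        warnings.warn("zero variance: Geary's C undefined")
        return np.nan
    num = np.sum(weights.w * (x[weights.i] - x[weights.j]) ** 2)
    return float((len(x) - 1) / (2.0 * weights.total) * num / denom)


@dataclass
class Correlogram:
    bin_edges: np.ndarray
    morans_i: np.ndarray
    n_pairs: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_lo": self.bin_edges[:-1],
                             "bin_hi": self.bin_edges[1:],
                             "I": self.morans_i, "n_pairs": self.n_pairs})


def correlogram(values: np.ndarray, lon: np.ndarray, lat: np.ndarray,
                bin_edges: np.ndarray | None = None,
                n_bins: int = 10) -> Correlogram:
    """Moran's I per great-circle distance bin (binary membership weights).

    Default bins: *n_bins* equal-width bins from 0 up to half the maximum
    pairwise distance.  Empty bins report NaN with pair count 0.
    """
    values = np.asarray(values, float)
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    if bin_edges is None:
        bin_edges = np.linspace(0.0, d.max() / 2.0, n_bins + 1)
    bin_edges = np.asarray(bin_edges, float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    I_vals = np.full(len(bin_edges) - 1, np.nan)
    n_pairs = np.zeros(len(bin_edges) - 1, dtype=int)
    for b in range(len(bin_edges) - 1):
        sel = (d > bin_edges[b]) & (d <= bin_edges[b + 1])
        np.fill_diagonal(sel, False)
        i, j = np.nonzero(sel)
        n_pairs[b] = len(i) // 2
        if len(i) == 0:
            continue
        w = SpatialWeights(i=i, j=j, w=np.ones(len(i)),
                           style="correlogram_bin", n_sites=len(values))
        I_vals[b] = morans_i(values, w)
    return Correlogram(bin_edges=bin_edges, morans_i=I_vals, n_pairs=n_pairs)
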