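"""Circular moving-window (focal) statistics on masked grids.

Used for the spatial-variability layer: the standard deviation of mean
annual cloud frequency within a circular window (the product's map uses a
one-degree, ~110 km window; on abstract grids the window is a radius in
cells with no great-circle correction).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import GeoGrid


def circular_kernel(radius_cells: float) -> np.ndarray:
    """Boolean disc: cells whose centre lies within *radius_cells* of the
    window centre.  radius 1 gives the 5-cell plus kernel."""
    if radius_cells < 1:
        raise ValueError("radius must be >= 1 cell")
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy**2 + xx**2) <= radius_cells**2


def circular_window_stat(
    grid: GeoGrid,
    radius_cells: float,
    stat: str = "sd",
    sample_sd: bool = False,
) -> GeoGrid:
    """Focal mean or SD over a circular window, ignoring masked cells.

    Output is masked where the centre cell is masked; the SD additionally
    requires at least two contributing cells.  ``sample_sd`` switches from
    the population (n) to the sample (n-1) denominator.
    """
    if stat not in ("sd", "mean"):
        raise ValueError(f"unknown stat {stat!r}")
    kernel = circular_kernel(radius_cells)
    if kernel.shape[0] > min(grid.shape):
        raise ValueError("window radius larger than grid")
    kernel = kernel.astype(float)

    valid = (~grid.mask).astype(float)
    vals = np.where(grid.mask, 0.0, grid.values)

    conv = lambda a: ndimage.convolve(a, kernel, mode="constant", cval=0.0)
    n = conv(valid)
    s1 = conv(vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        if stat == "mean":
            out = mean
            out_mask = grid.mask | (n < 1)
        else:
            s2 = conv(vals**2)
            var = s2 / n - mean**2
            var = np.maximum(var, 0.0)  # guard tiny negative round-off
            if sample_sd:
                var = var * n / np.maximum(n - 1, 1)
            out = np.sqrt(var)
            out_mask = grid.mask | (n < 2)
    out = np.where(out_mask, np.nan, out)
    return grid.copy_with(values=out, mask=out_mask)
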