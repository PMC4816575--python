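"""Zonal statistics: summarize a metric raster within labelled zones.

Mirrors the biome-summary table of the cloud product (columns icode, n,
min, max, mean, sd, plus optional descriptive columns).  Statistics are
unweighted cell statistics over unmasked metric cells; the cell count is
always reported so readers can judge support.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import GeoGrid


def zonal_stats(metric: GeoGrid, zones: GeoGrid, sample_sd: bool = True) -> pd.DataFrame:
    """One row per zone label present in *zones*.

    ``n`` counts unmasked metric cells in the zone; zones whose metric
    cells are all masked get ``n = 0`` and NaN statistics.
    """
    if not metric.same_geometry(zones):
        raise ValueError("metric and zones geometry mismatch")
    zvals = zones.values
    if not np.allclose(zvals[~zones.mask], np.round(zvals[~zones.mask])):
        raise ValueError("zone labels must be integers")

    rows = []
    labels = np.unique(zvals[~zones.mask]).astype(int)
    ddof = 1 if sample_sd else 0
    for lab in labels:
        in_zone = (~zones.mask) & (zvals == lab)
        vals = metric.values[in_zone & ~metric.mask]
        n = vals.size
        if n == 0:
            rows.append({"icode": lab, "n": 0, "min": np.nan, "max": np.nan,
                         "mean": np.nan, "sd": np.nan})
            continue
        sd = np.std(vals, ddof=ddof) if n > ddof else (0.0 if ddof == 0 else np.nan)
        rows.append({
            "icode": lab, "n": int(n),
            "min": float(vals.min()), "max": float(vals.max()),
            "mean": float(vals.mean()), "sd": float(sd),
        })
    return pd.DataFrame(rows, columns=["icode", "n", "min", "max", "mean", "sd"])
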