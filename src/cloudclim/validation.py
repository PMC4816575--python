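"""Validation of gridded cloud climatologies against station records.

Ground observers report monthly mean "total cloud" amount — the fraction
of visible sky covered — which samples a much larger area than a 1 km
pixel.  The gridded climatology is therefore averaged over a circular
footprint (default 16 km radius, great-circle) around each station before
comparison.  Stations are filtered by observation counts (two archive
modes), compared by ordinary least squares per month and per three-month
season, and residuals are summarized by latitude band and by the modal
land-cover class within the footprint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .climatology import CloudClimatology
from .grid import GeoGrid

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

SEASONS = {"DJF": (12, 1, 2), "MAM": (3, 4, 5),
           "JJA": (6, 7, 8), "SON": (9, 10, 11)}


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (R = 6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class StationRecord:
    """Monthly station cloud amounts (% of sky) with observation counts.

    ``obs_count`` maps (month, year) to the number of observations that
    contributed to the monthly mean.
    """

    id: str
    lon: float
    lat: float
    monthly_cloud_amount: np.ndarray  # 12 values, %
    obs_count: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.monthly_cloud_amount = np.asarray(self.monthly_cloud_amount, float)
        if self.monthly_cloud_amount.shape != (12,):
            raise ValueError("12 monthly cloud amounts required")
        if np.nanmin(self.monthly_cloud_amount) < 0 or \
                np.nanmax(self.monthly_cloud_amount) > 100:
            raise ValueError("cloud amounts must be in [0, 100] percent")


def station_footprint_mean(grid: GeoGrid, lon: float, lat: float,
                           radius_km: float = 16.0) -> float:
    """Unweighted mean of unmasked cells whose centers lie within
    *radius_km* (great-circle) of the station; NaN if none do."""
    lons, lats = grid.cell_centers()
    # cheap bounding box before the trig
    dlat = np.degrees(radius_km / EARTH_RADIUS_KM) + 1e-9
    dlon = dlat / max(np.cos(np.radians(lat)), 1e-6)
    box = (np.abs(lats - lat) <= dlat) & (np.abs(lons - lon) <= dlon)
    if not box.any():
        return np.nan
    d = haversine_km(lons[box], lats[box], lon, lat)
    inside = d <= radius_km
    vals = grid.values[box][inside]
    mask = grid.mask[box][inside]
    vals = vals[~mask]
    if vals.size == 0:
        return np.nan
    return float(vals.mean())


# ---------------------------------------------------------------------
# archive filters
# ---------------------------------------------------------------------

def filter_stations(records: list[StationRecord], mode: str,
                    window_years: tuple[int, int] | None = None,
                    min_obs: int = 20, min_years: int = 20
                    ) -> list[StationRecord]:
    """Apply the archive's observation-count filters.

    ``modis_era``: keep stations with at least *min_obs* observations in
    every month of every year of *window_years* (inclusive).
    ``full_record``: keep stations with at least *min_years* qualifying
    years, where a year qualifies if all 12 months have >= *min_obs*.
    """
    if mode not in ("modis_era", "full_record"):
        raise ValueError(f"unknown filter mode {mode!r}")
    kept = []
    for rec in records:
        years = sorted({y for (_, y) in rec.obs_count})
        if mode == "modis_era":
            if window_years is not None:
                years = [y for y in years
                         if window_years[0] <= y <= window_years[1]]
            if not years:
                continue
            ok = all(rec.obs_count.get((m, y), 0) >= min_obs
                     for y in years for m in range(1, 13))
        else:
            qualifying = sum(
                all(rec.obs_count.get((m, y), 0) >= min_obs
                    for m in range(1, 13))
                for y in years)
            ok = qualifying >= min_years
        if ok:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------
# regression validation
# ---------------------------------------------------------------------

@dataclass
class ValidationResult:
    """Per-period regression diagnostics and per-station residuals."""

    table: pd.DataFrame      # period, n, r2, rmse, slope, intercept
    residuals: pd.DataFrame  # station, lon, lat, period, observed, predicted, residual
    radius_km: float


def _ols_row(period: str, x: np.ndarray, y: np.ndarray) -> dict | None:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        warnings.warn(f"{period}: fewer than 3 stations; period skipped")
        return None
    if np.ptp(x) == 0:
        warnings.warn(f"{period}: degenerate predictor; period skipped")
        return None
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    return {"period": period, "n": int(x.size), "r2": fit.rvalue**2,
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "slope": fit.slope, "intercept": fit.intercept}


def monthly_validation(stations: list[StationRecord],
                       clim: CloudClimatology,
                       radius_km: float = 16.0) -> ValidationResult:
    """OLS of station cloud amount on footprint-mean gridded CF, per month
    and per three-month season (DJF, MAM, JJA, SON).

    Stations whose footprint holds no unmasked cell are dropped with a log
    entry.  RMSE is the root mean squared residual of the fit.
    """
    sat = np.full((len(stations), 12), np.nan)
    obs = np.full((len(stations), 12), np.nan)
    meta = []
    for i, rec in enumerate(stations):
        fp = [station_footprint_mean(
                GeoGrid(clim.mu[m], transform=clim.transform, crs=clim.crs),
                rec.lon, rec.lat, radius_km)
              for m in range(12)]
        if np.all(np.isnan(fp)):
            logger.info("station %s dropped: empty footprint", rec.id)
            continue
        sat[i] = fp
        obs[i] = rec.monthly_cloud_amount
        meta.append((i, rec))

    rows, resid_rows = [], []
    periods = [(f"{m:02d}", [m]) for m in range(1, 13)]
    periods += [(name, list(months)) for name, months in SEASONS.items()]
    for period, months in periods:
        mi = [m - 1 for m in months]
        x = np.nanmean(sat[:, mi], axis=1)
        y = np.nanmean(obs[:, mi], axis=1)
        row = _ols_row(period, x, y)
        if row is None:
            continue
        rows.append(row)
        pred = row["intercept"] + row["slope"] * x
        for i, rec in meta:
            if np.isfinite(x[i]) and np.isfinite(y[i]):
                resid_rows.append({
                    "station": rec.id, "lon": rec.lon, "lat": rec.lat,
                    "period": period, "observed": y[i], "predicted": pred[i],
                    "residual": y[i] - pred[i]})
    return ValidationResult(table=pd.DataFrame(rows),
                            residuals=pd.DataFrame(resid_rows),
                            radius_km=radius_km)


# ---------------------------------------------------------------------
# residual summaries
# ---------------------------------------------------------------------

def modal_class_in_footprint(lulc: GeoGrid, lon: float, lat: float,
                             radius_km: float = 16.0) -> int | None:
    """Most frequent land-cover class within the footprint; ties break to
    the lower class id."""
    lons, lats = lulc.cell_centers()
    d = haversine_km(lons, lats, lon, lat)
    inside = (d <= radius_km) & ~lulc.mask
    if not inside.any():
        return None
    classes, counts = np.unique(lulc.values[inside].astype(int),
                                return_counts=True)
    return int(classes[np.argmax(counts)])  # argmax ties -> lower id


def residual_summary(result: ValidationResult,
                     latitude_bands: list[float] | None = None,
                     lulc: GeoGrid | None = None) -> dict[str, pd.DataFrame]:
    """Residual mean/SD/n by latitude band and (optionally) by the modal
    land-cover class within each station footprint."""
    res = result.residuals.copy()
    out: dict[str, pd.DataFrame] = {}
    if latitude_bands is not None:
        band = pd.cut(res["lat"], bins=latitude_bands)
        grp = res.groupby(band, observed=True)["residual"]
        out["latitude"] = grp.agg(mean="mean", sd="std", n="count").reset_index()
    if lulc is not None:
        uniq = res[["station", "lon", "lat"]].drop_duplicates("station")
        cls = {row.station: modal_class_in_footprint(
            lulc, row.lon, row.lat, result.radius_km)
            for row in uniq.itertuples()}
        res["lulc"] = res["station"].map(cls)
        grp = res.dropna(subset=["lulc"]).groupby("lulc")["residual"]
        out["lulc"] = grp.agg(mean="mean", sd="std", n="count").reset_index()
    return out


def rank_correlation(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
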