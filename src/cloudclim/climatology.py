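"""Monthly cloud-frequency climatologies and derived seasonal metrics.

The cloud frequency (CF) of a pixel-month is the percentage of valid
daily observations carrying a positive cloud flag.  Per-month CF series
across years are summarized into climatological means mu_m and
inter-annual SDs sigma_m, the two sensors are merged by equal-weight
averaging, and the merged climatology yields:

* mean annual CF         — mean of the available monthly means,
* intra-annual variability — SD of the monthly means (seasonality),
* inter-annual variability — mean of the monthly SDs (stability),
* spatial variability    — focal SD of mean annual CF in a circular window,
* seasonal concentration — polar-vector summary of the monthly means: with
  month angles phi_m = 2*pi*(m-1)/12 and vector sum S = sum(mu_m * e^{i phi_m}),
  the index is 100*|S|/sum(mu_m), ranging 0 (aseasonal) to 100 (all cloud
  in one month), and the direction of S gives the peak month.

All SDs here use the sample (n-1) denominator.  Cells missing months
(e.g. polar winter darkness) are summarized over available months, with
the month count published alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .focal import circular_window_stat
from .grid import GeoGrid, GridStack, GridTransform, MONTH_LABELS
from .synthetic import DailyFlags
from .zonal import zonal_stats


# ---------------------------------------------------------------------
# monthly frequencies
# ---------------------------------------------------------------------

def monthly_frequency(flags: np.ndarray, valid: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """CF (%) and valid-observation count from one month of daily flags.

    *flags* and *valid* are (n_days, rows, cols) boolean; cells with zero
    valid observations come back NaN.
    """
    flags = np.asarray(flags, bool)
    valid = np.asarray(valid, bool)
    if flags.shape != valid.shape:
        raise ValueError("flags and valid masks must share shape")
    n = valid.sum(axis=0)
    pos = (flags & valid).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cf = 100.0 * pos / n
    cf = np.where(n > 0, cf, np.nan)
    return cf, n


@dataclass
class MonthlyCF:
    """Per-sensor monthly cloud frequencies CF[y, m] with valid counts."""

    sensor: str
    cf: np.ndarray       # (n_years, 12, rows, cols), % with NaN = masked
    valid_n: np.ndarray  # same shape, int
    years: list[int]
    transform: GridTransform
    crs: str = "EPSG:4326"


def monthly_cf_series(daily: DailyFlags) -> MonthlyCF:
    """Aggregate a daily flag stack into the (year, month) CF series."""
    years = sorted({d[0] for d in daily.dates})
    nr, nc = daily.flags.shape[1:]
    cf = np.full((len(years), 12, nr, nc), np.nan)
    vn = np.zeros((len(years), 12, nr, nc), dtype=int)
    dates = np.array(daily.dates)
    for yi, year in enumerate(years):
        for m in range(1, 13):
            sel = (dates[:, 0] == year) & (dates[:, 1] == m)
            if not sel.any():
                continue
            cf[yi, m - 1], vn[yi, m - 1] = monthly_frequency(
                daily.flags[sel], daily.valid[sel])
    return MonthlyCF(sensor=daily.sensor, cf=cf, valid_n=vn, years=years,
                     transform=daily.transform, crs=daily.crs)


def climatological_stats(monthly: MonthlyCF) -> tuple[np.ndarray, np.ndarray]:
    """Climatological mean mu_m and inter-annual sample SD sigma_m.

    Both are (12, rows, cols); sigma is NaN where fewer than two years
    contribute.
    """
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(monthly.cf, axis=0)
        n_years = np.sum(~np.isnan(monthly.cf), axis=0)
        sigma = np.full_like(mu, np.nan)
        enough = n_years >= 2
        sigma_all = np.nanstd(monthly.cf, axis=0, ddof=1)
        sigma[enough] = sigma_all[enough]
    return mu, sigma


def merge_sensors(per_sensor: list[np.ndarray]) -> np.ndarray:
    """Equal-weight mean across sensors, falling back to whichever sensor
    is valid where the other is masked; NaN where none is."""
    stack = np.stack(per_sensor)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack, axis=0)


# ---------------------------------------------------------------------
# seasonal concentration
# ---------------------------------------------------------------------

_MONTH_ANGLES = 2.0 * np.pi * np.arange(12) / 12.0


def seasonal_concentration(mu: np.ndarray, min_months: int = 2
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Seasonal concentration index (0-100) and peak month (1-12).

    Treats the 12 monthly means as polar vectors (magnitude mu_m, direction
    the month angle) and sums them; the index is the resultant magnitude
    normalized by total annual cloudiness and scaled to 100, so equal
    monthly cloudiness scores 0 and a single cloudy month scores 100.
    NaN months are skipped; cells with fewer than *min_months* months or
    zero annual total are NaN.  The peak month is the month angularly
    closest to the resultant (ties to the earlier calendar month); it is
    NaN where the resultant vanishes (no preferred season).
    """
    mu = np.asarray(mu, float)
    scalar_input = mu.ndim == 1
    if scalar_input:
        mu = mu[:, None, None]
    if mu.shape[0] != 12:
        raise ValueError("expected 12 monthly layers")
    avail = ~np.isnan(mu)
    n_months = avail.sum(axis=0)
    w = np.where(avail, mu, 0.0)
    cx = np.tensordot(np.cos(_MONTH_ANGLES), w, axes=1)
    sy = np.tensordot(np.sin(_MONTH_ANGLES), w, axes=1)
    total = w.sum(axis=0)
    mag = np.hypot(cx, sy)
    bad = (n_months < min_months) | (total <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where(bad, np.nan, 100.0 * mag / total)

    ang = np.mod(np.arctan2(sy, cx), 2.0 * np.pi)
    # angular distance from the resultant to each month's direction
    d = np.abs(np.mod(_MONTH_ANGLES[:, None, None] - ang[None], 2 * np.pi))
    d = np.minimum(d, 2 * np.pi - d)
    peak = np.argmin(d, axis=0) + 1.0  # argmin ties -> earlier month
    no_direction = bad | (mag <= 1e-9 * np.maximum(total, 1e-30))
    peak = np.where(no_direction, np.nan, peak)
    if scalar_input:
        return float(index[0, 0]), (float(peak[0, 0]) if np.isfinite(peak[0, 0])
                                    else np.nan)
    return index, peak


# ---------------------------------------------------------------------
# full climatology with derived metrics
# ---------------------------------------------------------------------

@dataclass
class CloudClimatology:
    """Merged monthly climatology plus every derived seasonal metric.

    All frequencies are percent (0-100); NaN marks masked cells.
    """

    mu: np.ndarray       # (12, rows, cols)
    sigma: np.ndarray    # (12, rows, cols)
    mean_annual: np.ndarray
    intra_annual: np.ndarray
    inter_annual: np.ndarray
    spatial_var: np.ndarray
    concentration: np.ndarray
    peak_month: np.ndarray
    months_available: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"

    def grid(self, name: str) -> GeoGrid:
        arr = getattr(self, name)
        return GeoGrid(arr, transform=self.transform, crs=self.crs)

    def mu_stack(self) -> GridStack:
        return GridStack.from_array(self.mu, MONTH_LABELS,
                                    transform=self.transform, crs=self.crs)


def derived_metrics(mu: np.ndarray, sigma: np.ndarray,
                    transform: GridTransform, crs: str = "EPSG:4326",
                    window_radius: float | None = 5.0) -> CloudClimatology:
    """Fill every derived metric from merged mu/sigma layers.

    mean annual = mean of available mu_m; intra-annual = sample SD of the
    available mu_m (NaN with <2 months); inter-annual = mean of available
    sigma_m; spatial variability = focal SD of mean annual within a
    circular window of *window_radius* cells (skipped, all-NaN, when
    *window_radius* is None or the window does not fit the grid).
    """
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    n_months = np.sum(~np.isnan(mu), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_annual = np.where(n_months > 0, np.nanmean(mu, axis=0), np.nan)
        intra = np.full(mean_annual.shape, np.nan)
        enough = n_months >= 2
        intra_all = np.nanstd(mu, axis=0, ddof=1)
        intra[enough] = intra_all[enough]
        inter = np.where(np.sum(~np.isnan(sigma), axis=0) > 0,
                         np.nanmean(sigma, axis=0), np.nan)
    if (window_radius is not None
            and 2 * int(np.floor(window_radius)) + 1 <= min(mean_annual.shape)):
        ma_grid = GeoGrid(mean_annual, transform=transform, crs=crs)
        spatial_vals = circular_window_stat(
            ma_grid, window_radius, stat="sd", sample_sd=True).filled()
    else:
        spatial_vals = np.full(mean_annual.shape, np.nan)
    conc, peak = seasonal_concentration(mu)
    return CloudClimatology(
        mu=mu, sigma=sigma, mean_annual=mean_annual, intra_annual=intra,
        inter_annual=inter, spatial_var=spatial_vals,
        concentration=conc, peak_month=peak, months_available=n_months,
        transform=transform, crs=crs)


def build_climatology(stacks: dict[str, DailyFlags],
                      window_radius: float = 5.0) -> CloudClimatology:
    """End-to-end: daily flags per sensor -> merged climatology + metrics."""
    mus, sigmas = [], []
    first = next(iter(stacks.values()))
    for daily in stacks.values():
        series = monthly_cf_series(daily)
        mu, sigma = climatological_stats(series)
        mus.append(mu)
        sigmas.append(sigma)
    mu = merge_sensors(mus)
    sigma = merge_sensors(sigmas)
    return derived_metrics(mu, sigma, first.transform, first.crs,
                           window_radius=window_radius)


# ---------------------------------------------------------------------
# stability hotspots
# ---------------------------------------------------------------------

HOTSPOT_CLASSES = {0: "none", 1: "intra_stable", 2: "inter_stable", 3: "both"}


@dataclass
class HotspotMap:
    classes: GeoGrid  # values per HOTSPOT_CLASSES; NaN outside top decile
    thresholds: dict


def hotspot_classification(clim: CloudClimatology, q_top: float = 0.90,
                           q_bottom: float = 0.10) -> HotspotMap:
    """Classify cloud-stability hotspots.

    Cells in the top decile of mean annual CF are labelled by whether they
    also fall in the bottom decile of intra-annual variability, of
    inter-annual variability, of both, or of neither.  Quantiles are
    global over unmasked cells and demand strictly varying inputs.
    """
    ma, intra, inter = clim.mean_annual, clim.intra_annual, clim.inter_annual
    for name, arr in (("mean_annual", ma), ("intra_annual", intra),
                      ("inter_annual", inter)):
        vals = arr[np.isfinite(arr)]
        if vals.size == 0 or vals.min() == vals.max():
            raise ValueError(f"{name} is constant or empty; "
                             "hotspot deciles undefined")
    t_ma = np.nanquantile(ma, q_top)
    t_intra = np.nanquantile(intra, q_bottom)
    t_inter = np.nanquantile(inter, q_bottom)
    top = np.isfinite(ma) & (ma >= t_ma)
    lo_intra = np.isfinite(intra) & (intra <= t_intra)
    lo_inter = np.isfinite(inter) & (inter <= t_inter)
    cls = np.where(top, 0.0, np.nan)
    cls[top & lo_intra & ~lo_inter] = 1
    cls[top & lo_inter & ~lo_intra] = 2
    cls[top & lo_intra & lo_inter] = 3
    grid = GeoGrid(cls, transform=clim.transform, crs=clim.crs)
    return HotspotMap(classes=grid, thresholds={
        "mean_annual_top": float(t_ma),
        "intra_annual_bottom": float(t_intra),
        "inter_annual_bottom": float(t_inter)})


def biome_summary(metric: GeoGrid, biomes: GeoGrid, product: str = "",
                  names: dict[int, str] | None = None):
    """Zonal biome table in the product's summary schema."""
    table = zonal_stats(metric, biomes)
    table["product"] = product
    if names:
        table["biome"] = table["icode"].map(names)
    return table
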