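"""Synthetic inputs with known ground truth for every pipeline stage.

The real product is built from ~15 years of twice-daily satellite cloud
flags, validated against a global synoptic station archive, and feeds a
presence-only cloud-forest model and a zero-inflated binomial occupancy
model.  This module emulates each of those inputs as draws from simple,
fully specified laws — Bernoulli daily flags over smooth monthly
probability surfaces, orbital-gap stripes as periodic missingness,
footprint-averaged station reports with Gaussian noise, a thinned Poisson
process for presence points, and the ZIB observation model for checklist
counts — and always returns the generating parameters alongside the data
so recovery can be tested exactly.

All randomness flows from one root seed through named substreams, so any
stage can be regenerated independently and byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GeoGrid, GridStack, GridTransform, MONTH_LABELS

_SUBSTREAMS = {"truth": 0, "stack": 1, "stations": 2, "points": 3,
               "occupancy": 4, "covariates": 5, "albedo": 6}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named stage, derived from the root seed."""
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return np.random.default_rng(children[_SUBSTREAMS[name]])


@dataclass
class Sensor:
    """One satellite sensor: overpass-gap stripes and optional stripe bias.

    ``overpass_gap_period = k`` marks the striped columns invalid every
    k-th day (k = 0 disables stripes); ``stripe_amplitude`` instead adds a
    multiplicative bias to the cloud probability along the stripe bands
    (used only by destriping experiments).
    """

    name: str
    overpass_gap_period: int = 0
    stripe_angle_deg: float = 15.0
    stripe_amplitude: float = 0.0
    stripe_spacing: int = 8
    stripe_width: int = 2


@dataclass
class SimulationConfig:
    seed: int = 0
    grid_shape: tuple[int, int] = (50, 50)
    years: Sequence[int] = tuple(range(2000, 2005))
    days_per_month: int = 30
    sensors: list[Sensor] = field(default_factory=lambda: [
        Sensor("terra", stripe_angle_deg=15.0),
        Sensor("aqua", stripe_angle_deg=-15.0),
    ])
    # truth climatology
    p_range: tuple[float, float] = (0.2, 0.8)
    seasonal_mode: str = "sinusoid"  # uniform | sinusoid | bimodal
    seasonal_amplitude: float = 0.15
    seasonal_peak_month: int = 7
    smooth_sigma: float = 5.0
    # stations
    station_n: int = 100
    station_noise_sd: float = 5.0  # % cloud amount
    station_footprint_cells: float = 2.0
    station_low_obs_frac: float = 0.1
    # artifacts
    albedo_anomaly_cells: list[tuple[int, int]] = field(default_factory=list)
    transform: GridTransform = GridTransform(0.0, 0.0, 0.01, 0.01)
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_range[0] <= self.p_range[1] <= 1.0):
            raise ValueError("p_range must satisfy 0 <= p_min <= p_max <= 1")
        if self.days_per_month < 1:
            raise ValueError("need at least one simulated day per month")


# ---------------------------------------------------------------------
# truth climatology
# ---------------------------------------------------------------------

def generate_truth_climatology(config: SimulationConfig) -> GridStack:
    """12 monthly cloud-probability surfaces (fractions in [0, 1]).

    A smooth spatial base field (Gaussian-filtered white noise rescaled to
    ``p_range``) modulated by the chosen seasonal structure; surfaces that
    would leave [0, 1] raise rather than being silently clipped.
    """
    rng = substream(config.seed, "truth")
    nr, nc = config.grid_shape
    base = ndimage.gaussian_filter(rng.standard_normal((nr, nc)),
                                   config.smooth_sigma, mode="reflect")
    lo, hi = config.p_range
    rng_span = base.max() - base.min()
    if rng_span > 0 and hi > lo:
        base = lo + (base - base.min()) / rng_span * (hi - lo)
    else:
        base = np.full((nr, nc), (lo + hi) / 2.0)

    months = np.arange(1, 13)
    phase = 2.0 * np.pi * (months - config.seasonal_peak_month) / 12.0
    if config.seasonal_mode == "uniform":
        season = np.zeros(12)
    elif config.seasonal_mode == "sinusoid":
        season = config.seasonal_amplitude * np.cos(phase)
    elif config.seasonal_mode == "bimodal":
        season = config.seasonal_amplitude * np.cos(2.0 * phase)
    else:
        raise ValueError(f"unknown seasonal_mode {config.seasonal_mode!r}")

    surfaces = base[None, :, :] + season[:, None, None]
    if surfaces.min() < 0.0 or surfaces.max() > 1.0:
        raise ValueError("monthly probabilities leave [0, 1]; "
                         "reduce seasonal_amplitude or narrow p_range")
    return GridStack.from_array(surfaces, MONTH_LABELS,
                                transform=config.transform, crs=config.crs)


# ---------------------------------------------------------------------
# daily cloud-flag stacks
# ---------------------------------------------------------------------

@dataclass
class DailyFlags:
    """Daily binary cloud flags and validity masks for one sensor."""

    sensor: str
    flags: np.ndarray  # (n_days, rows, cols) bool
    valid: np.ndarray  # (n_days, rows, cols) bool
    dates: list[tuple[int, int, int]]  # (year, month, day)
    transform: GridTransform = GridTransform(0.0, 0.0, 1.0, 1.0)
    crs: str = "EPSG:4326"


def stripe_band_mask(shape: tuple[int, int], angle_deg: float,
                     spacing: int, width: int) -> np.ndarray:
    """Boolean mask of near-longitudinal stripe bands at *angle_deg* from
    vertical, *width* cells wide every *spacing* cells."""
    nr, nc = shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    u = cols - rows * np.tan(np.deg2rad(angle_deg))
    return np.mod(u, spacing) < width


def stripe_profile_field(shape: tuple[int, int], angle_deg: float,
                         spacing: int, width: float) -> np.ndarray:
    """Smooth (Gaussian cross-profile) stripe field in [0, 1]: bumps of
    scale *width* cells centred every *spacing* cells along the same
    near-longitudinal geometry as :func:`stripe_band_mask`."""
    nr, nc = shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    u = cols - rows * np.tan(np.deg2rad(angle_deg))
    du = np.minimum(np.mod(u, spacing), spacing - np.mod(u, spacing))
    return np.exp(-0.5 * (du / width) ** 2)


def generate_cloud_stack(truth: GridStack, config: SimulationConfig
                         ) -> dict[str, DailyFlags]:
    """Per-sensor daily flag stacks drawn Bernoulli from the truth surfaces.

    Each simulated day draws flag ~ Bernoulli(p_month) independently per
    pixel.  Every ``overpass_gap_period``-th day the sensor's stripe bands
    are invalid (orbital-gap missingness); ``stripe_amplitude`` applies a
    persistent multiplicative cloud-probability bias along the bands.
    """
    rng = substream(config.seed, "stack")
    p_truth = truth.as_array()  # (12, nr, nc)
    nr, nc = p_truth.shape[1:]
    out: dict[str, DailyFlags] = {}
    for sensor in config.sensors:
        band = stripe_band_mask((nr, nc), sensor.stripe_angle_deg,
                                sensor.stripe_spacing, sensor.stripe_width)
        p_eff = p_truth.copy()
        if sensor.stripe_amplitude != 0.0:
            profile = stripe_profile_field(
                (nr, nc), sensor.stripe_angle_deg,
                sensor.stripe_spacing, sensor.stripe_width)
            p_eff = np.clip(
                p_eff * (1.0 + sensor.stripe_amplitude * profile), 0.0, 1.0)
        flags, valids, dates = [], [], []
        day_idx = 0
        for year in config.years:
            for month in range(1, 13):
                p_m = p_eff[month - 1]
                for day in range(1, config.days_per_month + 1):
                    f = rng.random((nr, nc)) < p_m
                    v = np.ones((nr, nc), dtype=bool)
                    if sensor.overpass_gap_period > 0 and (
                            day_idx % sensor.overpass_gap_period == 0):
                        v[band] = False
                    flags.append(f)
                    valids.append(v)
                    dates.append((year, month, day))
                    day_idx += 1
        out[sensor.name] = DailyFlags(
            sensor=sensor.name,
            flags=np.stack(flags),
            valid=np.stack(valids),
            dates=dates,
            transform=config.transform,
            crs=config.crs,
        )
    return out


# ---------------------------------------------------------------------
# station records
# ---------------------------------------------------------------------

def _footprint_mean(p_truth: np.ndarray, row: int, col: int,
                    radius_cells: float) -> np.ndarray:
    """Mean of each monthly surface over cells within radius of (row, col)."""
    nr, nc = p_truth.shape[1:]
    r = int(np.ceil(radius_cells))
    rows = np.arange(max(0, row - r), min(nr, row + r + 1))
    cols = np.arange(max(0, col - r), min(nc, col + r + 1))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    inside = (rr - row) ** 2 + (cc - col) ** 2 <= radius_cells**2
    return p_truth[:, rr[inside], cc[inside]].mean(axis=1)


def generate_station_records(truth: GridStack, config: SimulationConfig):
    """Monthly station cloud amounts with engineered observation counts.

    Station truth is the footprint mean of the monthly probability surfaces
    (in %), perturbed by Gaussian noise of SD ``station_noise_sd``.  A
    fraction ``station_low_obs_frac`` of stations is given sparse monthly
    observation counts (5/month) so the archive filters have something to
    reject; all other stations get 25 per month in every year.

    Returns ``(records, truth_info)`` where records is a list of
    :class:`~cloudclim.validation.StationRecord` and truth_info carries the
    noise-free footprint means and the engineered pass/fail flags.
    """
    from .validation import StationRecord

    rng = substream(config.seed, "stations")
    p_truth = truth.as_array()
    nr, nc = p_truth.shape[1:]
    t = truth.transform
    margin = int(np.ceil(config.station_footprint_cells))
    rows = rng.integers(margin, nr - margin, size=config.station_n)
    cols = rng.integers(margin, nc - margin, size=config.station_n)
    n_low = int(round(config.station_low_obs_frac * config.station_n))
    low_obs = np.zeros(config.station_n, dtype=bool)
    low_obs[:n_low] = True  # first stations sparse: deterministic bookkeeping

    records, truth_means = [], []
    for i in range(config.station_n):
        lon = t.x_origin + (cols[i] + 0.5) * t.dx
        lat = t.y_origin - (rows[i] + 0.5) * t.dy
        fmean = 100.0 * _footprint_mean(p_truth, rows[i], cols[i],
                                        config.station_footprint_cells)
        amounts = fmean + rng.normal(0.0, config.station_noise_sd, size=12)
        amounts = np.clip(amounts, 0.0, 100.0)
        n_obs = 5 if low_obs[i] else 25
        obs = {(m, y): n_obs for y in config.years for m in range(1, 13)}
        records.append(StationRecord(
            id=f"st{i:04d}", lon=lon, lat=lat,
            monthly_cloud_amount=amounts, obs_count=obs))
        truth_means.append(fmean)

    truth_info = {
        "footprint_mean_pct": np.array(truth_means),
        "noise_sd": config.station_noise_sd,
        "low_obs": low_obs,
        "rows": rows, "cols": cols,
    }
    return records, truth_info


# ---------------------------------------------------------------------
# covariate surfaces (shared by both SDM generators)
# ---------------------------------------------------------------------

def generate_covariates(shape: tuple[int, int], names: Sequence[str],
                        seed: int, smooth_sigma: float = 3.0,
                        transform: GridTransform = GridTransform(0, 0, 0.01, 0.01),
                        ) -> GridStack:
    """Smooth standardized (mean 0, SD 1) covariate surfaces."""
    rng = substream(seed, "covariates")
    fields = []
    for _ in names:
        f = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma,
                                    mode="reflect")
        fields.append((f - f.mean()) / f.std())
    return GridStack.from_array(np.stack(fields), list(names),
                                transform=transform)


# ---------------------------------------------------------------------
# presence points (thinned Poisson process)
# ---------------------------------------------------------------------

def generate_presence_points(intensity_coefs: Sequence[float],
                             covariates: GridStack, n_expected: int,
                             seed: int,
                             region_breaks_lon: Sequence[float] = ()):
    """Presence points from an inhomogeneous Poisson process.

    Cell intensity is exp(x'b) (no intercept; *intensity_coefs* aligns with
    the covariate stack order), globally rescaled so the expected point
    count is *n_expected*.  Counts are Poisson per cell; points land
    uniformly inside their cell.  Returns ``(DataFrame(lon, lat, region),
    truth)`` with the generating coefficients in truth.
    """
    rng = substream(seed, "points")
    X = covariates.as_array()  # (k, nr, nc)
    coefs = np.asarray(intensity_coefs, float)
    if coefs.shape[0] != X.shape[0]:
        raise ValueError("one coefficient per covariate required")
    log_int = np.tensordot(coefs, X, axes=1)
    mask = np.any(np.isnan(X), axis=0)
    lam = np.where(mask, 0.0, np.exp(log_int))
    lam *= n_expected / lam.sum()
    counts = rng.poisson(lam)
    t = covariates.transform
    rows, cols = np.nonzero(counts)
    lons, lats = [], []
    for r, c, k in zip(rows, cols, counts[rows, cols]):
        u = rng.random(k)
        v = rng.random(k)
        lons.extend(t.x_origin + (c + u) * t.dx)
        lats.extend(t.y_origin - (r + v) * t.dy)
    pts = pd.DataFrame({"lon": lons, "lat": lats})
    region = np.zeros(len(pts), dtype=int)
    for edge in region_breaks_lon:
        region += (pts["lon"].to_numpy() >= edge).astype(int)
    pts["region"] = np.array([f"region{g}" for g in region])
    truth = {"coefs": coefs, "expected_n": n_expected, "lambda": lam}
    return pts, truth


# ---------------------------------------------------------------------
# occupancy data (zero-inflated binomial observation model)
# ---------------------------------------------------------------------

def generate_occupancy_data(beta: Sequence[float], delta: float,
                            covariates: GridStack, seed: int,
                            trials_law: str = "1+poisson(4)"):
    """Cell-level trials/presences from the ZIB model.

    z_i ~ Bernoulli(logit^-1(x_i'beta)) is latent suitability and
    y_i ~ Binomial(n_i, z_i * delta) the detections, delta the constant
    per-survey detection probability.  The design row is (1, covariates).
    Default trials law n_i ~ 1 + Poisson(4) mimics sparse checklists.

    Returns ``(DataFrame(cell_id, lon, lat, n, y, <covariates>), truth)``
    with beta, delta and the latent z in truth.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError("detection probability delta must lie in [0, 1]")
    rng = substream(seed, "occupancy")
    X = covariates.as_array()
    nr, nc = X.shape[1:]
    mask = np.any(np.isnan(X), axis=0)
    rows, cols = np.nonzero(~mask)
    Xc = X[:, rows, cols].T  # (n_cells, k)
    beta = np.asarray(beta, float)
    if beta.shape[0] != Xc.shape[1] + 1:
        raise ValueError("beta must have one intercept + one slope per covariate")
    eta = beta[0] + Xc @ beta[1:]
    theta = 1.0 / (1.0 + np.exp(-eta))
    z = rng.random(theta.shape) < theta
    if trials_law == "1+poisson(4)":
        n = 1 + rng.poisson(4, size=theta.shape)
    elif trials_law.startswith("constant:"):
        n = np.full(theta.shape, int(trials_law.split(":")[1]))
    else:
        raise ValueError(f"unknown trials_law {trials_law!r}")
    y = rng.binomial(n, np.where(z, delta, 0.0))
    t = covariates.transform
    df = pd.DataFrame({
        "cell_id": np.arange(len(rows)),
        "lon": t.x_origin + (cols + 0.5) * t.dx,
        "lat": t.y_origin - (rows + 0.5) * t.dy,
        "n": n, "y": y,
    })
    for j, name in enumerate(covariates.labels):
        df[name] = Xc[:, j]
    truth = {"beta": beta, "delta": delta, "z": z.astype(int),
             "theta": theta}
    return df, truth


# ---------------------------------------------------------------------
# sidecar I/O
# ---------------------------------------------------------------------

def save_daily_flags(daily: DailyFlags, directory) -> None:
    """Write one sensor's stack as multi-band GeoTIFFs (flags and validity)
    with a sidecar CSV of the band dates."""
    from pathlib import Path

    from .raster import write_raster

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = [f"{y:04d}-{m:02d}-{d:02d}" for (y, m, d) in daily.dates]
    for name, arr in (("flags", daily.flags), ("valid", daily.valid)):
        stack = GridStack.from_array(arr.astype(float), labels,
                                     transform=daily.transform, crs=daily.crs)
        write_raster(stack, directory / f"{daily.sensor}_{name}.tif")
    pd.DataFrame({"band": np.arange(1, len(labels) + 1),
                  "date": labels}).to_csv(
        directory / f"{daily.sensor}_dates.csv", index=False)


def save_station_csv(records, path) -> None:
    """Stations as CSV: id, lon, lat, monthly amount columns m1..m12."""
    rows = []
    for r in records:
        row = {"id": r.id, "lon": r.lon, "lat": r.lat}
        row.update({f"m{m + 1}": r.monthly_cloud_amount[m]
                    for m in range(12)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def save_truth_sidecar(config: SimulationConfig, path, extra=None) -> None:
    """Record the generating parameters as a YAML sidecar so any dataset
    written to disk stays traceable to its ground truth."""
    import yaml
    from dataclasses import asdict

    doc = asdict(config)
    doc["years"] = list(config.years)
    doc["transform"] = list(config.transform)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------
# albedo surfaces for artifact detection tests
# ---------------------------------------------------------------------

def generate_albedo_stack(config: SimulationConfig,
                          base_albedo: float = 0.15,
                          anomaly_max: float = 0.9,
                          anomaly_min: float = 0.1) -> GridStack:
    """12 monthly albedo surfaces: constant low albedo everywhere except
    the configured anomaly cells, which swing seasonally between
    ``anomaly_min`` and ``anomaly_max`` (salt-flat style)."""
    nr, nc = config.grid_shape
    months = np.arange(12)
    swing = (anomaly_max + anomaly_min) / 2.0 + (
        (anomaly_max - anomaly_min) / 2.0) * np.cos(2 * np.pi * months / 12.0)
    arr = np.full((12, nr, nc), base_albedo)
    for (r, c) in config.albedo_anomaly_cells:
        arr[:, r, c] = swing
    return GridStack.from_array(arr, MONTH_LABELS,
                                transform=config.transform, crs=config.crs)
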