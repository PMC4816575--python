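"""Bayesian zero-inflated binomial (ZIB) occupancy model.

Detection/non-detection checklists aggregated to grid cells give trials
n_i and detections y_i.  Latent suitability z_i ~ Bernoulli(theta_i) with
logit(theta_i) = x_i'beta separates habitat suitability from imperfect
detection: conditional on a suitable cell, each trial detects the species
with probability delta (intercept-only, logit(delta) = gamma), so
y_i ~ Binomial(n_i, z_i * delta).  Priors on beta and gamma are diffuse
independent normals (variance 1e6 by default).

Fitting is Metropolis-within-Gibbs: z_i is drawn from its exact full
conditional (z_i = 1 whenever y_i > 0; otherwise Bernoulli with odds
theta_i (1-delta)^{n_i} : (1-theta_i)), while beta and gamma move by
adaptive random-walk Metropolis tuned toward 20-50% acceptance during
burn-in only (the proposal is frozen afterwards, preserving the Markov
property).  The per-draw deviance is computed on the z-marginalized
likelihood

    L_i = theta_i * Binom(y_i | n_i, delta) + (1 - theta_i) * 1[y_i = 0]

which feeds the DIC; convergence across chains is measured by the
Brooks-Gelman multivariate potential scale reduction factor (MPSRF).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .grid import GeoGrid, GridStack
from .ppm import auc_rank

logger = logging.getLogger(__name__)


@dataclass
class CellOccurrence:
    """Per-cell trials, presences, and suitability covariates."""

    df: pd.DataFrame  # columns: cell_id, lon, lat, n, y, <covariates>
    covariate_names: list[str]

    def __post_init__(self) -> None:
        y = self.df["y"].to_numpy()
        n = self.df["n"].to_numpy()
        if np.any(y < 0) or np.any(y > n):
            raise ValueError("need 0 <= y_i <= n_i")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(y, n, X_raw) over cells with n_i > 0 (likelihood cells)."""
        d = self.df[self.df["n"] > 0]
        return (d["y"].to_numpy(float), d["n"].to_numpy(float),
                d[self.covariate_names].to_numpy(float))


def filter_checklists(records: pd.DataFrame) -> pd.DataFrame:
    """Effort-filter survey checklists and aggregate to cell counts.

    Keeps complete checklists with duration strictly under 4 h and either
    distance <= 5 km or area <= 500 ha (a missing distance/area passes if
    the other bound holds).  Returns one row per cell with n (surviving
    checklists) and y (those with a detection).
    """
    df = records.copy()
    dist = df.get("distance_km", pd.Series(np.nan, index=df.index)).fillna(np.inf)
    area = df.get("area_ha", pd.Series(np.nan, index=df.index)).fillna(np.inf)
    keep = (df["complete"].astype(bool)
            & (df["duration_h"] < 4.0)
            & ((dist <= 5.0) | (area <= 500.0)))
    kept = df[keep]
    agg = kept.groupby("cell_id").agg(
        n=("detected", "size"), y=("detected", "sum")).reset_index()
    return agg


# ---------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC output: (chains, kept, params) with run metadata."""

    samples: np.ndarray       # beta (standardized scale) then gamma, last
    deviance: np.ndarray      # (chains, kept)
    param_names: list[str]
    burnin: int
    iters: int
    thin: int
    cov_means: np.ndarray
    cov_sds: np.ndarray
    acceptance: dict = field(default_factory=dict)

    @property
    def n_beta(self) -> int:
        return self.samples.shape[2] - 1

    def flat(self) -> np.ndarray:
        return self.samples.reshape(-1, self.samples.shape[2])

    def beta_original_scale(self) -> np.ndarray:
        """Map standardized-covariate beta draws back to the raw scale."""
        flat = self.flat()
        b = flat[:, :self.n_beta].copy()
        slopes = b[:, 1:] / self.cov_sds
        b0 = b[:, 0] - slopes @ self.cov_means
        return np.column_stack([b0, slopes])

    def summary(self) -> pd.DataFrame:
        flat = self.flat()
        qs = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame({
            "param": self.param_names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": qs[0], "median": qs[1], "q97.5": qs[2]})


def _marginal_deviance(y, n, log_binom, theta, delta) -> float:
    """-2 log of the z-marginalized ZIB likelihood."""
    with np.errstate(divide="ignore"):
        log_pdet = log_binom + y * np.log(delta) + (n - y) * np.log1p(-delta)
    # delta in {0,1} edge cases
    log_pdet = np.where((delta <= 0) & (y > 0), -np.inf, log_pdet)
    if delta <= 0:
        log_pdet = np.where(y == 0, 0.0, log_pdet)
    if delta >= 1:
        log_pdet = np.where(y == n, log_binom * 0.0, -np.inf)
    li = theta * np.exp(log_pdet) + (1 - theta) * (y == 0)
    return float(-2.0 * np.sum(np.log(np.maximum(li, 1e-300))))


def fit_zib(data: CellOccurrence, chains: int = 3, burnin: int = 10000,
            iters: int = 50000, thin: int = 50, seed: int = 0,
            prior_var: float = 1e6, standardize: bool = True
            ) -> PosteriorDraws:
    """Fit the ZIB model by Metropolis-within-Gibbs MCMC.

    Default iteration settings follow common practice for this model
    class (3 chains, 10k burn-in, 50k sampling, thin 50); scale them down
    for small problems.  Covariates are standardized internally (zero
    mean, unit SD); draws can be mapped back with
    :meth:`PosteriorDraws.beta_original_scale`.
    """
    y, n, X_raw = data.arrays()
    if y.size == 0:
        raise ValueError("no cells with trials")
    if not np.any(y > 0):
        raise ValueError("no cells with detections")
    means = X_raw.mean(axis=0) if standardize else np.zeros(X_raw.shape[1])
    sds = X_raw.std(axis=0) if standardize else np.ones(X_raw.shape[1])
    if np.any(sds == 0):
        raise ValueError("constant covariate column")
    X = np.column_stack([np.ones(len(y)), (X_raw - means) / sds])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    k = X.shape[1]
    log_binom = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    detected = y > 0

    kept = iters // thin
    samples = np.empty((chains, kept, k + 1))
    deviance = np.empty((chains, kept))
    acc_info = {}
    seeds = np.random.SeedSequence(seed).spawn(chains)
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        beta = rng.normal(0, 0.1, size=k)
        gamma = rng.normal(0, 0.1)
        scale_b, scale_g = 0.1, 0.2
        acc_b = acc_g = try_b = try_g = 0
        z = detected.astype(float)

        eta = X @ beta
        theta = expit(eta)
        delta = expit(gamma)

        def beta_logpost(beta_v, theta_v, z_v):
            lp = np.sum(z_v * np.log(np.maximum(theta_v, 1e-300))
                        + (1 - z_v) * np.log(np.maximum(1 - theta_v, 1e-300)))
            return lp - 0.5 * np.sum(beta_v**2) / prior_var

        for it in range(burnin + iters):
            # -- z from its exact full conditional
            with np.errstate(over="ignore"):
                odds = theta * np.exp(n * np.log1p(-delta))
            p_z1 = odds / (odds + (1 - theta))
            z = np.where(detected, 1.0, (rng.random(len(y)) < p_z1))

            # -- beta: joint random-walk Metropolis
            prop = beta + scale_b * rng.standard_normal(k)
            theta_prop = expit(X @ prop)
            logr = beta_logpost(prop, theta_prop, z) - beta_logpost(beta, theta, z)
            try_b += 1
            if np.log(rng.random()) < logr:
                beta, theta = prop, theta_prop
                acc_b += 1

            # -- gamma: random-walk Metropolis on the detection submodel
            occ = z > 0.5
            prop_g = gamma + scale_g * rng.standard_normal()
            d_new, d_old = expit(prop_g), delta

            def det_loglik(d):
                if not occ.any():
                    return 0.0
                return np.sum(y[occ] * np.log(np.maximum(d, 1e-300))
                              + (n[occ] - y[occ]) * np.log(np.maximum(1 - d, 1e-300)))

            logr = (det_loglik(d_new) - det_loglik(d_old)
                    - 0.5 * (prop_g**2 - gamma**2) / prior_var)
            try_g += 1
            if np.log(rng.random()) < logr:
                gamma, delta = prop_g, d_new
                acc_g += 1

            # -- diminishing adaptation during burn-in only
            if it < burnin and (it + 1) % 50 == 0:
                rate_b, rate_g = acc_b / try_b, acc_g / try_g
                scale_b *= np.exp((rate_b - 0.35) * 0.5)
                scale_g *= np.exp((rate_g - 0.35) * 0.5)
                acc_b = acc_g = try_b = try_g = 0

            if it >= burnin and (it - burnin) % thin == thin - 1:
                j = (it - burnin) // thin
                samples[c, j, :k] = beta
                samples[c, j, k] = gamma
                deviance[c, j] = _marginal_deviance(y, n, log_binom, theta, delta)

        rate_b = acc_b / max(try_b, 1)
        rate_g = acc_g / max(try_g, 1)
        acc_info[f"chain{c}"] = {"beta": rate_b, "gamma": rate_g}
        for nm, rate in (("beta", rate_b), ("gamma", rate_g)):
            if not (0.05 <= rate <= 0.95):
                warnings.warn(f"chain {c}: {nm} acceptance {rate:.2f} "
                              "outside [5%, 95%] after adaptation")

    names = (["beta0"] + [f"beta_{nm}" for nm in data.covariate_names]
             + ["gamma"])
    return PosteriorDraws(samples=samples, deviance=deviance,
                          param_names=names, burnin=burnin, iters=iters,
                          thin=thin, cov_means=means, cov_sds=sds,
                          acceptance=acc_info)


# ---------------------------------------------------------------------
# diagnostics and derived quantities
# ---------------------------------------------------------------------

def dic(draws: PosteriorDraws, data: CellOccurrence) -> dict:
    """Deviance information criterion on the z-marginalized likelihood.

    DIC = mean deviance + p_D, with p_D = mean deviance - deviance at the
    posterior mean parameters.  A negative p_D (a known DIC pathology for
    mixture-type likelihoods) is logged, not raised.
    """
    y, n, X_raw = data.arrays()
    means, sds = draws.cov_means, draws.cov_sds
    X = np.column_stack([np.ones(len(y)), (X_raw - means) / sds])
    log_binom = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    flat = draws.flat()
    post_mean = flat.mean(axis=0)
    theta_hat = expit(X @ post_mean[:-1])
    delta_hat = float(expit(post_mean[-1]))
    d_hat = _marginal_deviance(y, n, log_binom, theta_hat, delta_hat)
    d_bar = float(draws.deviance.mean())
    p_d = d_bar - d_hat
    if p_d < 0:
        logger.warning("negative p_D (%.3f): DIC pathology", p_d)
    return {"DIC": d_bar + p_d, "Dbar": d_bar, "Dhat": d_hat, "pD": p_d}


def mpsrf(draws: PosteriorDraws | np.ndarray) -> float:
    """Brooks-Gelman multivariate potential scale reduction factor.

    R = (n-1)/n + ((m+1)/m) * lambda_1, where lambda_1 is the largest
    eigenvalue of W^{-1} B/n for within- and between-chain covariances W
    and B; values near 1 indicate convergence.
    """
    chains = draws.samples if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    m, n, p = chains.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains of length >= 2")
    W = np.mean([np.cov(chains[c].T, ddof=1) for c in range(m)], axis=0)
    W = np.atleast_2d(W)
    chain_means = chains.mean(axis=1)
    B_over_n = np.atleast_2d(np.cov(chain_means.T, ddof=1))
    lam = np.max(np.real(np.linalg.eigvals(np.linalg.solve(
        W + 1e-12 * np.eye(p), B_over_n))))
    return float((n - 1) / n + (m + 1) / m * lam)


def predict_occurrence(draws: PosteriorDraws, covariates: GridStack
                       ) -> tuple[GeoGrid, GeoGrid, GeoGrid]:
    """Posterior mean and 95% CI grids of theta = logit^-1(x'beta)."""
    arr = covariates.as_array()
    mask = np.any(np.isnan(arr), axis=0)
    Xc = arr[:, ~mask].T
    X = np.column_stack([np.ones(len(Xc)),
                         (Xc - draws.cov_means) / draws.cov_sds])
    flat = draws.flat()[:, :-1]  # beta draws
    theta = expit(X @ flat.T)  # (cells, draws)
    mean = theta.mean(axis=1)
    lo = np.quantile(theta, 0.025, axis=1)
    hi = np.quantile(theta, 0.975, axis=1)
    grids = []
    for v in (mean, lo, hi):
        out = np.full(mask.shape, np.nan)
        out[~mask] = v
        grids.append(GeoGrid(out, transform=covariates.transform,
                             crs=covariates.crs))
    return tuple(grids)


def range_size(theta: GeoGrid | np.ndarray) -> float:
    """Expected number of occupied cells: sum of per-cell occurrence
    probabilities over the unmasked domain (no thresholding)."""
    if isinstance(theta, GeoGrid):
        vals = theta.unmasked_values()
    else:
        vals = np.asarray(theta, float)
        vals = vals[np.isfinite(vals)]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    return float(vals.sum())


def evaluate(theta_at_cells: np.ndarray, y: np.ndarray, n: np.ndarray) -> dict:
    """Cell-level AUC (detected vs never-detected) and Pearson correlation
    between y_i/n_i and predicted theta_i."""
    theta_at_cells = np.asarray(theta_at_cells, float)
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    use = n > 0
    th, yy, nn = theta_at_cells[use], y[use], n[use]
    pos = th[yy > 0]
    neg = th[yy == 0]
    auc = auc_rank(pos, neg)
    if np.ptp(th) == 0:
        warnings.warn("constant predictions: correlation undefined")
        cor = np.nan
    else:
        cor = float(np.corrcoef(yy / nn, th)[0, 1])
    return {"AUC": float(auc), "cor": cor,
            "nPresence": int((yy > 0).sum()), "nTrials": int(nn.sum())}


def enumerate_z_posterior(y, n, X, beta_grid, gamma_grid, prior_var=1e6):
    """Brute-force posterior P(z_i = 1 | data) on a tiny model by grid
    integration over (beta, gamma); independent oracle for the sampler.

    *beta_grid* is (n_points, k) covering intercept-plus-slopes;
    *gamma_grid* is 1-D.  Returns the marginal P(z_i=1|y) per cell.
    """
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    X = np.asarray(X, float)
    log_binom = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    num = np.zeros(len(y))
    den = 0.0
    for b in beta_grid:
        theta = expit(X @ b)
        for g in gamma_grid:
            d = expit(g)
            with np.errstate(divide="ignore"):
                log_pdet = log_binom + y * np.log(d) + (n - y) * np.log1p(-d)
            li_z1 = theta * np.exp(log_pdet)
            li_z0 = (1 - theta) * (y == 0)
            li = li_z1 + li_z0
            prior = np.exp(-0.5 * (np.sum(b**2) + g**2) / prior_var)
            joint = np.prod(li) * prior
            if joint > 0:
                num += joint * li_z1 / li
                den += joint
    return num / den
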