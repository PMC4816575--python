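"""Presence-only distribution modelling by infinitely weighted logistic
regression (IWLR).

Presence records (e.g. cloud-forest sites) carry weight 1 and a large
uniform background sample carries weight W; as W grows, the slope
estimates of the weighted logistic regression converge to the maximum
likelihood estimate of an inhomogeneous Poisson point-process intensity
log lambda(s) = x(s)'beta — the same estimand as MaxEnt.  The model is
fitted by Newton iteration (IRLS) on the weighted likelihood, and
compared via AIC/BIC on the weighted log-likelihood, AUC against the
background sample, and the point-biserial correlation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GeoGrid, GridStack


# ---------------------------------------------------------------------
# background sampling
# ---------------------------------------------------------------------

def sample_background(domain: GeoGrid, n: int = 10000,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """*n* points uniform over the unmasked cells of *domain* (cells drawn
    with replacement, positions uniform within the cell)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows, cols = np.nonzero(~domain.mask)
    if rows.size == 0:
        raise ValueError("domain has no unmasked cells")
    pick = rng.integers(0, rows.size, size=n)
    t = domain.transform
    u = rng.random(n)
    v = rng.random(n)
    return pd.DataFrame({
        "lon": t.x_origin + (cols[pick] + u) * t.dx,
        "lat": t.y_origin - (rows[pick] + v) * t.dy,
    })


# ---------------------------------------------------------------------
# design matrices (S4-Table-style formulas)
# ---------------------------------------------------------------------

@dataclass
class DesignInfo:
    """Everything needed to rebuild a design matrix on new data."""

    formula: str
    names: list[str]
    levels: dict[str, list] = field(default_factory=dict)


def _expand_term(term: str, df: pd.DataFrame, levels: dict) -> list[tuple[str, np.ndarray]]:
    term = term.strip()
    m = re.fullmatch(r"I\((\w+)\^2\)", term)
    if m:
        name = m.group(1)
        return [(f"I({name}^2)", df[name].to_numpy(float) ** 2)]
    if "*" in term:
        a, b = (s.strip() for s in term.split("*", 1))
        cols = _expand_term(a, df, levels) + _expand_term(b, df, levels)
        a_cols = _expand_term(a, df, levels)
        b_cols = _expand_term(b, df, levels)
        for an, av in a_cols:
            for bn, bv in b_cols:
                cols.append((f"{an}:{bn}", av * bv))
        return cols
    col = df[term]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        if term in levels:
            levs = levels[term]
        else:
            levs = sorted(col.unique())
            levels[term] = levs
        # reference level = first alphabetically
        return [(f"{term}[{lev}]", (col == lev).to_numpy(float))
                for lev in levs[1:]]
    return [(term, col.to_numpy(float))]


def build_design(formula: str, df: pd.DataFrame,
                 info: DesignInfo | None = None) -> tuple[np.ndarray, DesignInfo]:
    """Design matrix for a formula of linear terms, ``I(x^2)`` squares,
    categorical factors (reference = first level alphabetically), and
    ``a*factor`` interactions.  An intercept column always leads.

    Passing a previously returned *info* pins the factor levels so
    prediction designs align with the fitted coefficients.
    """
    rhs = formula.split("~", 1)[1] if "~" in formula else formula
    levels = dict(info.levels) if info is not None else {}
    names: list[str] = ["(Intercept)"]
    cols: list[np.ndarray] = [np.ones(len(df))]
    for term in rhs.split("+"):
        for name, values in _expand_term(term, df, levels):
            if name in names:
                continue  # a*b re-lists main effects; keep first occurrence
            names.append(name)
            cols.append(values)
    X = np.column_stack(cols)
    # duplicate/collinear guard (only meaningful with enough rows)
    if X.shape[0] >= X.shape[1]:
        for i in range(X.shape[1]):
            for j in range(i + 1, X.shape[1]):
                if np.allclose(X[:, i], X[:, j]):
                    raise ValueError(f"collinear duplicate column: {names[j]}")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
    out_info = DesignInfo(formula=formula, names=names, levels=levels)
    return X, out_info


# ---------------------------------------------------------------------
# the weighted logistic fit
# ---------------------------------------------------------------------

@dataclass
class PPMFit:
    """An IWLR fit with its model-comparison metrics."""

    coefficients: pd.Series
    cov: np.ndarray
    loglik: float
    aic: float
    bic: float
    auc: float
    cor: float
    W: float
    n_presence: int
    n_background: int
    design_info: DesignInfo = None
    n_iter: int = 0

    def wald_p(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov))
        z = self.coefficients.to_numpy() / se
        return pd.Series(2 * stats.norm.sf(np.abs(z)),
                         index=self.coefficients.index)

    def summary_table(self) -> pd.DataFrame:
        p = self.wald_p()
        stars = p.map(lambda v: "***" if v < 1e-3 else
                      "**" if v < 1e-2 else "*" if v < 5e-2 else "")
        return pd.DataFrame({"coefficient": self.coefficients.index,
                             "estimate": self.coefficients.to_numpy(),
                             "se": np.sqrt(np.diag(self.cov)),
                             "p": p.to_numpy(), "stars": stars.to_numpy()})


def auc_rank(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) statistic with tie correction."""
    ranks = stats.rankdata(np.concatenate([scores_pos, scores_neg]))
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    if n_pos == 0 or n_neg == 0:
        return np.nan
    return (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def fit_iwlr(X_presence: np.ndarray, X_background: np.ndarray,
             W: float = 1e3, design_info: DesignInfo | None = None,
             max_iter: int = 100, tol: float = 1e-8,
             max_abs_coef: float = 50.0) -> PPMFit:
    """Weighted logistic regression: weight 1 on presences, W on background.

    Newton/IRLS to gradient max-norm < *tol*; a coefficient exceeding
    *max_abs_coef* flags (quasi-)separation and raises.
    """
    X = np.vstack([X_presence, X_background])
    y = np.concatenate([np.ones(len(X_presence)), np.zeros(len(X_background))])
    w = np.concatenate([np.ones(len(X_presence)),
                        np.full(len(X_background), float(W))])
    k = X.shape[1]
    beta = np.zeros(k)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (y - p))
        if np.max(np.abs(grad)) < tol:
            break
        Wdiag = w * p * (1 - p)
        H = X.T @ (X * Wdiag[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise RuntimeError(f"singular Hessian at iteration {it}") from e
        beta = beta + step
        if np.max(np.abs(beta)) > max_abs_coef:
            raise RuntimeError(
                f"separation suspected: |coef| > {max_abs_coef} at iter {it}")
    else:
        raise RuntimeError(
            f"IWLR did not converge in {max_iter} iterations "
            f"(gradient norm {np.max(np.abs(grad)):.3g})")

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-300
    loglik = float(np.sum(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))
    cov = np.linalg.inv(X.T @ (X * (w * p * (1 - p))[:, None]))
    n_p, n_b = len(X_presence), len(X_background)
    # effective n for BIC: the presences are the information-bearing unit
    aic = -2 * loglik + 2 * k
    bic = -2 * loglik + k * np.log(n_p)
    auc = auc_rank(eta[:n_p], eta[n_p:])
    cor = float(np.corrcoef(y, p)[0, 1]) if np.ptp(p) > 0 else np.nan
    names = (design_info.names if design_info is not None
             else [f"b{i}" for i in range(k)])
    return PPMFit(coefficients=pd.Series(beta, index=names), cov=cov,
                  loglik=loglik, aic=aic, bic=bic, auc=auc, cor=cor,
                  W=float(W), n_presence=n_p, n_background=n_b,
                  design_info=design_info, n_iter=it)


def predict_ror(fit: PPMFit, cov_df: pd.DataFrame,
                covariates: GridStack | None = None) -> np.ndarray | GeoGrid:
    """Relative occurrence rate: exp(linear predictor without intercept),
    rescaled to a maximum of 1.

    *cov_df* holds one row per prediction cell/point.  If *covariates* is
    given the result is reshaped onto its grid geometry (rows must be the
    stack's unmasked cells in row-major order).
    """
    X, _ = build_design(fit.design_info.formula, cov_df, info=fit.design_info)
    beta = fit.coefficients.to_numpy().copy()
    beta[0] = 0.0  # intensity is relative: drop the intercept anchor
    eta = X @ beta
    ror = np.exp(eta - eta.max())  # max 1 by construction
    if covariates is None:
        return ror
    arr = covariates.as_array()
    mask = np.any(np.isnan(arr), axis=0)
    out = np.full(mask.shape, np.nan)
    out[~mask] = ror
    return GeoGrid(out, transform=covariates.transform, crs=covariates.crs)


def compare_models(fits: dict[str, PPMFit], baseline: str) -> pd.DataFrame:
    """Model-comparison table with deltas to *baseline*, sorted by BIC."""
    base = fits[baseline]
    rows = []
    for name, f in fits.items():
        rows.append({"model": name, "k": len(f.coefficients),
                     "loglik": f.loglik, "AIC": f.aic, "BIC": f.bic,
                     "AUC": f.auc, "COR": f.cor,
                     "dAIC": f.aic - base.aic, "dBIC": f.bic - base.bic,
                     "dAUC": f.auc - base.auc, "dCOR": f.cor - base.cor})
    return pd.DataFrame(rows).sort_values("BIC").reset_index(drop=True)
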