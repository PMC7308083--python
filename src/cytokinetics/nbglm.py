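"""Batched negative-binomial GLM with log link for hypersphere counts.

All hyperspheres share one design matrix, so the IRLS normal equations are
solved for every hypersphere simultaneously (stacked p x p solves). The
dispersion is a moment-based common dispersion estimated across
hyperspheres from Poisson fits of the full model; differential abundance
is assessed by a likelihood-ratio analysis of deviance between the full
(replicate + condition) and reduced (replicate only) models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "design_matrices",
    "fit_glm",
    "nb_deviance",
    "estimate_common_dispersion",
    "analysis_of_deviance",
]


def design_matrices(
    samples: pd.DataFrame,
    condition: str = "condition",
    replicate: str = "replicate",
    reference: str = "unstim",
):
    """Full (intercept + replicate + condition) and reduced (intercept +
    replicate) design matrices with the unstimulated condition as the
    reference level.

    Returns ``(X_full, X_reduced, condition_levels)`` where
    ``condition_levels`` names the non-reference condition columns, in the
    order of the trailing columns of ``X_full``.
    """
    cond = samples[condition].astype(str)
    if reference not in set(cond):
        raise ValueError(f"reference condition {reference!r} absent from samples")
    levels = [l for l in pd.unique(cond) if l != reference]
    rep = samples[replicate]
    rep_levels = list(pd.unique(rep))[1:]
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    for r in rep_levels:
        cols.append((rep == r).to_numpy(dtype=float))
        names.append(f"replicate[{r}]")
    X_reduced = np.column_stack(cols)
    for l in levels:
        cols.append((cond == l).to_numpy(dtype=float))
        names.append(f"condition[{l}]")
    X_full = np.column_stack(cols)
    for X, label in ((X_full, "full"), (X_reduced, "reduced")):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"{label} design is not of full rank: replicate and condition "
                "are aliased; check the sample sheet"
            )
    return X_full, X_reduced, levels


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Residual deviance of an NB (or Poisson when alpha = 0) model,
    summed per hypersphere (rows)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if alpha > 0:
        term2 = (y + 1.0 / alpha) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
        dev = 2.0 * (term1 - term2)
    else:
        dev = 2.0 * (term1 - (y - mu))
    return dev.sum(axis=-1)


def fit_glm(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    alpha: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-10,
):
    """Fit one NB GLM per row of ``Y`` (hyperspheres x samples), all sharing
    the design ``X`` (samples x p) and ``offset`` (log exposure).

    Returns a dict with ``beta`` (H x p), ``mu`` (H x n) and ``deviance``
    (H,).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    H, n = Y.shape
    p = X.shape[1]
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)

    mu = np.maximum(Y + 0.5, 0.5)
    eta = np.log(mu)
    dev = nb_deviance(Y, mu, alpha)
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        W = mu / (1.0 + alpha * mu)                     # IRLS working weights
        z = (eta - offset) + (Y - mu) / mu              # working response
        A = np.einsum("ni,hn,nj->hij", X, W, X) + ridge
        r = np.einsum("ni,hn->hi", X, W * z)
        beta = np.linalg.solve(A, r[..., None])[..., 0]
        eta = beta @ X.T + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        new_dev = nb_deviance(Y, mu, alpha)
        if np.max(np.abs(new_dev - dev)) < tol * (1.0 + np.max(np.abs(new_dev))):
            dev = new_dev
            break
        dev = new_dev
    return {"beta": beta, "mu": mu, "deviance": dev}


def estimate_common_dispersion(
    Y: np.ndarray, X: np.ndarray, offset: np.ndarray | None = None,
    max_rounds: int = 4,
) -> float:
    """Pearson-based common NB dispersion pooled across hyperspheres.

    Solves ``sum_h sum_i (y - mu)^2 / (mu + alpha mu^2) = H (n - p)``
    (pooled Pearson chi-square equal to its residual degrees of freedom)
    for one ``alpha`` shared by every hypersphere, alternating the 1-D
    solve with NB refits of the means until it stabilizes.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    H = Y.shape[0]
    n, p = X.shape
    if n <= p:
        return 0.0
    target = H * (n - p)
    alpha = 0.0
    for _ in range(max_rounds):
        mu = np.maximum(fit_glm(Y, X, offset=offset, alpha=alpha)["mu"], 1e-8)
        resid2 = (Y - mu) ** 2

        def pearson(a):
            return float((resid2 / (mu + a * mu**2)).sum() - target)

        if pearson(0.0) <= 0:
            new_alpha = 0.0
        else:
            hi = 1.0
            while pearson(hi) > 0 and hi < 1e4:
                hi *= 10.0
            from scipy.optimize import brentq

            new_alpha = float(brentq(pearson, 0.0, hi, xtol=1e-10, rtol=1e-8))
        if abs(new_alpha - alpha) < 1e-6 * (1.0 + new_alpha):
            alpha = new_alpha
            break
        alpha = new_alpha
    return alpha


def analysis_of_deviance(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    offset: np.ndarray | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test for dropping the condition terms.

    When ``alpha`` is None a common dispersion is estimated first. Returns
    a frame with the deviance difference, df, p-value and the natural-log
    condition coefficients of the full fit.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if np.any(Y < 0):
        raise ValueError("counts must be nonnegative")
    if alpha is None:
        alpha = estimate_common_dispersion(Y, X_full, offset)
    full = fit_glm(Y, X_full, offset=offset, alpha=alpha)
    reduced = fit_glm(Y, X_reduced, offset=offset, alpha=alpha)
    df = X_full.shape[1] - X_reduced.shape[1]
    lr = np.maximum(reduced["deviance"] - full["deviance"], 0.0)
    pvals = stats.chi2.sf(lr, df)
    out = pd.DataFrame({"lr": lr, "df": df, "pvalue": pvals})
    out.attrs["alpha"] = alpha
    out.attrs["beta"] = full["beta"]
    return out
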