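"""Ionome phenotype QC, block-corrected BLUEs and broad-sense heritability.

Replicated elemental measurements (leaf B, with Cr and Ti as soil-
contamination sentinels) are cleaned with a single-pass z-score filter and a
replicate floor, block effects are removed with best linear unbiased
estimates (BLUEs) from a mixed model with accession fixed and block random,
and broad-sense heritability H² = var_line / (var_line + var_residual) is
estimated from a one-way random-effects fit.

Both mixed models have a single variance component, so REML is profiled down
to a one-dimensional optimization over the log variance ratio
γ = σ²_random / σ²_residual, solved by bounded Brent search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "zscore_outlier_filter",
    "min_replicate_filter",
    "compute_blues",
    "broad_sense_heritability",
    "HeritabilityEstimate",
]

_GAMMA_BOUNDS = (1e-6, 1e6)  # variance-ratio search window
_BRENT_TOL = 1e-10


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Broad-sense heritability with its variance components ((µg/g)²)."""

    h2: float
    var_line: float
    var_residual: float


def zscore_outlier_filter(table: pd.DataFrame, channels=("B", "Cr", "Ti"),
                          threshold: float = 3.0) -> pd.DataFrame:
    """Drop individual plants with |z| > threshold on any listed channel.

    z-scores use the mean and sample SD (n-1 denominator) of each channel
    over all input rows, computed once before any removal (single pass).
    A channel with zero SD contributes z = 0 everywhere.
    """
    if len(table) < 2:
        raise ValueError("z-score filtering needs at least 2 rows")
    missing = [c for c in channels if c not in table.columns]
    if missing:
        raise KeyError(f"channels absent from table: {missing}")
    keep = np.ones(len(table), dtype=bool)
    for ch in channels:
        x = table[ch].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        z = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
        keep &= np.abs(z) <= threshold
    return table.loc[keep].reset_index(drop=True)


def min_replicate_filter(table: pd.DataFrame,
                         min_reps: int = 3) -> pd.DataFrame:
    """Drop accessions left with fewer than min_reps rows."""
    counts = table.groupby("accession")["accession"].transform("size")
    return table.loc[counts >= min_reps].reset_index(drop=True)


def _profiled_reml(y: np.ndarray, X: np.ndarray, Z: np.ndarray):
    """REML for y = Xβ + Zb + e with b ~ N(0, γσ²I), e ~ N(0, σ²I).

    Returns (gamma_hat, sigma2_hat, beta_hat, XtVinvX) at the optimum,
    using the Woodbury identity so the cost scales with the number of
    random-effect levels, not n.
    """
    n, p = X.shape
    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    q = Z.shape[1]

    def parts(gamma):
        # V = I + gamma Z Z'; V^-1 = I - Z M^-1 Z', M = I/gamma + Z'Z
        M = ZtZ + np.eye(q) / gamma
        Minv_ZtX = np.linalg.solve(M, ZtX)
        Minv_Zty = np.linalg.solve(M, Zty)
        XtVinvX = XtX - ZtX.T @ Minv_ZtX
        XtVinvy = Xty - ZtX.T @ Minv_Zty
        ytVinvy = yty - Zty @ Minv_Zty
        sign, logdet_M = np.linalg.slogdet(np.eye(q) + gamma * ZtZ)
        beta = np.linalg.solve(XtVinvX, XtVinvy)
        rss = float(ytVinvy - beta @ XtVinvy)  # r' V^-1 r
        return beta, XtVinvX, rss, logdet_M

    def neg_reml(log_gamma):
        gamma = np.exp(log_gamma)
        beta, XtVinvX, rss, logdet_V = parts(gamma)
        sign, logdet_XVX = np.linalg.slogdet(XtVinvX)
        if sign <= 0 or rss <= 0:
            return np.inf
        return 0.5 * (logdet_V + logdet_XVX + (n - p) * np.log(rss))

    res = minimize_scalar(neg_reml, bounds=np.log(_GAMMA_BOUNDS),
                          method="bounded",
                          options={"xatol": _BRENT_TOL})
    gamma = float(np.exp(res.x))
    beta, XtVinvX, rss, _ = parts(gamma)
    sigma2 = rss / (n - p)
    return gamma, sigma2, beta, XtVinvX


def _design(table: pd.DataFrame, element: str):
    y = table[element].to_numpy(dtype=float)
    accs = pd.Categorical(table["accession"])
    blocks = pd.Categorical(table["block"])
    X = pd.get_dummies(accs).to_numpy(dtype=float)
    Z = pd.get_dummies(blocks).to_numpy(dtype=float)
    return y, X, Z, list(accs.categories), list(blocks.categories)


def compute_blues(table: pd.DataFrame, element: str = "B") -> pd.DataFrame:
    """Per-accession BLUEs of an element after removing block effects.

    Fits value = accession (fixed) + block (random) + residual by REML and
    returns the accession fixed effects on the original µg/g scale.  When
    the design cannot separate block from accession effects (fewer than two
    blocks, or complete confounding), falls back with a warning to ordinary
    least squares with sum-to-zero fixed block contrasts.

    Returns a DataFrame with columns accession, blue, n_reps_used.
    """
    y, X, Z, acc_names, block_names = _design(table, element)
    n_reps = table.groupby("accession").size().reindex(acc_names).to_numpy()

    n_blocks = Z.shape[1]
    # sum-to-zero block contrasts keep accession effects on the data scale
    contrasts = Z[:, :-1] - Z[:, [-1]] if n_blocks > 1 else np.zeros((len(y), 0))
    full = np.hstack([X, contrasts])
    confounded = np.linalg.matrix_rank(full) < full.shape[1]

    if n_blocks < 2 or confounded:
        warnings.warn("block effects not estimable; falling back to OLS "
                      "with fixed block contrasts")
        coef, *_ = np.linalg.lstsq(full, y, rcond=None)
        blues = coef[:X.shape[1]]
    else:
        _, _, beta, _ = _profiled_reml(y, X, Z)
        blues = beta
    return pd.DataFrame({"accession": acc_names,
                         "blue": blues,
                         "n_reps_used": n_reps.astype(int)})


def broad_sense_heritability(table: pd.DataFrame,
                             element: str = "B") -> HeritabilityEstimate:
    """H² from a one-way random-effects fit (accession random, REML).

    H² = var_line / (var_line + var_residual), components truncated at 0.
    Affine-invariant: rescaling the element leaves H² unchanged.
    """
    y, X_acc, _, _, _ = _design(table, element)
    if np.allclose(y, y[0]):
        return HeritabilityEstimate(h2=0.0, var_line=0.0, var_residual=0.0)
    X = np.ones((len(y), 1))  # intercept only; accession is the random term
    gamma, sigma2, _, _ = _profiled_reml(y, X, X_acc)
    var_line = max(gamma * sigma2, 0.0)
    var_res = max(sigma2, 0.0)
    # a ratio pinned at the search floor means a zero line component
    if gamma <= _GAMMA_BOUNDS[0] * (1 + 1e-6):
        var_line = 0.0
    total = var_line + var_res
    h2 = var_line / total if total > 0 else 0.0
    return HeritabilityEstimate(h2=float(h2), var_line=float(var_line),
                                var_residual=float(var_res))
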