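"""Kinship-corrected linear-mixed-model association scan, from scratch.

The scan fits, for every variant x,

    y = intercept + covariates + x·β + u + ε,
    u ~ N(0, σ²_g K),  ε ~ N(0, σ²_e I),

on the eigenbasis of the centered kinship matrix K, optimizing the variance
ratio δ = σ²_e / σ²_g per marker by exact REML (Brent on log δ) and testing
β with a Wald χ²₁ statistic.  Inbred lines carry one haplotype each, so
genotypes are 0/1 and the homozygote contrast is 2β.

Also houses the supporting operations: VCF call filtering (DP/GQ), variant
filtering (MAF/missingness), the centered kinship estimator, conditional
scans on lead markers, Bonferroni/Benjamini-Hochberg thresholds, the genomic
control λ, and the Mann-Whitney-Wilcoxon group test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "AssociationResult",
    "filter_genotypes",
    "filter_variants",
    "centered_kinship",
    "lmm_scan",
    "conditional_scan",
    "significance_thresholds",
    "genomic_control_lambda",
    "effect_size_homozygous",
    "group_difference_test",
]

_LOG_DELTA_BOUNDS = (np.log(1e-5), np.log(1e5))
_BRENT_TOL = 1e-8
_PSD_TOL = 1e-8
_SYM_TOL = 1e-10


@dataclass
class AssociationResult:
    """Per-variant association statistics plus scan-level summaries.

    ``table`` has one row per tested variant with columns chrom, pos, ref,
    alt, id, maf, n_used, beta, se, p_wald (beta in µg/g DW per allele
    copy); λ_gc and the significance cuts describe the whole scan.
    """

    table: pd.DataFrame
    lambda_gc: float
    bonferroni_threshold: float
    fdr_threshold: float | None
    covariate_ids: list = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return int(self.table["p_wald"].notna().sum())

    def top_hit(self) -> pd.Series:
        return self.table.loc[self.table["p_wald"].idxmin()]


# ---------------------------------------------------------------------------
# filtering

def filter_genotypes(vcf_path: str, dp_min_exclusive: int = 3,
                     gq_min_exclusive: int = 20) -> GenotypeMatrix:
    """Parse a VCF into a haploid-coded GenotypeMatrix with call filtering.

    Non-biallelic records are dropped; calls with DP <= dp_min_exclusive or
    GQ <= gq_min_exclusive are set to missing (DP "greater than three" and
    GQ "above 20" are strict inequalities).  Heterozygous calls, which an
    inbred panel should not produce, are treated as missing.
    """
    from .cli_io import read_vcf

    g = read_vcf(vcf_path)
    calls = g.calls.copy()
    fail = (g.dp <= dp_min_exclusive) | (g.gq <= gq_min_exclusive)
    calls[fail] = MISSING
    return GenotypeMatrix(samples=g.samples, variants=g.variants,
                          calls=calls, dp=g.dp, gq=g.gq)


def filter_variants(g: GenotypeMatrix, maf_min: float = 0.05,
                    miss_max: float = 0.10) -> GenotypeMatrix:
    """Keep variants with MAF >= maf_min and missing fraction < miss_max.

    MAF is computed over non-missing calls, before any imputation.
    """
    with np.errstate(invalid="ignore"):
        keep = (g.maf() >= maf_min) & (g.missing_fraction() < miss_max)
    keep &= ~np.isnan(g.maf())
    return g.subset_variants(keep)


# ---------------------------------------------------------------------------
# kinship

def centered_kinship(g: GenotypeMatrix) -> np.ndarray:
    """Centered relatedness matrix K = W·Wᵀ / p.

    W holds mean-centered variant columns with missing calls mean-imputed
    per variant (so imputed entries center to zero), p = variant count.
    """
    if g.n_variants < 1:
        raise ValueError("kinship requires at least one variant")
    W = g.dosage(impute=True)
    W = W - W.mean(axis=0, keepdims=True)
    return (W @ W.T) / g.n_variants


def _check_kinship(K: np.ndarray) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=_SYM_TOL):
        raise ValueError("kinship matrix is not symmetric")
    S, U = np.linalg.eigh((K + K.T) / 2)
    if S.min() < -_PSD_TOL * max(1.0, S.max()):
        raise ValueError("kinship matrix is not positive semidefinite")
    return np.clip(S, 0.0, None), U


# ---------------------------------------------------------------------------
# the scan

def _reml_fit(yt: np.ndarray, Dt: np.ndarray, S: np.ndarray):
    """Exact REML for one marker on the kinship eigenbasis.

    yt, Dt are U'y and U'D; V is diagonal there: σ²_g·(S + δ).  Returns
    (beta, se_of_last_column, sigma2_g, delta).
    """
    n, q = Dt.shape

    def fit(delta):
        w = S + delta
        Dw = Dt / w[:, None]
        A = Dt.T @ Dw  # D' V^-1 D (up to sigma2_g)
        b = Dw.T @ yt
        beta = np.linalg.solve(A, b)
        rss = float(yt @ (yt / w) - beta @ b)
        return beta, A, rss, float(np.sum(np.log(w)))

    def neg_reml(log_delta):
        try:
            beta, A, rss, logdet_V = fit(np.exp(log_delta))
        except np.linalg.LinAlgError:
            return np.inf
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0 or rss <= 0:
            return np.inf
        return 0.5 * (logdet_V + logdet_A + (n - q) * np.log(rss))

    res = minimize_scalar(neg_reml, bounds=_LOG_DELTA_BOUNDS,
                          method="bounded", options={"xatol": _BRENT_TOL})
    delta = float(np.exp(res.x))
    beta, A, rss, _ = fit(delta)
    sigma2_g = rss / (n - q)
    cov = sigma2_g * np.linalg.inv(A)
    se = float(np.sqrt(cov[-1, -1]))
    return beta, se, sigma2_g, delta


def _align_phenotype(y, samples) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [s for s in samples if s not in y.index]
        if missing:
            raise KeyError(f"phenotype missing for samples: {missing[:5]}")
        y = y.reindex(samples).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if len(y) != len(samples):
            raise ValueError("phenotype length must match sample count")
    if np.isnan(y).any():
        raise ValueError("phenotype must be complete for used samples")
    return y


def lmm_scan(y, g: GenotypeMatrix, K: np.ndarray,
             covariates: np.ndarray | None = None,
             alpha: float = 0.05, fdr_q: float = 0.10,
             _exclude_ids: set | None = None) -> AssociationResult:
    """Single-marker LMM scan over all variants of g.

    y may be an ndarray aligned to g.samples or a Series indexed by sample
    id.  Missing genotypes are mean-imputed per variant; MAF and n_used are
    computed before imputation.  A marker collinear with the covariates
    gets NaN statistics.
    """
    yv = _align_phenotype(y, g.samples)
    S, U = _check_kinship(K)
    n = g.n_samples

    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        C = np.hstack([C, cov])

    yt = U.T @ yv
    Ct = U.T @ C
    X = g.dosage(impute=True)
    Xt = U.T @ X

    exclude = _exclude_ids or set()
    ids = g.variant_ids()
    maf = g.maf()
    n_used = (~g.missing_mask()).sum(axis=0)

    betas = np.full(g.n_variants, np.nan)
    ses = np.full(g.n_variants, np.nan)
    pvals = np.full(g.n_variants, np.nan)
    keep_rows = np.ones(g.n_variants, dtype=bool)

    for j in range(g.n_variants):
        if ids[j] in exclude:
            keep_rows[j] = False
            continue
        xt = Xt[:, j]
        # collinearity with covariates: residual norm after projecting out C
        coef, *_ = np.linalg.lstsq(Ct, xt, rcond=None)
        resid = xt - Ct @ coef
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(xt)):
            continue  # p stays NaN
        Dt = np.column_stack([Ct, xt])
        beta_vec, se, _, _ = _reml_fit(yt, Dt, S)
        betas[j] = beta_vec[-1]
        ses[j] = se
        stat = (beta_vec[-1] / se) ** 2
        # floor against underflow so p stays in (0, 1]
        pvals[j] = max(stats.chi2.sf(stat, df=1), 1e-300)

    table = g.variants.copy()
    table["maf"] = maf
    table["n_used"] = n_used.astype(int)
    table["beta"] = betas
    table["se"] = ses
    table["p_wald"] = pvals
    table = table.loc[keep_rows].reset_index(drop=True)

    tested = table["p_wald"].dropna().to_numpy()
    if len(tested):
        lam = genomic_control_lambda(tested)
        bonf, fdr = significance_thresholds(tested, n_tests=len(tested),
                                            alpha=alpha, fdr_q=fdr_q)
    else:
        lam, bonf, fdr = np.nan, np.nan, None
    return AssociationResult(table=table, lambda_gc=lam,
                             bonferroni_threshold=bonf, fdr_threshold=fdr)


def conditional_scan(y, g: GenotypeMatrix, K: np.ndarray,
                     lead_markers: list, covariates=None,
                     **kwargs) -> AssociationResult:
    """LMM scan with lead-marker genotypes as fixed covariates.

    The lead markers (mean-imputed) are appended to the covariates and
    excluded from the reported results.  An empty list reproduces
    ``lmm_scan`` exactly.
    """
    ids = list(g.variant_ids())
    missing = [m for m in lead_markers if m not in ids]
    if missing:
        raise KeyError(f"lead markers absent from genotypes: {missing}")
    X = g.dosage(impute=True)
    lead_cols = [X[:, ids.index(m)] for m in lead_markers]
    cov = None
    parts = []
    if covariates is not None:
        parts.append(np.atleast_2d(np.asarray(covariates, dtype=float)))
    if lead_cols:
        parts.append(np.column_stack(lead_cols))
    if parts:
        parts = [p if p.shape[0] == g.n_samples else p.T for p in parts]
        cov = np.hstack(parts)
    res = lmm_scan(y, g, K, covariates=cov,
                   _exclude_ids=set(lead_markers), **kwargs)
    res.covariate_ids = list(lead_markers)
    return res


# ---------------------------------------------------------------------------
# scan-level statistics

def significance_thresholds(pvals, n_tests: int | None = None,
                            alpha: float = 0.05, fdr_q: float = 0.10):
    """(Bonferroni cut, Benjamini-Hochberg cut or None).

    Bonferroni: alpha / n_tests.  BH: the largest p(i) with
    p(i) <= i·q/m (step-up); None when nothing qualifies.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = int(n_tests) if n_tests is not None else p.size
    bonf = alpha / m
    ps = np.sort(p)
    i = np.arange(1, ps.size + 1)
    ok = ps <= i * fdr_q / m
    fdr = float(ps[np.flatnonzero(ok)[-1]]) if ok.any() else None
    return float(bonf), fdr


def expected_chi2_median() -> float:
    """Median of the χ²₁ distribution (the λ denominator), by inverse CDF."""
    return float(stats.chi2.ppf(0.5, df=1))


def genomic_control_lambda(pvals) -> float:
    """λ = observed median χ²₁ / expected median χ²₁ (≈ 0.4549)."""
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / expected_chi2_median())


def effect_size_homozygous(beta: float) -> float:
    """Homozygote contrast: twice the per-allele effect, same units."""
    return 2.0 * beta


def group_difference_test(values, group_labels):
    """Mann-Whitney-Wilcoxon two-sided test between two groups.

    Exact null distribution when both groups have n <= 20 and the data are
    tie-free; otherwise the normal approximation with mid-ranks and the
    tie-corrected variance.  Returns (U statistic of the first group,
    two-sided p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    x = values[labels == groups[0]]
    z = values[labels == groups[1]]
    if len(x) == 0 or len(z) == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (len(x) <= 20 and len(z) <= 20 and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, z, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
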