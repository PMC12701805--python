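"""Single-SNP mixed-model GWAS and the multi-trait chi-square meta-analysis.

The association model is the MLMA convention: variance components
(sigma^2_a for the GRM term, sigma^2_e residual) are fitted once per
trait by single-component REML on the null model, then reused for every
variant, so the genome scan costs one eigendecomposition plus O(M)
generalized-least-squares fits.  Per-variant genetic variance explained
is 2p(1-p) beta^2 / sigma^2_a x 100%.  The multi-trait statistic for
variant i is t_i' V^-1 t_i where t_i is the vector of signed t-values
across traits and V is the correlation matrix of t-values estimated
over all scanned variants, referred to a chi-square with one degree of
freedom per trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import HaplotypePanel

__all__ = [
    "build_grm",
    "reml_variance",
    "VarianceComponents",
    "snp_association",
    "conditional_association",
    "varg_explained",
    "multitrait_chi2",
    "GENOME_WIDE_P",
    "SUGGESTIVE_P",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-6


def build_grm(panel: HaplotypePanel, variant_mask=None) -> np.ndarray:
    """GCTA-convention genomic relationship matrix.

    K = (1/m) sum_k (x_k - 2 p_k)(x_k - 2 p_k)' / (2 p_k (1 - p_k)).
    """
    d = panel.imputed_dosage()
    if variant_mask is not None:
        d = d[:, variant_mask]
    p = d.mean(axis=0) / 2
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic variant in GRM input")
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (z @ z.T) / z.shape[1]


@dataclass
class VarianceComponents:
    """REML variance components of the single-GRM mixed model."""

    sigma2_a: float
    sigma2_e: float
    loglik: float
    at_boundary: bool = False

    @property
    def lam(self) -> float:
        return self.sigma2_a / self.sigma2_e if self.sigma2_e > 0 else np.inf

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0


def _design(covariates, n) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    # always include an intercept unless a constant column is present
    if not any(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
        X = np.column_stack([np.ones(n), X])
    return X


def _reml_neg_loglik(log_lam, s, y_rot, x_rot):
    lam = np.exp(log_lam)
    d = lam * s + 1.0
    n, p = x_rot.shape
    w = 1.0 / d
    xtwx = x_rot.T @ (x_rot * w[:, None])
    xtwy = x_rot.T @ (y_rot * w)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return 1e30
    r = y_rot - x_rot @ beta
    rss = float(r @ (r * w))
    sign, logdet_x = np.linalg.slogdet(xtwx)
    if sign <= 0 or rss <= 0:
        return 1e30
    ll = -0.5 * (
        (n - p) * np.log(rss / (n - p))
        + np.log(d).sum()
        + logdet_x
        + (n - p)
    )
    return -ll


def reml_variance(y, covariates, grm) -> VarianceComponents:
    """Single-component REML via eigendecomposition of the GRM.

    Rotates y and the covariates by the GRM eigenvectors and maximizes
    the restricted likelihood in the single ratio lambda =
    sigma^2_a / sigma^2_e by bracketed scalar optimization.  An optimum
    at the search boundary is flagged, not raised.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    grm = np.asarray(grm, dtype=float)
    s, u = np.linalg.eigh(grm)
    if s.min() < -1e-6:
        raise ValueError("GRM is not positive semi-definite")
    s = np.clip(s, 0, None)
    X = _design(covariates, n)
    if n < X.shape[1] + 2:
        raise ValueError("too few observations for REML")
    y_rot = u.T @ y
    x_rot = u.T @ X

    lo, hi = np.log(1e-6), np.log(1e6)
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(s, y_rot, x_rot), method="bounded",
        options={"xatol": 1e-8},
    )
    log_lam = float(res.x)
    # degenerate GRM (e.g. identity): lambda unidentifiable, pin to boundary
    if np.allclose(s, s[0]):
        log_lam = lo
    lam = np.exp(log_lam)
    d = lam * s + 1.0
    w = 1.0 / d
    xtwx = x_rot.T @ (x_rot * w[:, None])
    beta = np.linalg.solve(xtwx, x_rot.T @ (y_rot * w))
    r = y_rot - x_rot @ beta
    p = x_rot.shape[1]
    sigma2_e = float(r @ (r * w)) / (n - p)
    sigma2_a = lam * sigma2_e
    at_boundary = log_lam <= lo + 1e-6 or log_lam >= hi - 1e-6 or np.allclose(s, s[0])
    return VarianceComponents(sigma2_a, sigma2_e, -float(res.fun), at_boundary)


def _gls_scan(dos, y, X, s, u, vc: VarianceComponents):
    """Per-variant GLS beta/se under covariance sigma2_a K + sigma2_e I."""
    d = vc.sigma2_a * s + vc.sigma2_e
    a = 1.0 / np.sqrt(d)
    yt = (u.T @ y) * a
    Xt = (u.T @ X) * a[:, None]
    Gt = (u.T @ dos) * a[:, None]
    q, _ = np.linalg.qr(Xt)
    y_r = yt - q @ (q.T @ yt)
    G_r = Gt - q @ (q.T @ Gt)
    xx = (G_r**2).sum(axis=0)
    ok = xx > 1e-12
    beta = np.full(dos.shape[1], np.nan)
    se = np.full(dos.shape[1], np.nan)
    beta[ok] = (G_r[:, ok] * y_r[:, None]).sum(axis=0) / xx[ok]
    se[ok] = 1.0 / np.sqrt(xx[ok])
    return beta, se, ok


def snp_association(
    panel: HaplotypePanel,
    trait,
    covariates=None,
    variance: VarianceComponents | None = None,
    grm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mixed-model single-SNP association scan (MLMA convention).

    ``variance`` holds the null-model REML components; if omitted it is
    fitted here from ``grm`` (which is built from the panel when not
    supplied).  Wald p-values are two-sided normal.  Variants with
    (near-)zero dosage variance are skipped with NaN statistics.

    Returns a SummaryStats table with columns chrom, pos, id,
    effect_allele, other_allele, eaf, beta, se, t, p, n and boolean
    significance labels at the genome-wide (5e-8) and suggestive (1e-6)
    thresholds.
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    X = _design(covariates, n)
    if grm is None:
        grm = build_grm(panel)
    if variance is None:
        variance = reml_variance(y, covariates, grm)
    s, u = np.linalg.eigh(grm)
    s = np.clip(s, 0, None)
    dos = panel.imputed_dosage()
    beta, se, ok = _gls_scan(dos, y, X, s, u, variance)
    t = beta / se
    p = 2 * stats.norm.sf(np.abs(t))
    eaf = dos.mean(axis=0) / 2
    out = panel.variants[["chrom", "pos", "id"]].copy()
    out["effect_allele"] = panel.variants["alt"]
    out["other_allele"] = panel.variants["ref"]
    out["eaf"] = eaf
    out["beta"] = beta
    out["se"] = se
    out["t"] = t
    out["p"] = p
    out["n"] = n
    out["genome_wide"] = p < GENOME_WIDE_P
    out["suggestive"] = p < SUGGESTIVE_P
    return out


def conditional_association(
    panel: HaplotypePanel,
    trait,
    target_variant: str,
    covariates=None,
    variance: VarianceComponents | None = None,
    grm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Association scan conditioning on the dosage of a target variant.

    The target's dosage joins the covariates and the target itself is
    excluded from the scan; a target collinear with an existing
    covariate raises with the offending column named.
    """
    ids = panel.variants["id"].to_numpy()
    where = np.where(ids == target_variant)[0]
    if len(where) == 0:
        raise KeyError(f"target variant {target_variant!r} not in panel")
    tix = int(where[0])
    tdos = panel.imputed_dosage()[:, tix]
    n = len(tdos)
    X = _design(covariates, n)
    for j in range(X.shape[1]):
        c = X[:, j]
        if c.std() > 0 and tdos.std() > 0:
            r = np.corrcoef(c, tdos)[0, 1]
            if abs(r) > 0.9999:
                raise ValueError(
                    f"target variant {target_variant} is collinear with covariate column {j}"
                )
    new_cov = np.column_stack([X, tdos])
    scan_panel = panel.subset(variant_mask=~(ids == target_variant))
    if grm is None:
        grm = build_grm(panel)
    return snp_association(scan_panel, trait, new_cov, variance=variance, grm=grm)


def varg_explained(beta: float, p: float, sigma2_a: float) -> float:
    """Percent of additive genetic variance explained by one variant:
    2 p (1 - p) beta^2 / sigma^2_a x 100."""
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    return 2 * p * (1 - p) * beta**2 / sigma2_a * 100.0


def multitrait_chi2(
    stats_by_trait: dict[str, pd.DataFrame],
    shrinkage: float = 0.05,
    null_t_max: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Multi-trait meta-analysis: chi2_i = t_i' V^-1 t_i, df = n_traits.

    V is the Pearson correlation of signed t-values across all scanned
    variants (optionally restricted to |t| < ``null_t_max`` when
    estimating it), then shrunk toward the identity by ``shrinkage`` to
    guard against ill-conditioning.  Variants missing a t-value for any
    trait are dropped.  Significance is Bonferroni 0.05 / M.
    """
    traits = list(stats_by_trait)
    merged = None
    for name in traits:
        df = stats_by_trait[name][["chrom", "pos", "id", "t"]].rename(columns={"t": f"t_{name}"})
        merged = df if merged is None else merged.merge(df, on=["chrom", "pos", "id"])
    merged = merged.dropna().reset_index(drop=True)
    T = merged[[f"t_{n}" for n in traits]].to_numpy()
    if null_t_max is not None:
        mask = (np.abs(T) < null_t_max).all(axis=1)
        V = np.corrcoef(T[mask].T) if mask.sum() > len(traits) + 2 else np.corrcoef(T.T)
    else:
        V = np.corrcoef(T.T)
    V = np.atleast_2d(V)
    Vs = (1 - shrinkage) * V + shrinkage * np.eye(len(traits))
    cond = np.linalg.cond(Vs)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"trait t-value correlation matrix singular (condition number {cond:.3g})"
        )
    sol = np.linalg.solve(Vs, T.T)
    chi2 = (T.T * sol).sum(axis=0)
    df = len(traits)
    p = stats.chi2.sf(chi2, df=df)
    out = merged[["chrom", "pos", "id"]].copy()
    out["chi2"] = chi2
    out["df"] = df
    out["p"] = p
    m = len(out)
    out["significant"] = p < 0.05 / max(m, 1)
    return out, Vs
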