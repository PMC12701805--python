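"""cis-eQTL mapping with permutation calibration.

Expression is quantile-normalized across samples and then rank-based
inverse-normal transformed per gene; hidden technical/biological
covariates are estimated as expression principal components and
combined with genotype PCs.  For each gene, every variant within 1 Mb
of the TSS is tested by a covariate-residualized slope test; gene-level
empirical p-values come from phenotype permutations with a Beta(a, b)
approximation to the null minimum p, eGenes are called by
Benjamini-Hochberg at FDR 0.05, and each eGene receives a nominal
per-variant threshold (the beta quantile of the global empirical-p
cutoff).  Allelic fold change (aFC), forward-stepwise independent
signals and Storey's pi1 replication statistic complete the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import HaplotypePanel

__all__ = [
    "normalize_expression",
    "hidden_factors",
    "genotype_pcs",
    "cis_scan",
    "permutation_pass",
    "egene_calling",
    "afc",
    "independent_eqtls",
    "storey_pi1",
    "CisResult",
]

AFC_CAP = 6.64  # |log2 fold change| cap, following the aFC convention (log2 100)
CIS_WINDOW_BP = 1_000_000


# ---------------------------------------------------------------------------
# Normalization and covariates


def quantile_normalize_samples(tpm: pd.DataFrame) -> pd.DataFrame:
    """Map every sample column onto the mean of the sorted columns."""
    X = tpm.to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(X.shape[0])[:, None], axis=0)
    ref = np.sort(X, axis=0).mean(axis=1)
    return pd.DataFrame(ref[ranks], index=tpm.index, columns=tpm.columns)


def normalize_expression(tpm: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize across samples, then per-gene inverse-normal.

    The rank-based step replaces each gene's values by Blom normal
    scores norm.ppf((rank - 3/8) / (n + 1/4)) with ties sharing the
    average rank.  Ranks are taken from the input values themselves:
    the cross-sample quantile normalization is monotone within a
    sample, not within a gene, so using its output ranks would inject
    spurious ties and rank flips into the per-gene transform, whose
    output the inverse-normal scores replace entirely anyway.  A
    constant gene yields all-zero scores.
    """
    X = tpm.to_numpy(dtype=float)
    out = np.empty_like(X)
    n = X.shape[1]
    for i in range(X.shape[0]):
        if np.ptp(X[i]) == 0:
            import warnings

            warnings.warn(f"constant gene {tpm.index[i]!r}: all-zero scores")
        r = stats.rankdata(X[i], method="average")
        out[i] = stats.norm.ppf((r - 3 / 8) / (n + 1 / 4))
    return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)


def hidden_factors(normalized: pd.DataFrame, k: int = 10) -> np.ndarray:
    """Top-k principal components of the sample x gene matrix.

    A deterministic PCA stand-in for latent-factor batch estimation:
    the scree of expression PCs plateaus at the same point the
    posterior variance of factor-analysis weights does, and PCs are
    reproducible without stochastic inference.  Sign convention: the
    largest-|loading| entry of each component is positive.  Returns a
    (samples, k) score matrix.
    """
    n = normalized.shape[1]
    if k >= n:
        raise ValueError("k must be smaller than the sample count")
    if k == 0:
        return np.zeros((n, 0))
    M = normalized.to_numpy().T  # samples x genes
    M = M - M.mean(axis=0)
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            scores[:, j] *= -1
    return scores


def genotype_pcs(panel: HaplotypePanel, k: int = 2) -> np.ndarray:
    """Top-k PCs of standardized dosages (population-structure covariates)."""
    d = panel.imputed_dosage()
    p = d.mean(axis=0) / 2
    ok = (p > 0) & (p < 1)
    z = (d[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
    u, s, _ = np.linalg.svd(z - z.mean(0), full_matrices=False)
    return u[:, :k] * s[:k]


# ---------------------------------------------------------------------------
# Nominal scan


def _residualize(M: np.ndarray, cov: np.ndarray | None) -> np.ndarray:
    n = M.shape[0]
    X = np.ones((n, 1)) if cov is None or cov.size == 0 else np.column_stack(
        [np.ones(n), cov]
    )
    q, _ = np.linalg.qr(X)
    return M - q @ (q.T @ M)


@dataclass
class CisResult:
    """Nominal cis scan for one gene plus permutation calibration."""

    gene_id: str
    pairs: pd.DataFrame  # variant id, pos, distance, beta, se, t, p
    n_covariates: int
    beta_a: float = np.nan
    beta_b: float = np.nan
    empirical_p: float = np.nan
    direct_p: float = np.nan
    beta_mom_fallback: bool = False
    egene: bool = False
    nominal_threshold: float = np.nan
    afc_log2: float = np.nan
    extra: dict = field(default_factory=dict)


def cis_scan(
    panel: HaplotypePanel,
    normalized: pd.DataFrame,
    gene_models: pd.DataFrame,
    covariates: np.ndarray | None = None,
    window_bp: int = CIS_WINDOW_BP,
) -> dict[str, CisResult]:
    """Nominal cis-eQTL scan: slope tests of residualized expression on
    residualized dosage for every variant within ``window_bp`` of the TSS.

    The slope test uses df = n - 2 - n_covariates; genes with zero cis
    variants are recorded with an empty pair table.
    """
    dos = panel.imputed_dosage()
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    ids = panel.variants["id"].to_numpy()
    n = panel.n_samples
    ncov = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    dos_r = _residualize(dos, covariates)
    results = {}
    for g in gene_models.itertuples(index=False):
        if g.gene_id not in normalized.index:
            continue
        cis = np.where((chrom == g.chrom) & (np.abs(pos - g.tss) <= window_bp))[0]
        y = normalized.loc[g.gene_id].to_numpy()
        y_r = _residualize(y[:, None], covariates)[:, 0]
        if len(cis) == 0:
            results[g.gene_id] = CisResult(
                g.gene_id,
                pd.DataFrame(columns=["id", "pos", "distance", "beta", "se", "t", "p"]),
                ncov,
            )
            continue
        X = dos_r[:, cis]
        xx = (X**2).sum(axis=0)
        ok = xx > 1e-12
        beta = np.full(len(cis), np.nan)
        se = np.full(len(cis), np.nan)
        df = n - 2 - ncov
        beta[ok] = X[:, ok].T @ y_r / xx[ok]
        resid_var = np.maximum(
            (y_r @ y_r) - beta[ok] ** 2 * xx[ok], 1e-300
        ) / df
        se[ok] = np.sqrt(resid_var / xx[ok])
        t = beta / se
        p = 2 * stats.t.sf(np.abs(t), df=df)
        results[g.gene_id] = CisResult(
            g.gene_id,
            pd.DataFrame(
                {
                    "id": ids[cis],
                    "pos": pos[cis],
                    "distance": pos[cis] - g.tss,
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "p": p,
                }
            ),
            ncov,
        )
    return results


# ---------------------------------------------------------------------------
# Permutations and eGene calling


def _fit_beta(pmin: np.ndarray) -> tuple[float, float, bool]:
    """Beta(a, b) fit to permutation minimum p-values; MoM fallback."""
    pmin = np.clip(pmin, 1e-300, 1 - 1e-12)
    try:
        a, b, _, _ = stats.beta.fit(pmin, floc=0, fscale=1)
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
            raise ValueError
        return float(a), float(b), False
    except Exception:
        m, v = pmin.mean(), pmin.var()
        v = max(v, 1e-12)
        common = m * (1 - m) / v - 1
        return float(max(m * common, 1e-3)), float(max((1 - m) * common, 1e-3)), True


def permutation_pass(
    panel: HaplotypePanel,
    normalized: pd.DataFrame,
    result: CisResult,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> CisResult:
    """Permute the gene's expression ``n_perm`` times and calibrate.

    Fits Beta(a, b) to the per-permutation minimum nominal p; the
    empirical p is BetaCDF(observed min p), and the direct-count
    estimate (1 + #{perm <= obs}) / (n_perm + 1) is kept alongside.
    """
    if len(result.pairs) == 0:
        raise ValueError(f"gene {result.gene_id} has no cis variants")
    rng = np.random.default_rng(seed)
    ids = panel.variants["id"].to_numpy()
    vmask = np.isin(ids, result.pairs["id"].to_numpy())
    dos_r = _residualize(panel.imputed_dosage()[:, vmask], covariates)
    norms = np.sqrt((dos_r**2).sum(axis=0))
    ok = norms > 1e-12
    U = dos_r[:, ok] / norms[ok]
    y = normalized.loc[result.gene_id].to_numpy()
    y_r = _residualize(y[:, None], covariates)[:, 0]
    n = len(y_r)
    df = n - 2 - result.n_covariates

    def min_p(Y):  # Y: (n, n_rep)
        ynorm = np.sqrt((Y**2).sum(axis=0))
        r = (U.T @ Y) / ynorm[None, :]
        r = np.clip(r, -0.999999999, 0.999999999)
        tstat = r * np.sqrt(df / (1 - r**2))
        return 2 * stats.t.sf(np.abs(tstat), df=df).min(axis=0)

    obs = float(min_p(y_r[:, None])[0])
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = y_r[rng.permutation(n)]
    pmin = min_p(perms)
    a, b, mom = _fit_beta(pmin)
    result.beta_a, result.beta_b, result.beta_mom_fallback = a, b, mom
    result.empirical_p = float(np.clip(stats.beta.cdf(obs, a, b), 1e-300, 1.0))
    result.direct_p = float((1 + (pmin <= obs).sum()) / (n_perm + 1))
    result.extra["obs_min_p"] = obs
    return result


def egene_calling(
    results: dict[str, CisResult], fdr: float = 0.05
) -> dict[str, CisResult]:
    """Benjamini-Hochberg over gene empirical p-values at FDR <= ``fdr``.

    The global empirical-p cutoff is the largest empirical p called
    significant; each eGene's per-variant nominal threshold is the beta
    quantile of that cutoff under its own Beta(a, b) null.
    """
    genes = [g for g, r in results.items() if np.isfinite(r.empirical_p)]
    if not genes:
        return results
    pvals = np.array([results[g].empirical_p for g in genes])
    rej, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    if rej.any():
        cutoff = pvals[rej].max()
    else:
        cutoff = 0.0
    for g, r in zip(genes, rej):
        res = results[g]
        res.egene = bool(r)
        if res.egene:
            res.nominal_threshold = float(
                stats.beta.ppf(cutoff, res.beta_a, res.beta_b)
            )
    return results


def afc(
    panel: HaplotypePanel,
    tpm: pd.DataFrame,
    gene_id: str,
    variant_id: str,
    covariates: np.ndarray | None = None,
) -> float:
    """log2 allelic fold change of an eVariant on its eGene.

    Fits mu + beta * dosage on covariate-residualized linear-scale TPM;
    aFC = log2(1 + 2 beta / mu) with mu the fitted mean at dosage 0,
    clamped to +/-6.64.  Returns NaN (flagged missing) when mu <= 0.
    """
    ids = panel.variants["id"].to_numpy()
    vi = np.where(ids == variant_id)[0]
    if len(vi) == 0:
        raise KeyError(variant_id)
    x = panel.imputed_dosage()[:, int(vi[0])]
    y = tpm.loc[gene_id].to_numpy(dtype=float)
    if covariates is not None and np.size(covariates):
        # remove covariate effects but keep the overall mean (linear scale)
        resid = _residualize(y[:, None], covariates)[:, 0]
        y = resid + y.mean()
    X = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu, beta = coef
    if mu <= 0:
        return float("nan")
    ratio = 1 + 2 * beta / mu
    if ratio <= 0:
        return -AFC_CAP
    return float(np.clip(np.log2(ratio), -AFC_CAP, AFC_CAP))


def independent_eqtls(
    panel: HaplotypePanel,
    normalized: pd.DataFrame,
    result: CisResult,
    covariates: np.ndarray | None = None,
    threshold: float | None = None,
) -> list[str]:
    """Forward-stepwise independent cis signals with backward refinement.

    Requires the gene to be a called eGene.  Variants are added while
    the best conditional p stays below the per-gene nominal
    ``threshold`` (defaulting to the one stored on the result); a
    backward pass re-tests each selected variant conditioned on the
    others.
    """
    if not result.egene:
        return []
    thr = result.nominal_threshold if threshold is None else threshold
    if not np.isfinite(thr):
        return []
    ids = panel.variants["id"].to_numpy()
    keep = np.isin(ids, result.pairs["id"].to_numpy())
    sub_ids = ids[keep]
    dos = panel.imputed_dosage()[:, keep]
    y = normalized.loc[result.gene_id].to_numpy()
    base_cov = None if covariates is None else np.atleast_2d(covariates)
    ncov0 = 0 if base_cov is None else base_cov.shape[1]

    def scan(selected):
        cov = base_cov
        if selected:
            sel = dos[:, [int(np.where(sub_ids == v)[0][0]) for v in selected]]
            cov = sel if cov is None else np.column_stack([cov, sel])
        X = _residualize(dos, cov)
        yr = _residualize(y[:, None], cov)[:, 0]
        xx = (X**2).sum(axis=0)
        ok = xx > 1e-8
        df = len(y) - 2 - ncov0 - len(selected)
        beta = np.where(ok, (X * yr[:, None]).sum(0) / np.where(ok, xx, 1), np.nan)
        rv = np.maximum((yr @ yr) - beta**2 * xx, 1e-300) / df
        t = beta / np.sqrt(rv / np.where(ok, xx, 1))
        p = 2 * stats.t.sf(np.abs(t), df=df)
        p[~ok] = 1.0
        p[np.isin(sub_ids, selected)] = 1.0
        return p

    selected: list[str] = []
    while True:
        p = scan(selected)
        j = int(np.argmin(p))
        if p[j] >= thr or len(selected) >= 10:
            break
        selected.append(sub_ids[j])
    # backward refinement: drop members no longer significant given the rest
    refined = list(selected)
    for v in list(selected):
        others = [w for w in refined if w != v]
        p = scan(others)
        j = int(np.where(sub_ids == v)[0][0])
        if p[j] >= thr and len(refined) > 1:
            refined.remove(v)
    return refined


# ---------------------------------------------------------------------------
# Replication


def storey_pi1(pvalues, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi1 = 1 - pi0 from a vector of replication p-values.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05); a cubic
    smoother is fitted to pi0(lambda) and read off at the top of the
    grid (the smoothed estimate closest to lambda -> 1); the result is
    clamped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if p.size < 100:
        import warnings

        warnings.warn("pi1 estimate from fewer than 100 p-values is unstable")
    lam = np.arange(0.05, 0.96, 0.05) if lambdas is None else np.asarray(lambdas)
    pi0 = np.array([(p > l).mean() / (1 - l) for l in lam])
    # precision weights: Var(pi0(lambda)) grows like lambda / (1 - lambda),
    # so the fit should not let the noisiest grid points steer the endpoint
    w = np.sqrt((1 - lam) / lam)
    coef = np.polyfit(lam, pi0, 3, w=w)
    pi0_hat = float(np.clip(np.polyval(coef, lam.max()), 0.0, 1.0))
    return 1.0 - pi0_hat
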