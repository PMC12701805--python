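"""Colocalization via approximate Bayes factors, and the SMR test.

Colocalization follows the single-causal-variant approximate-Bayes-
factor framework: per variant and dataset the Wakefield log-ABF is
0.5 [log(1 - r) + r z^2] with r = W / (V + W), V the squared standard
error and W the prior effect variance; the five hypotheses (no signal,
signal in one dataset, two distinct causal variants, one shared
variant) are scored by summing over single- and paired-variant
configurations with priors p1, p2, p12, and posteriors are normalized
by log-sum-exp.  SMR uses the top cis-eQTL as the instrument:
T_SMR = z_g^2 z_e^2 / (z_g^2 + z_e^2), referred to chi-square with one
degree of freedom, with Benjamini-Hochberg control across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = ["coloc_abf", "smr", "smr_table", "ColocResult", "SmrResult"]


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: dict[str, float]  # PP.H0 .. PP.H4
    n_snps: int
    priors: tuple[float, float, float]
    h4_variant_weights: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def h4(self) -> float:
        return self.pp["PP.H4"]

    @property
    def colocalized(self) -> bool:
        return self.h4 > 0.8


def _log_abf(beta, se, prior_sd):
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(1 - r) + r * z2)


def coloc_abf(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd: float = 0.15,
) -> ColocResult:
    """Colocalize two summary-statistic sets over a shared region.

    ``gwas`` and ``eqtl`` need columns id, beta, se (and optionally
    effect_allele/other_allele for sign harmonization).  Variants are
    intersected on id; records with se <= 0 are dropped.
    """
    g = gwas.dropna(subset=["beta", "se"]).query("se > 0")
    e = eqtl.dropna(subset=["beta", "se"]).query("se > 0")
    merged = g.merge(e, on="id", suffixes=("_g", "_e"))
    if "effect_allele_g" in merged and "effect_allele_e" in merged:
        flip = (
            (merged["effect_allele_g"] == merged["other_allele_e"])
            & (merged["other_allele_g"] == merged["effect_allele_e"])
        )
        merged.loc[flip, "beta_e"] *= -1
        keep = flip | (
            (merged["effect_allele_g"] == merged["effect_allele_e"])
            & (merged["other_allele_g"] == merged["other_allele_e"])
        )
        merged = merged[keep]
    if len(merged) == 0:
        raise ValueError("no shared variants between the two datasets")

    l1 = _log_abf(merged["beta_g"], merged["se_g"], prior_sd)
    l2 = _log_abf(merged["beta_e"], merged["se_e"], prior_sd)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over i != j of exp(l1_i + l2_j) = exp(s1 + s2) - exp(s12)
    hi = max(s1 + s2, s12)
    diff = np.exp(s1 + s2 - hi) - np.exp(s12 - hi)
    s3 = hi + np.log(diff) if diff > 0 else -np.inf

    lh = {
        "PP.H0": 0.0,
        "PP.H1": np.log(p1) + s1,
        "PP.H2": np.log(p2) + s2,
        "PP.H3": np.log(p1) + np.log(p2) + s3,
        "PP.H4": np.log(p12) + s12,
    }
    norm = logsumexp(list(lh.values()))
    pp = {k: float(np.exp(v - norm)) for k, v in lh.items()}
    w = np.exp(l1 + l2 - logsumexp(l1 + l2))
    weights = pd.DataFrame({"id": merged["id"].to_numpy(), "h4_weight": w})
    return ColocResult(pp, len(merged), (p1, p2, p12), weights)


@dataclass
class SmrResult:
    gene_id: str
    instrument: str
    b_xy: float
    t_smr: float
    p: float


def smr(beta_gwas, se_gwas, beta_eqtl, se_eqtl) -> tuple[float, float, float]:
    """SMR statistic at one instrument.

    Returns (b_xy, T_SMR, p); b_xy = beta_gwas / beta_eqtl is the
    effect of expression on the trait under the mediation model.
    z_e = 0 leaves the test undefined and raises.
    """
    z_g = beta_gwas / se_gwas
    z_e = beta_eqtl / se_eqtl
    if z_e == 0:
        raise ZeroDivisionError("eQTL z-score is zero; SMR undefined")
    if z_g == 0:
        return beta_gwas / beta_eqtl, 0.0, 1.0
    t = (z_g**2 * z_e**2) / (z_g**2 + z_e**2)
    return beta_gwas / beta_eqtl, float(t), float(stats.chi2.sf(t, df=1))


def smr_table(
    instruments: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """SMR across genes with BH control.

    ``instruments`` needs columns gene_id, instrument, beta_gwas,
    se_gwas, beta_eqtl, se_eqtl (one row per eGene, the instrument
    being its top cis-eQTL passing the gene's nominal threshold).
    """
    rows = []
    for r in instruments.itertuples(index=False):
        if r.beta_eqtl == 0:
            continue
        b, t, p = smr(r.beta_gwas, r.se_gwas, r.beta_eqtl, r.se_eqtl)
        rows.append((r.gene_id, r.instrument, b, t, p))
    out = pd.DataFrame(rows, columns=["gene_id", "instrument", "b_xy", "t_smr", "p"])
    if len(out):
        rej, _, _, _ = multipletests(out["p"], alpha=fdr, method="fdr_bh")
        out["fdr_significant"] = rej
    else:
        out["fdr_significant"] = pd.Series(dtype=bool)
    return out
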