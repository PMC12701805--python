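"""Permutation enrichment of variant sets in annotations, and TAD
co-occurrence of eGene-eVariant pairs.

One permutation engine serves both GWAS-signal and eQTL enrichment:
the observed overlap proportion of a candidate variant set with a
track (or with another variant set) is compared with draws of
equal-size sets from the tested variants, by default matched within
2%-MAF bins since both GWAS hits and eQTLs are frequency-biased.
Fold = observed / mean(null); the interval test is two-sided (folds
below one report depletion), while TAD co-occurrence is one-sided for
excess, permuting each eGene-variant pair to a random distance-matched
variant around a random gene's TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypePanel, IntervalTrack

__all__ = [
    "EnrichmentResult",
    "interval_enrichment",
    "gwas_in_eqtl_enrichment",
    "tad_cooccurrence",
]


@dataclass
class EnrichmentResult:
    set_name: str
    annotation: str
    observed: float
    perm_mean: float
    fold: float
    p: float
    n_candidates: int
    n_perm: int


def _maf_bins(maf: np.ndarray, width: float = 0.02) -> np.ndarray:
    return np.clip((maf / width).astype(int), 0, int(0.5 / width))


def _null_draws(candidate_idx, maf, n_perm, rng, maf_match):
    n_all = len(maf)
    k = len(candidate_idx)
    if not maf_match:
        return np.array([rng.choice(n_all, k, replace=False) for _ in range(n_perm)])
    bins = _maf_bins(maf)
    cand_bins = bins[candidate_idx]
    pools = {b: np.where(bins == b)[0] for b in np.unique(cand_bins)}
    counts = {b: int((cand_bins == b).sum()) for b in pools}
    draws = np.empty((n_perm, k), dtype=int)
    for t in range(n_perm):
        parts = [
            rng.choice(pools[b], min(c, len(pools[b])), replace=False)
            for b, c in counts.items()
        ]
        d = np.concatenate(parts)
        if len(d) < k:  # pad from the full pool if a bin ran short
            extra = rng.choice(n_all, k - len(d), replace=False)
            d = np.concatenate([d, extra])
        draws[t] = d[:k]
    return draws


def _two_sided_p(obs, null):
    """Two-sided empirical p around the permutation mean, mid-p ties.

    Overlap proportions are discrete, so the tie atoms at
    |perm - E| = |obs - E| are counted with weight 1/2; counting them
    fully makes the null p distribution visibly conservative.
    """
    e = null.mean()
    d = np.abs(null - e)
    od = abs(obs - e)
    greater = (d > od + 1e-12).sum()
    ties = np.isclose(d, od, atol=1e-12).sum()
    return float((1 + greater + 0.5 * ties) / (len(null) + 1))


def interval_enrichment(
    candidate_ids,
    panel: HaplotypePanel,
    track: IntervalTrack,
    n_perm: int = 1000,
    maf_match: bool = True,
    seed: int = 0,
    set_name: str = "candidates",
) -> EnrichmentResult:
    """Enrichment of a candidate variant subset inside a BED track.

    Candidates must be a subset of the panel's variants.  Two-sided
    empirical p: (1 + #{|perm - E| >= |obs - E|}) / (n_perm + 1).
    """
    if len(track) == 0:
        raise ValueError("annotation track is empty")
    ids = panel.variants["id"].to_numpy()
    cand = np.where(np.isin(ids, np.asarray(candidate_ids)))[0]
    if len(cand) == 0:
        return EnrichmentResult(set_name, track.name, np.nan, np.nan, np.nan, np.nan, 0, n_perm)
    chroms = panel.variants["chrom"].to_numpy()
    pos0 = panel.variants["pos"].to_numpy() - 1  # 0-based for interval lookup
    inside = track.contains(chroms, pos0)
    maf = panel.variants["maf"].to_numpy()
    rng = np.random.default_rng(seed)
    obs = inside[cand].mean()
    draws = _null_draws(cand, maf, n_perm, rng, maf_match)
    null = inside[draws].mean(axis=1)
    e = null.mean()
    fold = float(obs / e) if e > 0 else np.inf
    return EnrichmentResult(
        set_name, track.name, float(obs), float(e), fold, _two_sided_p(obs, null),
        len(cand), n_perm,
    )


def gwas_in_eqtl_enrichment(
    candidate_ids,
    evariant_ids,
    panel: HaplotypePanel,
    n_perm: int = 1000,
    maf_match: bool = True,
    seed: int = 0,
    set_name: str = "gwas",
) -> EnrichmentResult:
    """Enrichment of GWAS candidates within the eVariant id set
    (set membership instead of interval overlap)."""
    ids = panel.variants["id"].to_numpy()
    member = np.isin(ids, np.asarray(list(evariant_ids)))
    cand = np.where(np.isin(ids, np.asarray(candidate_ids)))[0]
    if len(cand) == 0:
        return EnrichmentResult(set_name, "eVariants", np.nan, np.nan, np.nan, np.nan, 0, n_perm)
    maf = panel.variants["maf"].to_numpy()
    rng = np.random.default_rng(seed)
    obs = member[cand].mean()
    draws = _null_draws(cand, maf, n_perm, rng, maf_match)
    null = member[draws].mean(axis=1)
    e = null.mean()
    fold = float(obs / e) if e > 0 else np.inf
    return EnrichmentResult(
        set_name, "eVariants", float(obs), float(e), fold, _two_sided_p(obs, null),
        len(cand), n_perm,
    )


def _tad_index(tads: IntervalTrack):
    by_chrom = {}
    for chrom, grp in tads.intervals.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("TADs must be non-overlapping within a chromosome")
        by_chrom[chrom] = (starts, ends)
    return by_chrom


def _which_tad(by_chrom, chrom, pos0):
    if chrom not in by_chrom:
        return -1
    starts, ends = by_chrom[chrom]
    i = np.searchsorted(starts, pos0, side="right") - 1
    if i >= 0 and pos0 < ends[i]:
        return i
    return -1


def tad_cooccurrence(
    pairs: pd.DataFrame,
    gene_models: pd.DataFrame,
    panel: HaplotypePanel,
    tads: IntervalTrack,
    n_perm: int = 5000,
    distance_tol_bp: int = 10_000,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Same-TAD co-occurrence of eGene TSSs and their top eVariants.

    ``pairs`` needs columns gene_id, variant_id.  Observed = fraction
    of pairs whose TSS and variant fall in the same TAD.  Each
    permutation replaces every pair's variant by a random tested
    variant at the same |TSS distance| (+/- tolerance, doubled when no
    match exists) from a random gene's TSS.  One-sided empirical
    p = (1 + #{perm >= obs}) / (n_perm + 1).

    Returns (observed, null distribution, p).
    """
    rng = np.random.default_rng(seed)
    by_chrom = _tad_index(tads)
    tss = dict(zip(gene_models["gene_id"], zip(gene_models["chrom"], gene_models["tss"])))
    vmeta = panel.variants.set_index("id")
    pos_by_chrom = {
        c: grp["pos"].to_numpy() - 1 for c, grp in panel.variants.groupby("chrom")
    }

    def same_tad(chrom_g, p_g, chrom_v, p_v):
        if chrom_g != chrom_v:
            return False
        i = _which_tad(by_chrom, chrom_g, p_g)
        return i >= 0 and i == _which_tad(by_chrom, chrom_v, p_v)

    obs_hits, dists = [], []
    for r in pairs.itertuples(index=False):
        chrom_g, tss_g = tss[r.gene_id]
        row = vmeta.loc[r.variant_id]
        p_v = int(row["pos"]) - 1
        obs_hits.append(same_tad(chrom_g, tss_g, row["chrom"], p_v))
        dists.append(abs(p_v - tss_g))
    obs = float(np.mean(obs_hits))

    gm = gene_models.reset_index(drop=True)
    null = np.zeros(n_perm)
    for i, d in enumerate(dists):
        gene_draws = rng.integers(0, len(gm), n_perm)
        hits = np.zeros(n_perm, dtype=bool)
        cache: dict[tuple[int, int], np.ndarray] = {}
        for t in range(n_perm):
            gi = int(gene_draws[t])
            chrom_g = gm.at[gi, "chrom"]
            tss_g = int(gm.at[gi, "tss"])
            tol = distance_tol_bp
            cand = None
            while cand is None or len(cand) == 0:
                key = (gi, tol)
                if key in cache:
                    cand = cache[key]
                else:
                    p = pos_by_chrom.get(chrom_g, np.empty(0, dtype=int))
                    dd = np.abs(np.abs(p - tss_g) - d)
                    cand = p[dd <= tol]
                    cache[key] = cand
                if len(cand) == 0:
                    tol *= 2  # no distance-matched variant: widen, logged upstream
                    if tol > 10**9:
                        cand = pos_by_chrom.get(chrom_g, np.empty(0, dtype=int))
                        break
            pv = int(cand[rng.integers(0, len(cand))]) if len(cand) else tss_g
            hits[t] = same_tad(chrom_g, tss_g, chrom_g, pv)
        null += hits
    null /= max(len(dists), 1)
    p = float((1 + (null >= obs - 1e-12).sum()) / (n_perm + 1))
    return obs, null, p
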