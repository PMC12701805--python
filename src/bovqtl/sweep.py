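"""Extended haplotype homozygosity (EHH) and the integrated haplotype
score (iHS) sweep scan.

EHH at distance x from a core allele is the probability that two
randomly drawn carrier haplotypes are identical over all markers
between the core and x.  iHH is the area under the EHH curve (trapezoid
rule over physical distance) integrated outward in both directions
until EHH decays below a cutoff; the unstandardized score is
ln(iHH_ancestral / iHH_derived), standardized to mean 0 / sd 1 within
derived-allele-frequency bins.  Candidate sweep windows are
non-overlapping 50-kb tiles whose mean |iHS| falls in the genome-wide
top 1% and which hold more than 10 scored SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .core import HaplotypePanel

__all__ = ["ehh", "ihs_scan", "standardize_ihs", "call_sweep_windows"]


@njit(cache=True)
def _walk_ihh(haps, carrier_idx, pos, core, direction, cutoff, max_gap):
    """Trapezoid iHH on one side of the core for one carrier class.

    Returns -1.0 when the walk must be skipped (over-long gap, or the
    chromosome ends before EHH decays below the cutoff).
    """
    n = carrier_idx.shape[0]
    m = haps.shape[1]
    denom = n * (n - 1) / 2.0
    group = np.zeros(n, np.int64)
    n_groups = 1
    prev_d = 0.0
    prev_e = 1.0
    ihh = 0.0
    prev_pos = pos[core]
    j = core + direction
    while 0 <= j < m:
        pj = pos[j]
        gap = pj - prev_pos if pj > prev_pos else prev_pos - pj
        if gap > max_gap:
            return -1.0
        counts = np.zeros(2 * n_groups, np.int64)
        for i in range(n):
            counts[group[i] * 2 + haps[carrier_idx[i], j]] += 1
        pairs = 0.0
        for k in range(2 * n_groups):
            pairs += counts[k] * (counts[k] - 1)
        e = pairs / 2.0 / denom
        d = float(pj - pos[core] if pj > pos[core] else pos[core] - pj)
        ihh += 0.5 * (prev_e + e) * (d - prev_d)
        if e < cutoff:
            return ihh
        relabel = np.empty(2 * n_groups, np.int64)
        ng = 0
        for k in range(2 * n_groups):
            if counts[k] > 0:
                relabel[k] = ng
                ng += 1
        for i in range(n):
            group[i] = relabel[group[i] * 2 + haps[carrier_idx[i], j]]
        n_groups = ng
        if n_groups == n:
            return ihh
        prev_d = d
        prev_e = e
        prev_pos = pj
        j += direction
    return -1.0


def _ehh_values(carriers: np.ndarray, order: np.ndarray) -> np.ndarray:
    """EHH at each successive marker (columns of ``carriers`` in walk order).

    ``carriers`` is (n_hap, n_markers) in chromosome order; ``order``
    indexes the markers in the order they are visited walking away from
    the core.  Haplotypes are grouped by their growing allele prefix;
    EHH_k = sum_h C(n_h, 2) / C(n_a, 2).
    """
    n = carriers.shape[0]
    denom = n * (n - 1) / 2
    group = np.zeros(n, dtype=np.int64)
    out = np.empty(len(order))
    for k, j in enumerate(order):
        key = group * 2 + carriers[:, j]
        _, group, counts = np.unique(key, return_inverse=True, return_counts=True)
        out[k] = (counts * (counts - 1) / 2).sum() / denom
    return out


def ehh(
    panel_or_haps,
    core: int,
    allele: int,
    direction: str,
) -> list[tuple[int, float]]:
    """EHH curve for one core allele in one direction.

    Parameters
    ----------
    panel_or_haps
        A :class:`HaplotypePanel` or a (n_hap, M) 0/1 matrix.
    core
        Column index of the core variant.
    allele
        0 (ancestral) or 1 (derived); carriers are rows with this
        allele at the core.
    direction
        ``"left"`` or ``"right"``.

    Returns ``[(distance_bp, EHH), ...]`` starting at (0, 1.0).  Fewer
    than two carriers leaves EHH undefined and raises ValueError.
    """
    if isinstance(panel_or_haps, HaplotypePanel):
        haps = panel_or_haps.haplotypes
        pos = panel_or_haps.variants["pos"].to_numpy()
    else:
        haps = np.asarray(panel_or_haps)
        pos = np.arange(haps.shape[1])
    carriers = haps[haps[:, core] == allele]
    if carriers.shape[0] < 2:
        raise ValueError("fewer than two carrier haplotypes")
    if direction == "right":
        order = np.arange(core + 1, haps.shape[1])
    elif direction == "left":
        order = np.arange(core - 1, -1, -1)
    else:
        raise ValueError("direction must be 'left' or 'right'")
    vals = _ehh_values(carriers, order)
    dist = np.abs(pos[order] - pos[core])
    return [(0, 1.0)] + list(zip(dist.tolist(), vals.tolist()))




def ihs_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    max_gap_bp: int = 800_000,
) -> pd.DataFrame:
    """Unstandardized iHS for every eligible core SNP.

    The ancestral allele is taken from the panel's AA annotation (REF
    by construction in the simulator, i.e. allele 0 is ancestral).
    Cores whose EHH hits a gap larger than ``max_gap_bp`` or reaches a
    chromosome end before decaying below ``ehh_cutoff`` are skipped.

    Returns a table chrom, pos, id, daf, ihh_a, ihh_d, unihs (NaN for
    skipped cores).
    """
    if (panel.haplotypes < 0).any():
        raise ValueError("iHS requires a fully phased, non-missing panel")
    variants = panel.variants
    # alleles are stored relative to REF; AA == REF means allele 0 ancestral
    anc_is_ref = (variants["aa"] == variants["ref"]).to_numpy()
    rows = []
    for chrom in variants["chrom"].unique():
        m = (variants["chrom"] == chrom).to_numpy()
        idx = np.where(m)[0]
        haps = np.ascontiguousarray(panel.haplotypes[:, idx])
        pos = variants["pos"].to_numpy()[idx].astype(np.int64)
        freq1 = haps.mean(axis=0)
        ids = variants["id"].to_numpy()[idx]
        for j in range(len(idx)):
            anc = 0 if anc_is_ref[idx[j]] else 1
            daf = 1 - freq1[j] if anc == 1 else freq1[j]
            maf = min(freq1[j], 1 - freq1[j])
            if maf < maf_min:
                continue
            ihh = {}
            for allele, tag in ((anc, "a"), (1 - anc, "d")):
                carrier_idx = np.where(haps[:, j] == allele)[0]
                if len(carrier_idx) < 2:
                    ihh = None
                    break
                left = _walk_ihh(haps, carrier_idx, pos, j, -1, ehh_cutoff, max_gap_bp)
                right = _walk_ihh(haps, carrier_idx, pos, j, 1, ehh_cutoff, max_gap_bp)
                if left < 0 or right < 0:
                    ihh = None
                    break
                ihh[tag] = left + right
            if ihh is None or ihh["a"] <= 0 or ihh["d"] <= 0:
                continue
            rows.append(
                (
                    chrom,
                    int(pos[j]),
                    ids[j],
                    float(daf),
                    ihh["a"],
                    ihh["d"],
                    float(np.log(ihh["a"] / ihh["d"])),
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "daf", "ihh_a", "ihh_d", "unihs"]
    )


def standardize_ihs(scores: pd.DataFrame, n_bins: int = 100) -> pd.DataFrame:
    """Standardize iHS within equal-width DAF bins.

    Bins holding fewer than two scores are merged with their nearest
    occupied neighbour; within each (merged) bin, score -> (score -
    mean) / sd.  All scores in one zero-variance bin is an error.
    """
    out = scores.copy()
    daf = out["daf"].to_numpy()
    bins = np.clip((daf * n_bins).astype(int), 0, n_bins - 1)
    # merge sparse bins into the next occupied neighbour (rightward, then left)
    uniq, counts = np.unique(bins, return_counts=True)
    mapping = {}
    i = 0
    while i < len(uniq):
        b, c = uniq[i], counts[i]
        group = [b]
        while c < 2 and i + 1 < len(uniq):
            i += 1
            group.append(uniq[i])
            c += counts[i]
        if c < 2 and mapping:
            # trailing sparse bin: merge left
            last = mapping[uniq[i - len(group)]] if i - len(group) >= 0 else None
            tgt = last if last is not None else group[0]
            for g in group:
                mapping[g] = tgt
        else:
            for g in group:
                mapping[g] = group[0]
        i += 1
    merged = np.array([mapping[b] for b in bins])
    z = np.full(len(out), np.nan)
    for b in np.unique(merged):
        m = merged == b
        mu = out.loc[m, "unihs"].mean()
        sd = out.loc[m, "unihs"].std(ddof=0)
        if sd == 0:
            if m.all():
                raise ValueError("all scores fall in one degenerate bin with zero sd")
            sd = np.nan
        z[m] = (out.loc[m, "unihs"] - mu) / sd
    out["ihs"] = z
    return out


def call_sweep_windows(
    scores: pd.DataFrame,
    window_bp: int = 50_000,
    top_frac: float = 0.01,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Non-overlapping window tiling with top-1% mean |iHS| candidate calls.

    Windows tile each chromosome from position 0; the window statistic
    is the mean |standardized iHS| over its SNPs.  The top fraction is
    taken over windows holding at least one SNP (int(n * top_frac)
    highest-statistic windows), and candidates additionally require
    strictly more than ``min_snps`` SNPs.
    """
    df = scores.dropna(subset=["ihs"]).copy()
    df["window"] = (df["pos"] - 1) // window_bp
    grp = df.groupby(["chrom", "window"])
    win = grp["ihs"].agg(lambda v: np.abs(v).mean()).rename("mean_abs_ihs").reset_index()
    win["n_snps"] = grp.size().values
    win["start"] = win["window"] * window_bp
    win["end"] = win["start"] + window_bp
    n_top = int(len(win) * top_frac)
    order = np.argsort(-win["mean_abs_ihs"].to_numpy(), kind="stable")
    top = np.zeros(len(win), dtype=bool)
    top[order[:n_top]] = True
    win["top_1pct"] = top
    win["candidate"] = top & (win["n_snps"] > min_snps)
    return win[["chrom", "start", "end", "n_snps", "mean_abs_ihs", "top_1pct", "candidate"]]
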