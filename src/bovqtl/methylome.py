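"""CpG-island scanning, experimentally supported CGI filtering, and
hypomethylated-region (HMR) segmentation.

Computational CpG islands (cCGIs) are found by a slide-merge-trim scan
with the standard thresholds: length >= 500 bp, GC content >= 0.55 and
observed/expected CpG ratio >= 0.65 with Exp = (#C * #G) / L.  A cCGI
is experimentally supported (eCGI) when at least five CpG sites with
coverage above 5x show a weighted mean methylation below 30% in at
least one WGBS sample.  HMRs are called per sample by a two-state
hidden Markov model with beta-binomial emissions on (methylated,
coverage) counts at CpGs with >= 10x coverage, trained by Baum-Welch
and decoded by posterior state; hypo-state runs are split wherever the
gap between consecutive CpGs exceeds a desert limit (10 kb default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import IntervalTrack

__all__ = ["cgi_scan", "ecgi_filter", "hmr_call", "HmrModel"]


# ---------------------------------------------------------------------------
# CpG islands from sequence


def _criteria(n_c, n_g, n_cpg, length):
    if length <= 0:
        return False
    gc = (n_c + n_g) / length
    exp = n_c * n_g / length
    oe = n_cpg / exp if exp > 0 else 0.0
    return gc >= 0.55 and oe >= 0.65


def cgi_scan(
    sequence_by_chrom: dict[str, str],
    window: int = 500,
    step: int = 100,
    min_len: int = 500,
) -> IntervalTrack:
    """Sliding-window CpG-island scan (slide, merge, trim).

    500-bp windows at 100-bp steps are marked when GC >= 0.55 and
    ObsCpG/ExpCpG >= 0.65 (inclusive); overlapping marked windows are
    merged, and each merged region is trimmed in 10-bp steps from both
    ends until the whole region meets both criteria at length >= 500,
    otherwise discarded.  N bases count as non-GC.
    """
    rows = []
    for chrom, seq in sequence_by_chrom.items():
        seq = seq.upper()
        arr = np.frombuffer(seq.encode(), dtype="S1")
        L = len(arr)
        if L < window:
            continue
        is_c = (arr == b"C").astype(np.int64)
        is_g = (arr == b"G").astype(np.int64)
        is_cpg = np.zeros(L, dtype=np.int64)
        is_cpg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")
        cum_c = np.concatenate([[0], np.cumsum(is_c)])
        cum_g = np.concatenate([[0], np.cumsum(is_g)])
        cum_p = np.concatenate([[0], np.cumsum(is_cpg)])

        starts = np.arange(0, L - window + 1, step)
        n_c = cum_c[starts + window] - cum_c[starts]
        n_g = cum_g[starts + window] - cum_g[starts]
        n_p = cum_p[starts + window] - cum_p[starts]
        gc = (n_c + n_g) / window
        exp = n_c * n_g / window
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(exp > 0, n_p / np.where(exp > 0, exp, 1), 0.0)
        marked = (gc >= 0.55) & (oe >= 0.65)

        # merge overlapping marked windows
        regions = []
        cur = None
        for s in starts[marked]:
            e = s + window
            if cur is None:
                cur = [s, e]
            elif s <= cur[1]:
                cur[1] = e
            else:
                regions.append(tuple(cur))
                cur = [s, e]
        if cur is not None:
            regions.append(tuple(cur))

        def region_ok(s, e):
            return _criteria(
                cum_c[e] - cum_c[s], cum_g[e] - cum_g[s], cum_p[e] - cum_p[s], e - s
            )

        for s, e in regions:
            # trim 10-bp steps alternately from each end
            while e - s >= min_len and not region_ok(s, e):
                if not region_ok(s + 10, e - 10):
                    # shrink the worse end first: try each
                    if region_ok(s + 10, e):
                        s += 10
                        continue
                    if region_ok(s, e - 10):
                        e -= 10
                        continue
                s += 10
                e -= 10
            if e - s >= min_len and region_ok(s, e):
                rows.append((chrom, int(s), int(e), "cCGI"))
    return IntervalTrack("cCGI", pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


# ---------------------------------------------------------------------------
# Experimentally supported CGIs


def ecgi_filter(
    ccgis: IntervalTrack,
    cpg_by_sample: dict[str, pd.DataFrame],
    min_sites: int = 5,
    min_cov: int = 5,
    meth_max: float = 0.30,
) -> IntervalTrack:
    """Keep cCGIs with low methylation support in at least one sample.

    A cCGI qualifies when some sample shows >= ``min_sites`` CpGs at
    coverage > ``min_cov`` inside it whose coverage-weighted mean
    methylation (sum meth / sum cov) is below ``meth_max``.
    """
    rows = []
    for iv in ccgis.intervals.itertuples(index=False):
        supported = False
        for tbl in cpg_by_sample.values():
            m = (
                (tbl["chrom"] == iv.chrom)
                & (tbl["pos"] >= iv.start)
                & (tbl["pos"] < iv.end)
                & (tbl["coverage"] > min_cov)
            )
            sub = tbl.loc[m]
            if len(sub) < min_sites:
                continue
            level = sub["methylated"].sum() / sub["coverage"].sum()
            if level < meth_max:
                supported = True
                break
        if supported:
            rows.append((iv.chrom, iv.start, iv.end, "eCGI"))
    return IntervalTrack("eCGI", pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


# ---------------------------------------------------------------------------
# HMR segmentation


@dataclass
class HmrModel:
    """Two-state (hypo, hyper) beta-binomial HMM."""

    alpha: np.ndarray  # per-state alpha
    beta: np.ndarray  # per-state beta
    trans: np.ndarray  # 2x2 row-stochastic
    start: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    loglik_path: list[float] = field(default_factory=list)

    def state_means(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)


def _bb_logpmf(k, n, a, b):
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + special.betaln(k + a, n - k + b)
        - special.betaln(a, b)
    )


def _weighted_bb_mle(k, n, w, a0, b0):
    """Maximize sum w * log BetaBinom(k; n, a, b) over (a, b).

    The search is bounded in log space: unbounded concentrations drive
    betaln into a regime where cancellation error fabricates positive
    "log-likelihoods" and collapses the HMM.
    """
    lo, hi = np.log(1e-2), np.log(1e3)

    def nll(theta):
        a, b = np.exp(np.clip(theta, lo, hi))
        return -float((w * _bb_logpmf(k, n, a, b)).sum())

    res = optimize.minimize(
        nll, np.clip(np.log([a0, b0]), lo, hi), method="Nelder-Mead",
        bounds=[(lo, hi), (lo, hi)],
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200},
    )
    a, b = np.exp(np.clip(res.x, lo, hi))
    return float(a), float(b)


def _forward_backward(loge, log_trans, log_start):
    T, S = loge.shape
    la = np.empty((T, S))
    lb = np.empty((T, S))
    la[0] = log_start + loge[0]
    for t in range(1, T):
        la[t] = loge[t] + special.logsumexp(la[t - 1][:, None] + log_trans, axis=0)
    lb[-1] = 0.0
    for t in range(T - 2, -1, -1):
        lb[t] = special.logsumexp(log_trans + (loge[t + 1] + lb[t + 1])[None, :], axis=1)
    ll = float(special.logsumexp(la[-1]))
    gamma = np.exp(la + lb - ll)
    return la, lb, gamma, ll


def fit_hmr_model(
    meth: np.ndarray,
    cov: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-4,
) -> tuple[HmrModel, np.ndarray]:
    """Baum-Welch training with fixed initialization.

    Init: hypo mean 0.1, hyper mean 0.8 (concentration 10),
    self-transition 0.9.  The per-iteration log-likelihood is recorded
    and is non-decreasing up to M-step numerical tolerance.  Returns
    the model and the posterior probability of the hypo state.
    """
    k = np.asarray(meth, dtype=float)
    n = np.asarray(cov, dtype=float)
    a = np.array([1.0, 8.0])
    b = np.array([9.0, 2.0])
    trans = np.array([[0.9, 0.1], [0.1, 0.9]])
    start = np.array([0.5, 0.5])
    lls: list[float] = []
    gamma = None
    for _ in range(max_iter):
        loge = np.stack([_bb_logpmf(k, n, a[s], b[s]) for s in range(2)], axis=1)
        la, lb, gamma, ll = _forward_backward(loge, np.log(trans), np.log(start))
        if lls and abs(ll - lls[-1]) < tol:
            lls.append(ll)
            break
        lls.append(ll)
        # M-step: transitions
        T = len(k)
        lxi = (
            la[:-1, :, None]
            + np.log(trans)[None, :, :]
            + (loge[1:] + lb[1:])[:, None, :]
            - ll
        )
        xi = np.exp(special.logsumexp(lxi, axis=0))
        trans = xi / xi.sum(axis=1, keepdims=True)
        start = gamma[0] / gamma[0].sum()
        start = np.clip(start, 1e-6, 1)
        start /= start.sum()
        # M-step: emissions
        for s in range(2):
            a[s], b[s] = _weighted_bb_mle(k, n, gamma[:, s], a[s], b[s])
        # keep state 0 the hypomethylated one
        if a[0] / (a[0] + b[0]) > a[1] / (a[1] + b[1]):
            a, b = a[::-1].copy(), b[::-1].copy()
            trans = trans[::-1, ::-1].copy()
            start = start[::-1].copy()
            gamma = gamma[:, ::-1]
    model = HmrModel(a, b, trans, start, lls)
    return model, gamma[:, 0]


def hmr_call(
    cpg_by_sample: dict[str, pd.DataFrame],
    min_coverage: int = 10,
    desert_bp: int = 10_000,
    max_iter: int = 30,
    merge_samples: bool = True,
) -> tuple[IntervalTrack, dict[str, IntervalTrack], dict[str, HmrModel]]:
    """HMR segmentation per sample, plus the merged (union) track.

    CpGs below ``min_coverage`` are dropped before training; fewer
    than 50 usable sites raises.  HMRs are maximal runs of
    posterior-hypo CpGs, split wherever the gap between consecutive
    CpGs exceeds ``desert_bp``; the interval spans the first to last
    CpG of the run (half-open at last CpG + 2 to cover the dinucleotide).
    """
    per_sample: dict[str, IntervalTrack] = {}
    models: dict[str, HmrModel] = {}
    cols = ["chrom", "start", "end", "label"]
    for name, tbl in cpg_by_sample.items():
        rows = []
        for chrom, grp in tbl.groupby("chrom"):
            grp = grp.sort_values("pos")
            grp = grp[grp["coverage"] >= min_coverage]
            if len(grp) < 50:
                raise ValueError(
                    f"sample {name} chrom {chrom}: fewer than 50 CpGs at "
                    f">={min_coverage}x coverage"
                )
            pos = grp["pos"].to_numpy()
            model, p_hypo = fit_hmr_model(
                grp["methylated"].to_numpy(), grp["coverage"].to_numpy(),
                max_iter=max_iter,
            )
            models[f"{name}:{chrom}"] = model
            hypo = p_hypo > 0.5
            i = 0
            while i < len(pos):
                if not hypo[i]:
                    i += 1
                    continue
                j = i
                while (
                    j + 1 < len(pos)
                    and hypo[j + 1]
                    and pos[j + 1] - pos[j] <= desert_bp
                ):
                    j += 1
                rows.append((chrom, int(pos[i]), int(pos[j]) + 2, "HMR"))
                i = j + 1
        per_sample[name] = IntervalTrack(f"HMR:{name}", pd.DataFrame(rows, columns=cols))
    if merge_samples:
        allint = pd.concat([t.intervals for t in per_sample.values()], ignore_index=True)
        merged = IntervalTrack("HMR:merged", allint).merged()
    else:
        merged = IntervalTrack("HMR:merged", pd.DataFrame(columns=cols))
    return merged, per_sample, models
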