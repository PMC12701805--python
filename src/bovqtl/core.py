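"""Core in-memory containers shared across the pipeline.

The two central objects are :class:`HaplotypePanel` (phased diploid
genotypes plus per-variant metadata) and :class:`IntervalTrack` (named
genomic intervals with BED semantics).  All internal coordinates are
0-based half-open; the VCF/BED writers and readers convert to and from
the 1-based (VCF) and 0-based (BED) on-disk conventions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "IntervalTrack",
    "substream",
    "spawn_rng",
]


def substream(seed: int, name: str) -> int:
    """Derive a named child seed from a global seed.

    The child is a deterministic function of ``(seed, name)`` so that
    toggling one pipeline stage never shifts the random stream of
    another.  The result is kept below 2**31.
    """
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def spawn_rng(seed: int, name: str) -> np.random.Generator:
    """A fresh :class:`numpy.random.Generator` for a named substream."""
    return np.random.default_rng(substream(seed, name))


VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "aa", "dr2", "maf"]


@dataclass
class HaplotypePanel:
    """Phased diploid haplotypes with variant metadata.

    Attributes
    ----------
    samples
        Sample identifiers, length N.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt, aa, dr2, maf``.
        ``pos`` is the 1-based basepair position (VCF convention);
        ``aa`` is the ancestral allele, ``dr2`` an imputation-quality
        score in [0, 1].
    haplotypes
        ``(2N, M)`` int8 matrix of phased alleles in {0, 1}; rows
        ``2i`` and ``2i+1`` are the two haplotypes of sample ``i``.
        Missing alleles are coded -1.
    """

    samples: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError(
                f"haplotype matrix {self.haplotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isin(self.haplotypes, (-1, 0, 1)).all()
        if not ok:
            raise ValueError("haplotype entries must be in {-1, 0, 1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosage(self) -> np.ndarray:
        """``(N, M)`` float dosage matrix; NaN where either allele is missing."""
        h = self.haplotypes
        a, b = h[0::2].astype(float), h[1::2].astype(float)
        d = a + b
        d[(a < 0) | (b < 0)] = np.nan
        return d

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-variant mean."""
        d = self.dosage()
        mean = np.nanmean(d, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        idx = np.where(np.isnan(d))
        d[idx] = mean[idx[1]]
        return d

    def allele_freq(self) -> np.ndarray:
        """ALT allele frequency per variant from non-missing alleles."""
        h = self.haplotypes
        valid = h >= 0
        with np.errstate(invalid="ignore"):
            return np.where(
                valid.sum(0) > 0, (h * valid).sum(0) / valid.sum(0).clip(1), np.nan
            )

    def recompute_maf(self) -> None:
        p = self.allele_freq()
        self.variants = self.variants.assign(maf=np.minimum(p, 1 - p))

    def subset(self, variant_mask=None, sample_idx=None) -> "HaplotypePanel":
        """Panel restricted to a boolean/index variant mask and/or sample index."""
        h = self.haplotypes
        variants = self.variants
        samples = self.samples
        if variant_mask is not None:
            variants = variants.loc[np.asarray(variant_mask)].reset_index(drop=True) \
                if np.asarray(variant_mask).dtype == bool else \
                variants.iloc[np.asarray(variant_mask)].reset_index(drop=True)
            h = h[:, variant_mask]
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            samples = [samples[i] for i in sample_idx]
            rows = np.empty(2 * len(sample_idx), dtype=int)
            rows[0::2] = 2 * sample_idx
            rows[1::2] = 2 * sample_idx + 1
            h = h[rows]
        return HaplotypePanel(samples, variants, h.copy())

    def region(self, chrom: str, start: int | None = None, end: int | None = None):
        """Panel restricted to ``chrom[:start-end]`` (1-based inclusive pos)."""
        m = (self.variants["chrom"] == chrom).to_numpy()
        if start is not None:
            m &= self.variants["pos"].to_numpy() >= start
        if end is not None:
            m &= self.variants["pos"].to_numpy() <= end
        return self.subset(variant_mask=m)


@dataclass
class IntervalTrack:
    """Named genomic intervals, 0-based half-open, sorted within chromosome."""

    name: str
    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "label"]))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end", "label"])
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("interval with start >= end")
        self.intervals = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> "IntervalTrack":
        """Union of overlapping/adjacent intervals (labels dropped)."""
        rows = []
        for chrom, grp in self.intervals.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e, "."))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                rows.append((chrom, cur_s, cur_e, "."))
        return IntervalTrack(self.name, pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))

    def contains(self, chroms, positions) -> np.ndarray:
        """Membership of 0-based positions in the merged track (vectorized)."""
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        out = np.zeros(len(positions), dtype=bool)
        merged = self.merged().intervals
        for chrom, grp in merged.groupby("chrom", sort=False):
            m = chroms == chrom
            if not m.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            idx = np.searchsorted(starts, positions[m], side="right") - 1
            hit = (idx >= 0) & (positions[m] < ends[idx.clip(0)])
            out[np.where(m)[0]] = hit
        return out

    def total_bp(self) -> int:
        m = self.merged().intervals
        return int((m["end"] - m["start"]).sum())
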