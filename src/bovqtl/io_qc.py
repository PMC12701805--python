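"""Standard-format I/O and the variant / expression QC filters.

Genotypes are read from VCF 4.2 via cyvcf2 into a
:class:`~bovqtl.core.HaplotypePanel`.  Variant QC applies, in order,
per-variant call rate, MAF, Hardy-Weinberg equilibrium (1-df chi-square
on genotype counts) and an imputation-quality (DR2-like) filter, each
with the thresholds used for array and imputed-sequence data in large
cattle cohorts.  Expression QC keeps genes detectably expressed (TPM at
or above a floor in a minimum fraction of samples).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

from .core import VARIANT_COLUMNS, HaplotypePanel, IntervalTrack

__all__ = [
    "load_genotypes",
    "write_vcf",
    "variant_qc",
    "QcThresholds",
    "filter_expressed_genes",
    "read_bed",
    "write_bed",
    "read_table",
    "write_table",
]


def _opener(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


# ---------------------------------------------------------------------------
# VCF


def load_genotypes(
    vcf_path,
    region: str | None = None,
    require_phased: bool = True,
) -> HaplotypePanel:
    """Load phased genotypes from a VCF into a :class:`HaplotypePanel`.

    Parameters
    ----------
    vcf_path
        Path to a VCF (optionally bgzipped and indexed when ``region``
        is given on a compressed file).
    region
        Optional ``chrom[:start-end]`` filter (1-based inclusive).
    require_phased
        When True, an unphased heterozygous record raises.

    Missing alleles are stored as -1.  MAF is recomputed from the
    non-missing alleles of the loaded samples.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows, haps = [], []
    chrom = lo = hi = None
    if region:
        chrom, _, span = region.partition(":")
        if span:
            a, _, b = span.partition("-")
            lo, hi = int(a), int(b)
    for var in vcf:
        if region:
            if var.CHROM != chrom:
                continue
            if lo is not None and not (lo <= var.POS <= hi):
                continue
        gts = np.array(var.genotypes, dtype=object)
        if any(len(g) != 3 for g in gts):
            raise ValueError(
                f"mixed-ploidy record at {var.CHROM}:{var.POS} is unsupported"
            )
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int8)
        if require_phased:
            het_unphased = [
                g for g in gts if g[0] != g[1] and g[0] >= 0 and not g[2]
            ]
            if het_unphased:
                raise ValueError(
                    f"unphased heterozygote at {var.CHROM}:{var.POS}"
                )
        aa = var.INFO.get("AA")
        dr2 = var.INFO.get("DR2")
        rows.append(
            (
                var.CHROM,
                var.POS,
                var.ID or f"{var.CHROM}:{var.POS}",
                var.REF,
                var.ALT[0] if var.ALT else ".",
                aa if aa is not None else var.REF,
                float(dr2) if dr2 is not None else 1.0,
                np.nan,
            )
        )
        haps.append(alleles.reshape(-1))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    h = (
        np.array(haps, dtype=np.int8).T
        if haps
        else np.zeros((2 * len(samples), 0), dtype=np.int8)
    )
    panel = HaplotypePanel(samples, variants, h)
    panel.recompute_maf()
    return panel


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as phased VCF 4.2 with INFO keys AA and DR2."""
    path = Path(path)
    h = panel.haplotypes
    n = panel.n_samples
    with _opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, grp in panel.variants.groupby("chrom", sort=True):
            fh.write(
                f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n"
            )
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write(
            '##INFO=<ID=DR2,Number=1,Type=Float,Description='
            '"Estimated imputation dosage r-squared">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        allele_str = np.array([".", "0", "1"])
        a = allele_str[h[0::2].astype(int) + 1]
        b = allele_str[h[1::2].astype(int) + 1]
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            gt = "\t".join(
                a[i, j] + "|" + b[i, j] for i in range(n)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t"
                f"PASS\tAA={row.aa};DR2={row.dr2:.4g}\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# BED and tables


def read_bed(path, name: str | None = None) -> IntervalTrack:
    rows = []
    with _opener(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            label = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return IntervalTrack(name or Path(path).stem, df)


def write_bed(track: IntervalTrack, path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC


@dataclass
class QcThresholds:
    """Variant-QC thresholds.

    ``call_rate_min`` is the per-variant genotype call rate;
    ``sample_call_rate_min`` the per-sample call rate (both of the two
    call-rate criteria used for array QC are exposed separately).
    """

    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.95
    dr2_min: float = 0.8


def hwe_chi2_p(n_rr: np.ndarray, n_ra: np.ndarray, n_aa: np.ndarray) -> np.ndarray:
    """1-df chi-square Hardy-Weinberg test from genotype counts."""
    n_rr, n_ra, n_aa = (np.asarray(x, dtype=float) for x in (n_rr, n_ra, n_aa))
    n = n_rr + n_ra + n_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_rr + n_ra) / (2 * n)
        q = 1 - p
        exp = np.stack([n * p**2, 2 * n * p * q, n * q**2])
        obs = np.stack([n_rr, n_ra, n_aa])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0).sum(0)
    pval = stats.chi2.sf(chi2, df=1)
    # monomorphic sites fit HWE perfectly
    return np.where((p <= 0) | (p >= 1), 1.0, pval)


def variant_qc(
    panel: HaplotypePanel, thresholds: QcThresholds | None = None
) -> tuple[HaplotypePanel, dict[str, int]]:
    """Filter variants, attributing each exclusion to the first failing filter.

    Filters are applied in the order call-rate, MAF, HWE, DR2; the
    returned ledger has one exclusive count per filter plus the number
    retained, and the counts partition the input variants.
    """
    thr = thresholds or QcThresholds()
    d = panel.dosage()
    call_rate = 1 - np.isnan(d).mean(axis=0)
    p = panel.allele_freq()
    maf = np.minimum(p, 1 - p)
    n_rr = np.nansum(d == 0, axis=0)
    n_ra = np.nansum(d == 1, axis=0)
    n_aa = np.nansum(d == 2, axis=0)
    hwe_p = hwe_chi2_p(n_rr, n_ra, n_aa)
    dr2 = panel.variants["dr2"].to_numpy(dtype=float)

    fail_cr = call_rate < thr.call_rate_min
    fail_maf = ~fail_cr & (maf < thr.maf_min)
    fail_hwe = ~fail_cr & ~fail_maf & (hwe_p < thr.hwe_p_min)
    fail_dr2 = ~fail_cr & ~fail_maf & ~fail_hwe & (dr2 < thr.dr2_min)
    keep = ~(fail_cr | fail_maf | fail_hwe | fail_dr2)

    ledger = {
        "call_rate": int(fail_cr.sum()),
        "maf": int(fail_maf.sum()),
        "hwe": int(fail_hwe.sum()),
        "dr2": int(fail_dr2.sum()),
        "retained": int(keep.sum()),
    }
    out = panel.subset(variant_mask=keep)
    out.recompute_maf()
    return out, ledger


def sample_qc(
    panel: HaplotypePanel, call_rate_min: float = 0.95
) -> tuple[HaplotypePanel, int]:
    """Drop samples whose genotype call rate falls below the threshold."""
    d = panel.dosage()
    cr = 1 - np.isnan(d).mean(axis=1)
    keep = np.where(cr >= call_rate_min)[0]
    return panel.subset(sample_idx=keep), int((cr < call_rate_min).sum())


def filter_expressed_genes(
    tpm: pd.DataFrame, tpm_min: float = 0.1, frac_samples: float = 0.20
) -> pd.DataFrame:
    """Keep genes with TPM >= ``tpm_min`` in >= ceil(frac * n_samples) samples.

    ``tpm`` is genes x samples.  Both boundaries are inclusive.
    """
    if tpm.size == 0:
        raise ValueError("empty TPM matrix")
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    need = int(np.ceil(frac_samples * tpm.shape[1]))
    n_ok = (tpm.to_numpy() >= tpm_min).sum(axis=1)
    return tpm.loc[n_ok >= need]
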