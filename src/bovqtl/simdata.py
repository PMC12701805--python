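"""Synthetic cattle-like cohort generator with a known truth manifest.

The simulator emulates the data layers of an integrative body-weight
study — LD-structured phased genotypes with ancestral-allele labels, a
planted partial selective sweep, correlated quantitative traits driven
by a shared pleiotropic causal block plus a polygenic background,
cis-regulated gene expression with hidden batch factors, beta-binomial
CpG methylation with planted hypomethylated regions, a genome sequence
with embedded CpG islands, and TSS-enriched annotation tracks (peaks,
TADs, chromatin states).

Haplotype model: a founder pool of H haplotypes is built by a
first-order Markov chain over sites (the neighbour-copy probability
sets local LD); each individual haplotype is a recombinant mosaic of
founder draws with a per-bp switch probability.  The partial sweep is
planted by making a chosen fraction of haplotypes carry one founder's
alleles unbroken across the sweep interval, which yields the long
shared haplotypes an iHS scan detects.  The ancestral allele equals REF
by construction and is recorded in the AA INFO tag.

Every operation is deterministic given ``SimConfig.seed``: each
component draws from a named substream so that regenerating one layer
never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import VARIANT_COLUMNS, HaplotypePanel, IntervalTrack, spawn_rng
from .io_qc import write_bed, write_table, write_vcf

__all__ = [
    "SimConfig",
    "PleiotropicBlock",
    "SweepConfig",
    "MethylomeConfig",
    "TruthManifest",
    "simulate_haplotypes",
    "simulate_gene_models",
    "simulate_phenotypes",
    "simulate_expression",
    "simulate_methylome",
    "simulate_sequence",
    "simulate_tracks",
    "simulate_cohort",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PleiotropicBlock:
    """A compact genomic block whose variants affect several traits at once.

    The block is narrow by default so its causal variants are
    co-inherited, mimicking a high-LD candidate region where one shared
    signal drives both traits and cis expression.
    """

    chrom: str = "chr1"
    start_bp: int = 4_000_000
    end_bp: int = 4_100_000
    n_causal: int = 5
    effect_scale: float = 0.5
    #: plant a cis-eQTL for the gene nearest the block at the block's first
    #: causal variant, creating a variant -> expression -> trait chain
    link_gene: bool = True
    link_effect: float = 1.0


@dataclass
class SweepConfig:
    """A planted partial sweep: one haplotype driven to high frequency."""

    chrom: str = "chr2"
    core_bp: int = 5_000_000
    final_derived_freq: float = 0.8
    width_bp: int = 500_000


@dataclass
class MethylomeConfig:
    """CpG methylation layer on a subregion of the first chromosome."""

    chrom: str = "chr1"
    region_bp: int = 200_000
    n_cpg: int = 4000
    n_samples: int = 3
    n_islands: int = 12
    n_hmr: int = 6
    island_meth_mean: float = 0.10
    background_meth_mean: float = 0.80
    coverage_mean: float = 20.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults give a desk-scale analogue of a beef-cattle cohort: a few
    hundred individuals, two 10-Mb chromosomes with ~5-kb variant
    spacing, three correlated body-weight-like traits of moderate
    heritability, ~30% of genes carrying a cis-eQTL, and a partial
    sweep on the second chromosome.
    """

    seed: int = 0
    n_individuals: int = 400
    n_chromosomes: int = 2
    variants_per_chrom: int = 2000
    chrom_length_bp: int = 10_000_000
    n_founder_haplotypes: int = 30
    recomb_rate_per_bp: float = 5e-7
    #: autocorrelation of the founder haplotypes' latent chain (sets LD)
    founder_ld_rho: float = 0.9
    n_traits: int = 3
    trait_corr: np.ndarray | None = None
    trait_corr_offdiag: float = 0.6
    n_causal_polygenic: int = 30
    polygenic_effect_sd: float = 0.15
    pleiotropic_block: PleiotropicBlock | None = field(default_factory=PleiotropicBlock)
    trait_h2: float | list[float] = 0.4
    n_genes: int = 300
    gene_length_bp: int = 20_000
    frac_genes_with_eqtl: float = 0.30
    frac_genes_with_second_eqtl: float = 0.0
    eqtl_effect_sd: float = 0.6
    expr_noise_sd: float = 0.5
    expr_baseline_range: tuple[float, float] = (1.0, 6.0)
    n_hidden_factors: int = 2
    hidden_factor_sd: float = 0.4
    n_expression_samples: int | None = None
    sweep: SweepConfig | None = field(default_factory=SweepConfig)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def h2_per_trait(self) -> np.ndarray:
        h2 = self.trait_h2
        arr = np.full(self.n_traits, h2, dtype=float) if np.isscalar(h2) else np.asarray(h2, dtype=float)
        if arr.shape != (self.n_traits,):
            raise ConfigurationError("trait_h2 must be scalar or one value per trait")
        return arr

    def corr_matrix(self) -> np.ndarray:
        if self.trait_corr is not None:
            R = np.asarray(self.trait_corr, dtype=float)
        else:
            R = np.full((self.n_traits, self.n_traits), self.trait_corr_offdiag)
            np.fill_diagonal(R, 1.0)
        return R

    def validate(self) -> None:
        R = self.corr_matrix()
        if R.shape != (self.n_traits, self.n_traits):
            raise ConfigurationError("trait_corr has wrong shape")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ConfigurationError("trait_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ConfigurationError("trait_corr is not positive semi-definite")
        h2 = self.h2_per_trait()
        if ((h2 < 0) | (h2 >= 1)).any():
            raise ConfigurationError("trait_h2 must lie in [0, 1)")
        if self.chrom_length_bp < 10 * self.variants_per_chrom:
            raise ConfigurationError(
                "chrom_length_bp too small for the requested variant count"
            )
        if self.sweep is not None and not (0 < self.sweep.final_derived_freq < 1):
            raise ConfigurationError("sweep.final_derived_freq must lie in (0, 1)")
        if not (0 <= self.frac_genes_with_eqtl <= 1):
            raise ConfigurationError("frac_genes_with_eqtl must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Truth manifest


@dataclass
class TruthManifest:
    """Ground truth planted by the simulator; the parameter-recovery surface.

    Intervals are 0-based half-open.
    """

    causal_variants: list = field(default_factory=list)  # (variant_id, trait, beta)
    eqtl_truth: list = field(default_factory=list)  # (gene_id, variant_id, log2 effect)
    sweep_region: dict | None = None
    hmr_truth: list = field(default_factory=list)  # (chrom, start, end)
    cgi_truth: list = field(default_factory=list)
    hidden_factor_loadings: list = field(default_factory=list)
    hidden_factor_scores: list = field(default_factory=list)
    genetic_values: dict = field(default_factory=dict)  # trait -> per-sample g

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Genotypes


def simulate_haplotypes(config: SimConfig) -> HaplotypePanel:
    """Founder-mosaic phased haplotypes with a planted partial sweep."""
    config.validate()
    rng = spawn_rng(config.seed, "haplotypes")
    n, H = config.n_individuals, config.n_founder_haplotypes
    m = config.variants_per_chrom
    all_chrom, all_pos, all_h = [], [], []
    for chrom in config.chrom_names():
        # evenly spaced positions with jitter, 1-based, unique and sorted
        spacing = config.chrom_length_bp / (m + 1)
        pos = (np.arange(1, m + 1) * spacing
               + rng.uniform(-0.3 * spacing, 0.3 * spacing, m))
        pos = np.maximum.accumulate(np.round(pos).astype(int))
        pos = pos + np.arange(m) // 1_000_000  # safety against ties
        pos = np.unique(pos)
        while len(pos) < m:  # pragma: no cover - jitter rarely collides
            extra = rng.integers(1, config.chrom_length_bp, m - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        pos = pos[:m]

        # founder pool: first-order chain via a latent Gaussian AR(1) per
        # founder, thresholded at the per-site target frequency.  The
        # autocorrelation sets LD between neighbouring sites while the
        # thresholding preserves each site's marginal allele frequency.
        target_freq = rng.uniform(0.05, 0.95, m)
        rho = config.founder_ld_rho
        eps = rng.standard_normal((H, m))
        z = np.empty((H, m))
        z[:, 0] = eps[:, 0]
        scale = np.sqrt(1 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
        from scipy.stats import norm as _norm

        founders = (z < _norm.ppf(target_freq)[None, :]).astype(np.int8)

        # individual haplotypes: recombinant mosaics of founders
        n_hap = 2 * n
        gaps = np.diff(pos, prepend=pos[0])
        switch_p = 1 - np.exp(-config.recomb_rate_per_bp * gaps)
        switch = rng.random((n_hap, m)) < switch_p[None, :]
        switch[:, 0] = True
        draws = rng.integers(0, H, (n_hap, m))
        source = np.empty((n_hap, m), dtype=np.int64)
        cur = draws[:, 0]
        for j in range(m):
            cur = np.where(switch[:, j], draws[:, j], cur)
            source[:, j] = cur
        haps = founders[source, np.arange(m)[None, :]]

        if config.sweep is not None and chrom == config.sweep.chrom:
            haps = _plant_sweep(haps, founders, pos, config, rng)

        all_chrom.append(np.full(m, chrom, dtype=object))
        all_pos.append(pos)
        all_h.append(haps)

    chroms = np.concatenate(all_chrom)
    positions = np.concatenate(all_pos)
    haps = np.concatenate(all_h, axis=1)

    # ascertainment: emitted variants are polymorphic in the cohort, as a
    # cohort-discovered call set would be; fix rare all-0/all-1 draws by
    # flipping one haplotype (a singleton)
    freq = haps.mean(axis=0)
    mono = np.where((freq == 0) | (freq == 1))[0]
    if len(mono):
        rows = rng.integers(0, haps.shape[0], len(mono))
        haps[rows, mono] = 1 - haps[rows, mono]

    # allele labels: ancestral = REF by construction
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, len(positions))
    ref = bases[ref_idx]
    alt = bases[(ref_idx + rng.integers(1, 4, len(positions))) % 4]
    dr2 = np.round(rng.beta(20, 1.5, len(positions)), 4)

    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions.astype(int),
            "id": [f"rs{i + 1:07d}" for i in range(len(positions))],
            "ref": ref,
            "alt": alt,
            "aa": ref,
            "dr2": dr2,
            "maf": np.nan,
        },
        columns=VARIANT_COLUMNS,
    )
    samples = [f"ind{i + 1:05d}" for i in range(n)]
    panel = HaplotypePanel(samples, variants, haps)
    panel.recompute_maf()
    return panel


def _plant_sweep(haps, founders, pos, config: SimConfig, rng) -> np.ndarray:
    """Drive one founder haplotype to the target frequency over the interval."""
    sw = config.sweep
    core = int(np.argmin(np.abs(pos - sw.core_bp)))
    lo, hi = sw.core_bp - sw.width_bp // 2, sw.core_bp + sw.width_bp // 2
    in_iv = (pos >= lo) & (pos <= hi)
    founders = founders.copy()
    founders[:, core] = 0
    founders[0, core] = 1  # founder 0 carries the derived core allele
    n_hap = haps.shape[0]
    k = int(round(n_hap * sw.final_derived_freq))
    carriers = rng.choice(n_hap, size=k, replace=False)
    haps = haps.copy()
    haps[:, core] = 0
    haps[np.ix_(carriers, np.where(in_iv)[0])] = founders[0, in_iv]
    haps[carriers, core] = 1
    return haps


# ---------------------------------------------------------------------------
# Gene models


def simulate_gene_models(config: SimConfig) -> pd.DataFrame:
    """Gene bodies placed uniformly along the chromosomes."""
    rng = spawn_rng(config.seed, "genes")
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    gid = 0
    margin = 200_000
    for chrom, k in zip(config.chrom_names(), per_chrom):
        starts = np.sort(
            rng.integers(margin, config.chrom_length_bp - margin - config.gene_length_bp, k)
        )
        for s in starts:
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            e = s + config.gene_length_bp
            tss = s if strand == "+" else e
            rows.append((f"gene{gid:04d}", chrom, int(s), int(e), int(tss), strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "tss", "strand"])


# ---------------------------------------------------------------------------
# Phenotypes


def _block_causal_indices(panel: HaplotypePanel, config: SimConfig) -> np.ndarray:
    """Causal-variant indices of the pleiotropic block (shared stream).

    Drawn from a substream keyed only on the seed so the phenotype and
    expression layers agree on which block variants are causal.
    """
    blk = config.pleiotropic_block
    if blk is None or blk.n_causal == 0:
        return np.array([], dtype=int)
    rng = spawn_rng(config.seed, "block_causals")
    maf = panel.variants["maf"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    eligible = np.where(
        (maf >= 0.10)
        & (chrom == blk.chrom)
        & (pos >= blk.start_bp)
        & (pos <= blk.end_bp)
    )[0]
    if len(eligible) < blk.n_causal:
        raise ConfigurationError("pleiotropic block holds too few eligible variants")
    chosen = rng.choice(eligible, blk.n_causal, replace=False)
    chosen.sort()
    return chosen


def _block_lead_index(panel: HaplotypePanel, config: SimConfig) -> int | None:
    """The block's mechanism lead: its highest-MAF causal variant.

    The lead carries the block's dominant trait effect and, when the
    block is linked to a gene, its planted cis-eQTL — the shape of a
    colocalisable GWAS/eQTL locus.  Choosing the best-powered (highest
    2p(1-p)) causal keeps the lead the top association signal of its
    locus rather than losing that rank to a commoner neighbour.
    """
    causals = _block_causal_indices(panel, config)
    if len(causals) == 0:
        return None
    maf = panel.variants["maf"].to_numpy()[causals]
    return int(causals[np.argmax(maf * (1 - maf))])


def simulate_phenotypes(
    panel: HaplotypePanel, config: SimConfig
) -> tuple[pd.DataFrame, list, dict]:
    """Correlated traits from a pleiotropic block plus polygenic background.

    Each trait t is y_t = sum_k x_k beta_kt + eps_t plus farm/sex fixed
    effects; cross-trait effect and residual correlation both follow
    ``trait_corr``, and the residual scale is set so the realized
    genetic/total variance ratio matches ``trait_h2``.

    Returns the phenotype/covariate table, the causal-variant truth
    list and the per-trait genetic values.
    """
    config.validate()
    rng = spawn_rng(config.seed, "phenotypes")
    n, T = panel.n_samples, config.n_traits
    R = config.corr_matrix()
    L = np.linalg.cholesky(R + 1e-10 * np.eye(T))
    h2 = config.h2_per_trait()
    dos = panel.imputed_dosage()
    maf = panel.variants["maf"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()

    eligible = np.where(maf >= 0.10)[0]
    causal_idx, betas = [], []
    blk = config.pleiotropic_block
    if blk is not None and blk.n_causal > 0:
        chosen = _block_causal_indices(panel, config)
        # hierarchical block: one dominant lead QTN plus weaker satellites,
        # all pleiotropic (shared-direction component across traits)
        b = (rng.standard_normal((blk.n_causal, T)) @ L.T) * 0.6 * blk.effect_scale
        b += 0.6 * blk.effect_scale * np.sign(b[:, [0]])
        lead = _block_lead_index(panel, config)
        if lead is not None and blk.link_gene:
            k = int(np.where(chosen == lead)[0][0])
            b[k] = 2.5 * blk.effect_scale
        causal_idx.extend(chosen.tolist())
        betas.extend(b.tolist())
    remaining = np.setdiff1d(eligible, np.array(causal_idx, dtype=int))
    k_poly = min(config.n_causal_polygenic, len(remaining))
    poly = rng.choice(remaining, k_poly, replace=False)
    poly.sort()
    b_poly = (rng.standard_normal((k_poly, T)) @ L.T) * config.polygenic_effect_sd
    causal_idx.extend(poly.tolist())
    betas.extend(b_poly.tolist())

    causal_idx = np.array(causal_idx, dtype=int)
    B = np.array(betas)  # (n_causal, T)
    G = dos[:, causal_idx] @ B  # (n, T) genetic values
    G = G * np.sqrt(h2 > 0)  # h2 = 0 traits carry no genetic signal
    eps = rng.standard_normal((n, T)) @ L.T
    y = np.empty((n, T))
    for t in range(T):
        vg = G[:, t].var()
        if h2[t] <= 0 or vg <= 0:
            sd_e = 1.0
            G[:, t] = 0.0
        else:
            sd_e = np.sqrt(vg * (1 - h2[t]) / h2[t])
        y[:, t] = G[:, t] + sd_e * eps[:, t] / eps[:, t].std()

    farm = rng.integers(0, 3, n)
    sex = rng.integers(0, 2, n)
    farm_eff = np.array([0.0, 0.3, -0.2])
    y = y + farm_eff[farm][:, None] + (0.25 * sex)[:, None]

    ids = panel.variants["id"].to_numpy()
    truth = [
        (ids[i], f"trait_{t + 1}", float(B[k, t]))
        for k, i in enumerate(causal_idx)
        for t in range(T)
        if h2[t] > 0 and abs(B[k, t]) > 0
    ]
    pheno = pd.DataFrame(
        {"sample": panel.samples, "farm": farm, "sex": sex}
        | {f"trait_{t + 1}": y[:, t] for t in range(T)}
    )
    gvals = {f"trait_{t + 1}": G[:, t].tolist() for t in range(T)}
    return pheno, truth, gvals


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    panel: HaplotypePanel, gene_models: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, list, np.ndarray, np.ndarray]:
    """Cis-regulated TPM with hidden batch factors.

    log2(TPM + 1) = baseline + sum(effect * dosage) + Z Lambda' + noise;
    TPM is the back-transform, floored at zero.  Returns the TPM matrix
    (genes x samples), the eQTL truth list, the hidden-factor score
    matrix (samples x k) and the loading matrix (genes x k).
    """
    config.validate()
    rng = spawn_rng(config.seed, "expression")
    if config.n_expression_samples is not None:
        idx = rng.choice(panel.n_samples, config.n_expression_samples, replace=False)
        idx.sort()
        panel = panel.subset(sample_idx=idx)
    n = panel.n_samples
    genes = gene_models.reset_index(drop=True)
    dos = panel.imputed_dosage()
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    maf = panel.variants["maf"].to_numpy()
    ids = panel.variants["id"].to_numpy()

    k = config.n_hidden_factors
    Z = rng.standard_normal((n, k)) if k else np.zeros((n, 0))
    # geometric decay in factor strength (distinct batch magnitudes); this
    # also makes the factor subspace identifiable without rotation
    scales = config.hidden_factor_sd * 0.7 ** np.arange(k)
    lam = (rng.standard_normal((len(genes), k)) * scales
           if k else np.zeros((len(genes), 0)))

    n_eqtl = int(round(config.frac_genes_with_eqtl * len(genes)))
    eqtl_genes = set(rng.choice(len(genes), n_eqtl, replace=False).tolist()) if n_eqtl else set()
    second = set(
        rng.choice(sorted(eqtl_genes), int(round(config.frac_genes_with_second_eqtl * len(genes))), replace=False).tolist()
    ) if eqtl_genes and config.frac_genes_with_second_eqtl else set()

    lo, hi = config.expr_baseline_range
    baseline = rng.uniform(lo, hi, len(genes))
    X = baseline[:, None] + lam @ Z.T  # (genes, n)
    truth = []
    link = config.pleiotropic_block
    link_gene_idx = None
    if link is not None and link.link_gene:
        on_chrom = genes.index[genes["chrom"] == link.chrom]
        if len(on_chrom):
            center = (link.start_bp + link.end_bp) / 2
            link_gene_idx = int(
                on_chrom[np.argmin(np.abs(genes.loc[on_chrom, "tss"] - center))]
            )
            eqtl_genes.add(link_gene_idx)

    for gi in sorted(eqtl_genes):
        g = genes.iloc[gi]
        cis = np.where(
            (chrom == g["chrom"]) & (np.abs(pos - g["tss"]) <= 1_000_000) & (maf >= 0.10)
        )[0]
        if len(cis) == 0:
            raise ConfigurationError(f"gene {g['gene_id']} has no eligible cis variant")
        if gi == link_gene_idx:
            # instrument the block's lead trait variant so the
            # variant -> expression -> trait chain shares one signal
            lead = _block_lead_index(panel, config)
            if lead is not None and lead in cis:
                v = lead
            else:
                in_blk = cis[(pos[cis] >= link.start_bp) & (pos[cis] <= link.end_bp)]
                v = int(in_blk[0]) if len(in_blk) else int(rng.choice(cis))
            eff = link.link_effect
        else:
            v = int(rng.choice(cis))
            eff = float(rng.standard_normal() * config.eqtl_effect_sd)
        X[gi] += eff * dos[:, v]
        truth.append((g["gene_id"], ids[v], float(eff)))
        if gi in second:
            far = cis[np.abs(pos[cis] - pos[v]) > 200_000]
            if len(far):
                v2 = int(rng.choice(far))
                eff2 = float(rng.standard_normal() * config.eqtl_effect_sd)
                X[gi] += eff2 * dos[:, v2]
                truth.append((g["gene_id"], ids[v2], float(eff2)))

    X += rng.standard_normal(X.shape) * config.expr_noise_sd
    tpm = np.maximum(np.exp2(X) - 1.0, 0.0)
    tpm_df = pd.DataFrame(tpm, index=genes["gene_id"], columns=panel.samples)
    return tpm_df, truth, Z, lam


# ---------------------------------------------------------------------------
# Methylome and sequence


def simulate_methylome(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], list, list, dict[str, str]]:
    """CpG counts per WGBS-like sample, plus sequence with embedded islands.

    Returns (per-sample CpG tables, hmr_truth intervals, cgi_truth
    intervals, {chrom: sequence}).  CpG positions are the actual CG
    dinucleotides of the generated sequence, so the sequence-based CGI
    scan and the count-based methylation calls agree by construction.
    Half the islands fall inside planted hypomethylated regions (these
    become experimentally supported CGIs); island and background
    methylation follow beta-binomial draws around the configured means.
    """
    mc = config.methylome
    rng = spawn_rng(config.seed, "methylome")
    L = mc.region_bp
    bases = np.array(list("ACGT"))
    # CpG-depleted background: draw letters, then break most CG pairs
    seq = bases[rng.integers(0, 4, L)]
    cg = np.where((seq[:-1] == "C") & (seq[1:] == "G"))[0]
    drop = cg[rng.random(len(cg)) < 0.9]
    seq[drop] = "T"

    # planted hypomethylated regions (3-8 kb), disjoint
    slots = np.linspace(0.05 * L, 0.9 * L, mc.n_hmr).astype(int)
    hmr = []
    for s in slots:
        w = int(rng.integers(3000, 8000))
        hmr.append((mc.chrom, int(s), int(min(s + w, L))))

    # CpG islands: half inside HMRs, half in methylated background
    islands = []
    for i in range(mc.n_islands):
        w = int(rng.integers(700, 1400))
        if i % 2 == 0 and hmr:
            h = hmr[(i // 2) % len(hmr)]
            s = int(rng.integers(h[1], max(h[1] + 1, h[2] - w)))
        else:
            s = int(rng.integers(0, L - w))
            # keep background islands clear of the HMRs
            while any(s < e + 2000 and s + w > b - 2000 for _, b, e in hmr):
                s = int(rng.integers(0, L - w))
        islands.append((mc.chrom, s, s + w))
        # CpG-rich, GC-rich island sequence: alternate CG with GC-biased filler
        block = rng.choice(list("CG") * 3 + list("AT"), w)
        block[0::3] = "C"
        block[1::3] = "G"
        seq[s : s + w] = block[: w]

    sequence = "".join(seq)
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    cpg_pos = np.where((arr[:-1] == b"C") & (arr[1:] == b"G"))[0]
    if len(cpg_pos) > mc.n_cpg:
        keep = rng.choice(len(cpg_pos), mc.n_cpg, replace=False)
        keep.sort()
        cpg_pos = cpg_pos[keep]

    in_hypo = np.zeros(len(cpg_pos), dtype=bool)
    for _, s, e in hmr:
        in_hypo |= (cpg_pos >= s) & (cpg_pos < e)
    for (_, s, e), i in zip(islands, range(len(islands))):
        if i % 2 == 0:
            in_hypo |= (cpg_pos >= s) & (cpg_pos < e)

    tables = {}
    conc = 30.0
    for si in range(mc.n_samples):
        mean = np.where(in_hypo, mc.island_meth_mean, mc.background_meth_mean)
        level = rng.beta(mean * conc, (1 - mean) * conc)
        cov = rng.poisson(mc.coverage_mean, len(cpg_pos))
        meth = rng.binomial(cov, level)
        tables[f"wgbs{si + 1}"] = pd.DataFrame(
            {
                "chrom": mc.chrom,
                "pos": cpg_pos.astype(int),
                "strand": "+",
                "coverage": cov,
                "methylated": meth,
            }
        )
    return tables, hmr, islands, {mc.chrom: sequence}


def simulate_sequence(config: SimConfig) -> dict[str, str]:
    """Random background sequence for every chromosome (islands live only
    in the methylome region, which is generated by :func:`simulate_methylome`)."""
    rng = spawn_rng(config.seed, "sequence")
    bases = np.array(list("ACGT"))
    out = {}
    for chrom in config.chrom_names():
        seq = bases[rng.integers(0, 4, config.chrom_length_bp)]
        cg = np.where((seq[:-1] == "C") & (seq[1:] == "G"))[0]
        seq[cg[rng.random(len(cg)) < 0.9]] = "T"
        out[chrom] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# Annotation tracks


def simulate_tracks(
    gene_models: pd.DataFrame, config: SimConfig
) -> dict[str, IntervalTrack]:
    """TSS-enriched peaks, tiling TADs, and chromatin-state labels."""
    rng = spawn_rng(config.seed, "tracks")
    peaks, states = [], []
    for g in gene_models.itertuples(index=False):
        if rng.random() < 0.7:
            half = int(rng.integers(400, 1500))
            peaks.append((g.chrom, max(0, g.tss - half), g.tss + half, "peak"))
        states.append((g.chrom, max(0, g.tss - 1000), g.tss + 1000, "E2"))  # active TSS
    for chrom in config.chrom_names():
        for _ in range(40):  # background peaks
            s = int(rng.integers(0, config.chrom_length_bp - 2000))
            peaks.append((chrom, s, s + int(rng.integers(500, 2000)), "peak"))
        for _ in range(60):
            s = int(rng.integers(0, config.chrom_length_bp - 10_000))
            states.append((chrom, s, s + int(rng.integers(2000, 10_000)),
                           f"E{int(rng.integers(8, 15))}"))
    tads = []
    for chrom in config.chrom_names():
        s = 0
        while s < config.chrom_length_bp:
            w = int(rng.integers(500_000, 1_500_000))
            e = min(s + w, config.chrom_length_bp)
            tads.append((chrom, s, e, f"tad_{chrom}_{s}"))
            s = e
    cols = ["chrom", "start", "end", "label"]
    return {
        "peaks": IntervalTrack("peaks", pd.DataFrame(peaks, columns=cols)),
        "tads": IntervalTrack("tads", pd.DataFrame(tads, columns=cols)),
        "chromatin_states": IntervalTrack("chromatin_states", pd.DataFrame(states, columns=cols)),
    }


# ---------------------------------------------------------------------------
# Full bundle


def simulate_cohort(config: SimConfig, outdir) -> tuple[dict[str, Path], TruthManifest]:
    """Generate and write the full synthetic bundle.

    Writes phased VCF, phenotype/covariate table, gene models, TPM
    matrix, per-sample CpG count tables, FASTA, BED tracks and the JSON
    truth manifest.  Identical (config, seed) reproduces every file
    byte-for-byte.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = simulate_haplotypes(config)
    genes = simulate_gene_models(config)
    pheno, causal_truth, gvals = simulate_phenotypes(panel, config)
    tpm, eqtl_truth, Z, lam = simulate_expression(panel, genes, config)
    meth_tables, hmr_truth, cgi_truth, meth_seq = simulate_methylome(config)
    tracks = simulate_tracks(genes, config)

    paths = {
        "vcf": outdir / "genotypes.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "gene_models": outdir / "gene_models.tsv",
        "tpm": outdir / "expression_tpm.tsv",
        "fasta": outdir / "genome.fa",
        "truth": outdir / "truth.json",
    }
    write_vcf(panel, paths["vcf"])
    write_table(pheno, paths["phenotypes"])
    write_table(genes, paths["gene_models"])
    tpm.reset_index().to_csv(paths["tpm"], sep="\t", index=False)
    for name, tbl in meth_tables.items():
        p = outdir / f"methylation.{name}.tsv"
        write_table(tbl, p)
        paths[f"methylation.{name}"] = p
    for name, track in tracks.items():
        p = outdir / f"{name}.bed"
        write_bed(track, p)
        paths[name] = p

    seqs = simulate_sequence(config)
    mc = config.methylome
    # splice the island-bearing methylome region into its chromosome
    s = seqs[mc.chrom]
    seqs[mc.chrom] = meth_seq[mc.chrom] + s[mc.region_bp:]
    with open(paths["fasta"], "w") as fh:
        for chrom in config.chrom_names():
            fh.write(f">{chrom}\n")
            seq = seqs[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    sweep_region = None
    if config.sweep is not None:
        sw = config.sweep
        pos = panel.variants["pos"].to_numpy()
        on = (panel.variants["chrom"] == sw.chrom).to_numpy()
        core = int(np.where(on)[0][np.argmin(np.abs(pos[on] - sw.core_bp))])
        sweep_region = {
            "chrom": sw.chrom,
            "start": int(sw.core_bp - sw.width_bp // 2),
            "end": int(sw.core_bp + sw.width_bp // 2),
            "core_id": panel.variants["id"].iloc[core],
            "core_pos": int(pos[core]),
            "target_freq": sw.final_derived_freq,
        }

    manifest = TruthManifest(
        causal_variants=causal_truth,
        eqtl_truth=eqtl_truth,
        sweep_region=sweep_region,
        hmr_truth=hmr_truth,
        cgi_truth=cgi_truth,
        hidden_factor_loadings=lam.tolist(),
        hidden_factor_scores=Z.tolist(),
        genetic_values=gvals,
    )
    manifest.to_json(paths["truth"])
    return paths, manifest
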