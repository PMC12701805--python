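"""Tests of the synthetic-cohort generator: conservation, determinism,
and recoverability of every planted signal."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from bovqtl.simdata import (
    ConfigurationError,
    MethylomeConfig,
    PleiotropicBlock,
    SimConfig,
    SweepConfig,
    simulate_cohort,
    simulate_expression,
    simulate_gene_models,
    simulate_haplotypes,
    simulate_phenotypes,
)


def _tiny_cfg(seed=1, **kw):
    base = dict(
        seed=seed,
        n_individuals=50,
        n_chromosomes=2,
        variants_per_chrom=300,
        chrom_length_bp=3_000_000,
        n_genes=30,
        sweep=SweepConfig(chrom="chr2", core_bp=1_500_000, width_bp=300_000),
        pleiotropic_block=PleiotropicBlock(start_bp=1_000_000, end_bp=1_400_000),
        methylome=MethylomeConfig(region_bp=100_000, n_cpg=1500, n_islands=6, n_hmr=4),
    )
    base.update(kw)
    return SimConfig(**base)


def _hash_tree(d: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
        if p.is_file()
    }


class TestBundle:
    def test_counts_and_files(self, tmp_path):
        cfg = _tiny_cfg()
        paths, manifest = simulate_cohort(cfg, tmp_path / "b")
        for p in paths.values():
            assert Path(p).exists()
        n_records = sum(
            1 for line in open(paths["vcf"]) if not line.startswith("#")
        )
        assert n_records == cfg.n_chromosomes * cfg.variants_per_chrom

    def test_seed_determinism_byte_identical(self, tmp_path):
        h1 = _hash_tree(simulate_cohort(_tiny_cfg(), tmp_path / "a")[0]["vcf"].parent)
        h2 = _hash_tree(simulate_cohort(_tiny_cfg(), tmp_path / "b")[0]["vcf"].parent)
        assert h1 == h2

    def test_different_seed_differs(self, tmp_path):
        h1 = _hash_tree(simulate_cohort(_tiny_cfg(1), tmp_path / "a")[0]["vcf"].parent)
        h2 = _hash_tree(simulate_cohort(_tiny_cfg(2), tmp_path / "b")[0]["vcf"].parent)
        assert h1["genotypes.vcf"] != h2["genotypes.vcf"]


class TestHaplotypes:
    def test_sweep_core_frequency(self):
        cfg = SimConfig(
            seed=3, n_individuals=500, n_chromosomes=1, variants_per_chrom=500,
            chrom_length_bp=5_000_000, pleiotropic_block=None,
            sweep=SweepConfig(chrom="chr1", core_bp=2_500_000,
                              final_derived_freq=0.8, width_bp=400_000),
        )
        panel = simulate_haplotypes(cfg)
        pos = panel.variants["pos"].to_numpy()
        core = int(np.argmin(np.abs(pos - 2_500_000)))
        daf = panel.haplotypes[:, core].mean()
        assert abs(daf - 0.8) <= 0.05

    def test_ld_decays_with_distance(self, small_panel):
        pos = small_panel.variants["pos"].to_numpy()
        chrom = small_panel.variants["chrom"].to_numpy()
        d = small_panel.imputed_dosage()
        idx = np.where(chrom == "chr1")[0]
        rng = np.random.default_rng(0)

        def mean_r2(lo, hi, n=400):
            vals = []
            p = pos[idx]
            for _ in range(n):
                i = rng.integers(0, len(idx))
                cand = np.where((np.abs(p - p[i]) >= lo) & (np.abs(p - p[i]) <= hi))[0]
                if len(cand) == 0:
                    continue
                j = cand[rng.integers(0, len(cand))]
                a, b = d[:, idx[i]], d[:, idx[j]]
                if a.std() == 0 or b.std() == 0:
                    continue
                vals.append(np.corrcoef(a, b)[0, 1] ** 2)
            return np.mean(vals)

        assert mean_r2(1, 5_000) > mean_r2(500_000, 3_000_000)

    def test_sweep_region_haplotype_homozygosity(self, small_panel, small_cfg):
        sw = small_cfg.sweep
        pos = small_panel.variants["pos"].to_numpy()
        chrom = small_panel.variants["chrom"].to_numpy()
        rng = np.random.default_rng(1)

        def pairwise_identity(cols):
            h = small_panel.haplotypes[:, cols]
            total = match = 0
            for _ in range(300):
                i, j = rng.integers(0, h.shape[0], 2)
                if i == j:
                    continue
                match += (h[i] == h[j]).all()
                total += 1
            return match / total

        in_sweep = np.where(
            (chrom == sw.chrom)
            & (pos >= sw.core_bp - 100_000)
            & (pos <= sw.core_bp + 100_000)
        )[0]
        k = len(in_sweep)
        elsewhere = np.where(chrom == "chr1")[0][:k]
        assert pairwise_identity(in_sweep) > pairwise_identity(elsewhere)

    def test_invalid_configs_raise(self):
        bad_corr = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ConfigurationError):
            SimConfig(n_traits=2, trait_corr=bad_corr).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(variants_per_chrom=5000, chrom_length_bp=10_000).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(trait_h2=1.5).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(sweep=SweepConfig(final_derived_freq=1.0)).validate()


class TestPhenotypes:
    def test_h2_zero_trait_has_no_genetic_slope(self):
        cfg = _tiny_cfg(n_individuals=500, trait_h2=[0.0, 0.4, 0.4])
        panel = simulate_haplotypes(cfg)
        pheno, truth, gvals = simulate_phenotypes(panel, cfg)
        # the trait's genetic values are identically zero and absent from truth
        assert np.allclose(gvals["trait_1"], 0.0)
        assert not any(t == "trait_1" for _, t, _ in truth)

    def test_variance_decomposition_matches_h2(self):
        cfg = _tiny_cfg(seed=5, n_individuals=1000, trait_h2=0.5)
        panel = simulate_haplotypes(cfg)
        pheno, truth, gvals = simulate_phenotypes(panel, cfg)
        g = np.asarray(gvals["trait_2"])
        y = pheno["trait_2"].to_numpy()
        # remove the fixed covariate effects before decomposing
        resid = y - g
        farm = pheno["farm"].to_numpy()
        sex = pheno["sex"].to_numpy()
        import numpy.linalg as la

        X = np.column_stack([np.ones(len(y)), farm == 1, farm == 2, sex]).astype(float)
        e = resid - X @ la.lstsq(X, resid, rcond=None)[0]
        ratio = g.var() / (g.var() + e.var())
        assert 0.4 <= ratio <= 0.6

    def test_pleiotropic_block_variants_shared_across_traits(self, small_pheno):
        _, truth, _ = small_pheno
        by_variant = {}
        for vid, trait, beta in truth:
            by_variant.setdefault(vid, set()).add(trait)
        multi = [v for v, ts in by_variant.items() if len(ts) >= 2]
        assert len(multi) >= 5


class TestExpression:
    def test_no_eqtl_fraction_empty_truth(self, small_panel, small_genes):
        cfg = _tiny_cfg(frac_genes_with_eqtl=0.0)
        cfg.pleiotropic_block = None
        tpm, truth, _, _ = simulate_expression(small_panel, small_genes, cfg)
        assert truth == []
        assert (tpm.to_numpy() >= 0).all()

    def test_planted_effect_recovered_by_ols(self):
        cfg = _tiny_cfg(seed=8, n_individuals=200)
        cfg.pleiotropic_block.link_effect = 1.0
        panel = simulate_haplotypes(cfg)
        genes = simulate_gene_models(cfg)
        tpm, truth, _, _ = simulate_expression(panel, genes, cfg)
        link = [(g, v, e) for g, v, e in truth if e == 1.0]
        assert link, "link gene with unit effect must be planted"
        g, v, e = link[0]
        ids = panel.variants["id"].to_numpy()
        x = panel.imputed_dosage()[:, int(np.where(ids == v)[0][0])]
        y = np.log2(tpm.loc[g].to_numpy() + 1)
        slope = np.polyfit(x, y, 1)[0]
        assert abs(slope - 1.0) <= 0.2

    def test_hidden_factors_recoverable_by_pca(self):
        cfg = SimConfig(
            seed=9, n_individuals=150, n_chromosomes=1, variants_per_chrom=800,
            chrom_length_bp=8_000_000, n_genes=500, n_hidden_factors=2,
            pleiotropic_block=None, sweep=None,
        )
        panel = simulate_haplotypes(cfg)
        genes = simulate_gene_models(cfg)
        tpm, _, Z, _ = simulate_expression(panel, genes, cfg)
        from bovqtl import eqtl, io_qc

        norm = eqtl.normalize_expression(io_qc.filter_expressed_genes(tpm))
        pcs = eqtl.hidden_factors(norm, k=2)
        for j in range(2):
            r = max(abs(np.corrcoef(pcs[:, i], Z[:, j])[0, 1]) for i in range(2))
            assert r > 0.8
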