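"""Mixed-model association, REML variance components, per-variant
genetic variance and the multi-trait chi-square statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bovqtl import assoc
from bovqtl.core import HaplotypePanel
from bovqtl.simdata import SimConfig, simulate_haplotypes


def _panel(dos):
    dos = np.asarray(dos)
    n, m = dos.shape
    h = np.zeros((2 * n, m), dtype=np.int8)
    h[0::2] = (dos >= 1).astype(np.int8)
    h[1::2] = (dos == 2).astype(np.int8)
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, m + 1) * 1000,
         "id": [f"v{i}" for i in range(m)], "ref": "A", "alt": "G",
         "aa": "A", "dr2": 1.0, "maf": np.nan}
    )
    p = HaplotypePanel([f"s{i}" for i in range(n)], variants, h)
    p.recompute_maf()
    return p


class TestGrm:
    def test_two_sample_hand_computation(self):
        dos = np.array([[0, 2], [2, 1]])
        K = assoc.build_grm(_panel(dos))
        p = np.array([0.5, 0.75])
        z = (dos - 2 * p) / np.sqrt(2 * p * (1 - p))
        expected = z @ z.T / 2
        assert np.allclose(K, expected, atol=1e-12)

    def test_duplicated_sample_relatedness(self, poly_panel):
        idx = np.concatenate([[0, 0], np.arange(1, 60)])
        dup = poly_panel.subset(sample_idx=idx)
        p = dup.allele_freq()
        dup = dup.subset(variant_mask=(p > 0) & (p < 1))
        K = assoc.build_grm(dup)
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-9)

    def test_mean_diagonal_near_one(self, poly_panel):
        K = assoc.build_grm(poly_panel)
        assert 0.95 <= np.diag(K).mean() <= 1.05

    def test_monomorphic_variant_rejected(self):
        with pytest.raises(ValueError):
            assoc.build_grm(_panel(np.array([[0, 0], [1, 0]])))


@pytest.fixture(scope="module")
def reml_panel():
    cfg = SimConfig(seed=21, n_individuals=500, n_chromosomes=1,
                    variants_per_chrom=800, chrom_length_bp=8_000_000,
                    pleiotropic_block=None, sweep=None)
    return simulate_haplotypes(cfg)


class TestReml:
    def test_null_heritability_near_zero(self, reml_panel):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(reml_panel.n_samples)
        K = assoc.build_grm(reml_panel)
        vc = assoc.reml_variance(y, None, K)
        assert vc.h2 < 0.15

    def test_recovers_planted_heritability(self):
        cfg = SimConfig(seed=22, n_individuals=1000, n_chromosomes=1,
                        variants_per_chrom=600, chrom_length_bp=6_000_000,
                        pleiotropic_block=None, sweep=None)
        panel = simulate_haplotypes(cfg)
        rng = np.random.default_rng(1)
        K = assoc.build_grm(panel)
        # polygenic trait with h2 = 0.5 built directly from the GRM factor
        s, u = np.linalg.eigh(K)
        g = u @ (np.sqrt(np.clip(s, 0, None)) * rng.standard_normal(len(s)))
        g = g / g.std()
        y = g + rng.standard_normal(len(g))
        vc = assoc.reml_variance(y, None, K)
        assert 0.35 <= vc.h2 <= 0.65

    def test_identity_grm_flagged_unidentifiable(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(100)
        vc = assoc.reml_variance(y, None, np.eye(100))
        assert vc.at_boundary
        # the variance split reduces to the OLS residual variance
        assert vc.sigma2_a + vc.sigma2_e == pytest.approx(y.var(ddof=1), rel=0.05)


class TestSnpAssociation:
    def test_zero_grm_weight_reduces_to_ols(self, small_panel, small_pheno,
                                            pheno_covariates):
        pheno = small_pheno[0]
        y = pheno["trait_1"].to_numpy()
        vc = assoc.VarianceComponents(0.0, 1.0, 0.0)
        ss = assoc.snp_association(
            small_panel, y, pheno_covariates, variance=vc,
            grm=np.eye(small_panel.n_samples),
        )
        # OLS oracle on a handful of variants
        dos = small_panel.imputed_dosage()
        X0 = np.column_stack([np.ones(len(y)), pheno_covariates])
        for j in [0, 100, 500, 1500]:
            X = np.column_stack([X0, dos[:, j]])
            beta = np.linalg.lstsq(X, y, rcond=None)[0][-1]
            assert abs(ss["beta"].iloc[j] - beta) < 1e-8

    def test_type_one_error_on_permuted_phenotype(self, poly_panel):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(poly_panel.n_samples)
        K = assoc.build_grm(poly_panel)
        vc = assoc.reml_variance(y, None, K)
        ss = assoc.snp_association(poly_panel, y, None, variance=vc, grm=K)
        frac = (ss["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_large_planted_effect_reaches_genome_wide(self):
        cfg = SimConfig(seed=23, n_individuals=500, n_chromosomes=1,
                        variants_per_chrom=500, chrom_length_bp=5_000_000,
                        pleiotropic_block=None, sweep=None)
        panel = simulate_haplotypes(cfg)
        rng = np.random.default_rng(4)
        maf = panel.variants["maf"].to_numpy()
        j = int(np.argmin(np.abs(maf - 0.3)))
        y = panel.imputed_dosage()[:, j] * 1.0 + rng.standard_normal(panel.n_samples)
        K = assoc.build_grm(panel)
        vc = assoc.reml_variance(y, None, K)
        ss = assoc.snp_association(panel, y, None, variance=vc, grm=K)
        assert ss["p"].iloc[j] < 5e-8
        assert ss["genome_wide"].iloc[j]


class TestConditional:
    @pytest.fixture(scope="class")
    def causal_scan(self):
        cfg = SimConfig(seed=24, n_individuals=400, n_chromosomes=2,
                        variants_per_chrom=600, chrom_length_bp=6_000_000,
                        pleiotropic_block=None, sweep=None)
        panel = simulate_haplotypes(cfg)
        rng = np.random.default_rng(5)
        maf = panel.variants["maf"].to_numpy()
        chrom = panel.variants["chrom"].to_numpy()
        j = int(np.where((chrom == "chr1") & (maf > 0.3))[0][100])
        dos = panel.imputed_dosage()
        y = dos[:, j] * 0.8 + rng.standard_normal(panel.n_samples)
        K = assoc.build_grm(panel)
        vc = assoc.reml_variance(y, None, K)
        base = assoc.snp_association(panel, y, None, variance=vc, grm=K)
        return panel, y, j, K, vc, base

    def test_conditioning_on_causal_kills_linked_signals(self, causal_scan):
        panel, y, j, K, vc, base = causal_scan
        target = panel.variants["id"].iloc[j]
        cond = assoc.conditional_association(panel, y, target, None,
                                             variance=vc, grm=K)
        dos = panel.imputed_dosage()
        x = dos[:, j]
        r2 = np.array([
            np.corrcoef(x, dos[:, k])[0, 1] ** 2 if dos[:, k].std() > 0 else 0
            for k in range(panel.n_variants)
        ])
        ids_linked = set(panel.variants["id"][(r2 > 0.8)]) - {target}
        linked = cond[cond["id"].isin(ids_linked)]
        assert (linked["p"] > 5e-8).all()

    def test_conditioning_on_other_chromosome_changes_little(self, causal_scan):
        panel, y, j, K, vc, base = causal_scan
        other = panel.variants.loc[panel.variants["chrom"] == "chr2", "id"].iloc[50]
        cond = assoc.conditional_association(panel, y, other, None,
                                             variance=vc, grm=K)
        merged = base.merge(cond, on="id", suffixes=("_b", "_c"))
        # compare at common variants on the causal chromosome; variants in
        # LD with the conditioning variant itself are expected to move
        common = panel.variants.loc[
            (panel.variants["maf"] >= 0.1) & (panel.variants["chrom"] == "chr1"),
            "id"]
        merged = merged[merged["id"].isin(common)]
        sd_y = np.std(y)
        assert (np.abs(merged["beta_b"] - merged["beta_c"]) < 0.05 * sd_y).all()

    def test_collinear_covariate_raises(self, causal_scan):
        panel, y, j, K, vc, _ = causal_scan
        target = panel.variants["id"].iloc[j]
        dup = panel.imputed_dosage()[:, j]
        with pytest.raises(ValueError, match="collinear"):
            assoc.conditional_association(panel, y, target, dup[:, None],
                                          variance=vc, grm=K)


class TestVargExplained:
    def test_direct_arithmetic(self):
        assert assoc.varg_explained(1.0, 0.5, 2.0) == pytest.approx(25.0)

    def test_rare_allele_limit(self):
        assert assoc.varg_explained(1.0, 1e-12, 2.0) == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_in_beta(self):
        one = assoc.varg_explained(1.0, 0.3, 1.5)
        two = assoc.varg_explained(2.0, 0.3, 1.5)
        assert two == pytest.approx(4 * one)

    def test_requires_positive_genetic_variance(self):
        with pytest.raises(ValueError):
            assoc.varg_explained(1.0, 0.5, 0.0)


def _stats_from_t(tmat):
    out = {}
    m, T = tmat.shape
    for k in range(T):
        out[f"trait_{k + 1}"] = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(m), "id": [f"v{i}" for i in range(m)],
             "t": tmat[:, k]}
        )
    return out


class TestMultitrait:
    def test_identity_v_reduces_to_sum_of_squares(self):
        rng = np.random.default_rng(6)
        tmat = rng.standard_normal((5000, 3))
        tmat[0] = [1.0, 2.0, 2.0]
        out, V = assoc.multitrait_chi2(_stats_from_t(tmat), shrinkage=0.0)
        # independent simulated traits: V ~ I, so chi2 ~ sum t^2
        assert out["chi2"].iloc[0] == pytest.approx(9.0, rel=0.05)
        exact, _ = assoc.multitrait_chi2(_stats_from_t(tmat), shrinkage=1.0)
        assert exact["chi2"].iloc[0] == pytest.approx(9.0, abs=1e-10)

    def test_single_trait_equals_squared_t(self):
        rng = np.random.default_rng(7)
        tmat = rng.standard_normal((500, 1))
        out, _ = assoc.multitrait_chi2(_stats_from_t(tmat), shrinkage=0.0)
        assert np.allclose(out["chi2"], tmat[:, 0] ** 2, atol=1e-10)
        expected_p = 2 * stats.norm.sf(np.abs(tmat[:, 0]))
        assert np.allclose(out["p"], expected_p, atol=1e-10)

    def test_duplicated_trait_shrinkage_matches_pseudoinverse(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(2000)
        tmat = np.column_stack([base, base])
        out, V = assoc.multitrait_chi2(_stats_from_t(tmat), shrinkage=0.05)
        assert np.isfinite(out["chi2"]).all()
        # oracle: same statistic via explicit inverse of the shrunk matrix
        Vs = 0.95 * np.corrcoef(tmat.T) + 0.05 * np.eye(2)
        oracle = np.einsum("ij,jk,ik->i", tmat, np.linalg.pinv(Vs), tmat)
        assert np.allclose(out["chi2"], oracle, atol=1e-8)
        # a duplicated trait contributes roughly once, not twice
        ratio = out["chi2"].to_numpy() / np.maximum(base**2, 1e-12)
        assert 0.9 <= np.median(ratio) <= 1.1

    def test_null_calibration_with_correlated_traits(self, poly_panel,
                                                     small_pheno, pheno_covariates):
        # permuted phenotypes: no causal variants, but traits stay correlated
        pheno = small_pheno[0]
        rng = np.random.default_rng(9)
        perm = rng.permutation(poly_panel.n_samples)
        K = assoc.build_grm(poly_panel)
        stats_by = {}
        for trait in ["trait_1", "trait_2", "trait_3"]:
            y = pheno[trait].to_numpy()[perm]
            vc = assoc.reml_variance(y, pheno_covariates, K)
            stats_by[trait] = assoc.snp_association(
                poly_panel, y, pheno_covariates, variance=vc, grm=K
            )
        out, _ = assoc.multitrait_chi2(stats_by)
        frac = (out["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
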