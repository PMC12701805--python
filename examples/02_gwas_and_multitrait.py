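"""Mixed-model GWAS on three correlated traits plus the multi-trait scan.

Fits REML variance components once per trait, scans every variant by
GLS under the fitted covariance, then combines the three traits'
signed t-values through the inverse correlation matrix.
"""

import numpy as np
import pandas as pd

from bovqtl import assoc
from bovqtl.simdata import SimConfig, simulate_haplotypes, simulate_phenotypes

cfg = SimConfig(seed=2, n_individuals=500, variants_per_chrom=1500)
panel = simulate_haplotypes(cfg)
pheno, truth, _ = simulate_phenotypes(panel, cfg)
covs = np.column_stack([
    pd.get_dummies(pheno["farm"], drop_first=True, dtype=float).to_numpy(),
    pheno["sex"].to_numpy(dtype=float),
])

grm = assoc.build_grm(panel)
stats_by = {}
for trait in ("trait_1", "trait_2", "trait_3"):
    y = pheno[trait].to_numpy()
    vc = assoc.reml_variance(y, covs, grm)
    stats_by[trait] = assoc.snp_association(panel, y, covs, variance=vc, grm=grm)
    print(f"{trait}: h2 = {vc.h2:.2f}, "
          f"genome-wide hits (p < 5e-8): {stats_by[trait]['genome_wide'].sum()}")

multi, V = assoc.multitrait_chi2(stats_by)
print(f"trait t-value correlations (off-diagonal): "
      f"{V[np.triu_indices_from(V, 1)].round(2)}")
print(f"multi-trait significant variants (Bonferroni): {multi['significant'].sum()}")
top = multi.nsmallest(1, "p").iloc[0]
sigma2_a = assoc.reml_variance(pheno["trait_1"].to_numpy(), covs, grm).sigma2_a
row = stats_by["trait_1"].set_index("id").loc[top["id"]]
vg = assoc.varg_explained(row["beta"], row["eaf"], sigma2_a)
print(f"top variant {top['id']} explains {vg:.1f}% of trait_1's genetic variance")
# Hits cluster in the planted pleiotropic block; the multi-trait scan
# gains power over any single trait because the effects are shared.
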