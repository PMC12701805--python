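"""TWAS: heritability screen, weight training, gene-trait association."""

import numpy as np

from bovqtl import eqtl, io_qc, twas
from bovqtl.simdata import (SimConfig, simulate_expression,
                            simulate_gene_models, simulate_haplotypes,
                            simulate_phenotypes)

cfg = SimConfig(seed=6, n_individuals=500, variants_per_chrom=1200,
                n_genes=60, frac_genes_with_eqtl=0.4,
                n_expression_samples=250)
panel = simulate_haplotypes(cfg)
genes = simulate_gene_models(cfg).set_index("gene_id")
pheno, _, _ = simulate_phenotypes(panel, cfg)
tpm, truth, _, _ = simulate_expression(panel, genes.reset_index(), cfg)
norm = eqtl.normalize_expression(io_qc.filter_expressed_genes(tpm))
epanel = panel.subset(sample_idx=[panel.samples.index(s) for s in norm.columns])
covs = np.column_stack([eqtl.hidden_factors(norm, 10),
                        eqtl.genotype_pcs(epanel, 2)])

weights = []
for gid in norm.index:
    g = genes.loc[gid]
    y = norm.loc[gid].to_numpy()
    try:
        h2, p = twas.cis_h2(epanel, y, g["chrom"], int(g["tss"]), covs)
    except ValueError:
        continue
    if h2 > 0 and p <= 0.05:  # the non-zero-heritability screen
        gw = twas.train_weights(gid, epanel, y, g["chrom"], int(g["tss"]),
                                h2, covs, seed=0)
        if gw is not None:
            weights.append(gw)
print(f"{len(weights)} genes pass the cis-h2 screen and train usable weights")

res = twas.twas_associate(weights, panel, pheno["trait_1"].to_numpy())
print(res.sort_values("p").head(5).to_string(index=False))
print(f"TWAS genes at FDR 0.05: {res['fdr_significant'].sum()}")
# The selected column shows which weight model (top1 / ridge BLUP /
# lasso / elastic net) won each gene's 5-fold cross-validation.
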