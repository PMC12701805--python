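"""cis-eQTL mapping with permutation calibration, aFC and pi1."""

import numpy as np

from bovqtl import eqtl, io_qc
from bovqtl.simdata import (SimConfig, simulate_expression,
                            simulate_gene_models, simulate_haplotypes)

cfg = SimConfig(seed=5, n_individuals=200, variants_per_chrom=1500,
                n_genes=120, frac_genes_with_eqtl=0.3)
panel = simulate_haplotypes(cfg)
genes = simulate_gene_models(cfg)
tpm, truth, _, _ = simulate_expression(panel, genes, cfg)

kept = io_qc.filter_expressed_genes(tpm)           # TPM >= 0.1 in >= 20%
norm = eqtl.normalize_expression(kept)             # rank inverse-normal
covs = np.column_stack([eqtl.hidden_factors(norm, 10),
                        eqtl.genotype_pcs(panel, 2)])

results = eqtl.cis_scan(panel, norm, genes, covs)  # +/-1 Mb of each TSS
for i, (gid, res) in enumerate(sorted(results.items())):
    if len(res.pairs):
        eqtl.permutation_pass(panel, norm, res, covs, n_perm=1000, seed=i)
eqtl.egene_calling(results, fdr=0.05)

egenes = [g for g, r in results.items() if r.egene]
planted = {g for g, _, _ in truth}
tp = sum(g in planted for g in egenes)
print(f"{len(egenes)} eGenes at FDR 0.05 "
      f"({tp} carry a planted eQTL, {len(egenes) - tp} do not)")
gid = egenes[0]
res = results[gid]
top = res.pairs.loc[res.pairs["p"].idxmin()]
a = eqtl.afc(panel, kept, gid, top["id"], covs)
print(f"example eGene {gid}: top variant {top['id']} "
      f"(p = {top['p']:.2e}, nominal threshold {res.nominal_threshold:.2e}), "
      f"aFC = {a:.2f} log2 units")
pi1 = eqtl.storey_pi1([results[g].empirical_p for g in sorted(results)])
print(f"pi1 over all genes' empirical p: {pi1:.2f} "
      f"(upper-end estimate of the fraction of genes with a cis signal; "
      f"coarse at ~100 genes)")
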