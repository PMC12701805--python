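"""CpG-island scan, experimentally supported CGIs, and HMR calling."""

from bovqtl import methylome
from bovqtl.simdata import SimConfig, simulate_methylome

cfg = SimConfig(seed=9)
tables, hmr_truth, cgi_truth, seqs = simulate_methylome(cfg)

ccgi = methylome.cgi_scan(seqs)
print(f"{len(ccgi)} computational CpG islands "
      f"(>=500 bp, GC >= 0.55, Obs/Exp CpG >= 0.65); "
      f"{len(cgi_truth)} were planted")

ecgi = methylome.ecgi_filter(ccgi, tables)
print(f"{len(ecgi)} experimentally supported CGIs "
      f"(methylation < 30% in at least one of {len(tables)} WGBS samples)")

merged, per_sample, models = methylome.hmr_call(tables)
m = next(iter(models.values()))
print(f"{len(merged)} merged hypomethylated regions; "
      f"HMM state means {m.state_means().round(2)} "
      f"(hypo vs hyper methylation levels)")
print(f"{len(hmr_truth)} HMRs were planted")
# Half the planted islands sit inside hypomethylated regions and come
# back as eCGIs; the rest are methylated and are filtered out.
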