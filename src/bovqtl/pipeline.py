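"""End-to-end orchestration: simulate -> QC -> GWAS -> gene-based and
multi-trait scans -> sweep -> eQTL -> TWAS -> colocalization/SMR ->
enrichment -> methylome -> report.

Each stage writes its outputs into a run directory and records a
provenance entry (parameters hash, output file SHA-256) in
``manifest.json``; a rerun with the same configuration and seed
reproduces every file byte-for-byte.  Stage toggles are honoured in
dependency order: disabling a prerequisite makes the dependent stage
refuse to run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, enrich, eqtl, geneassoc, integrate, io_qc, methylome, sweep
from .core import IntervalTrack, substream
from .io_qc import QcThresholds
from .simdata import MethylomeConfig, PleiotropicBlock, SimConfig, SweepConfig, simulate_cohort
from .twas import cis_h2, train_weights, twas_associate

logger = logging.getLogger("bovqtl")

STAGES = [
    "simulate", "qc", "gwas", "gene_gwas", "multitrait", "sweep",
    "eqtl", "twas", "coloc_smr", "enrich", "methylome", "report",
]
DEPENDENCIES = {
    "simulate": [],
    "qc": ["simulate"],
    "gwas": ["qc"],
    "gene_gwas": ["gwas"],
    "multitrait": ["gwas"],
    "sweep": ["qc"],
    "eqtl": ["qc"],
    "twas": ["eqtl", "gwas"],
    "coloc_smr": ["eqtl", "gwas"],
    "enrich": ["eqtl", "gwas"],
    "methylome": ["simulate"],
    "report": [],
}


@dataclass
class PipelineConfig:
    """Run-level configuration: simulator settings, stage toggles and
    the analysis thresholds (defaulting to the study's stated values)."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    qc: QcThresholds = field(default_factory=QcThresholds)
    gwas_trait: str = "trait_1"
    hidden_k: int = 10
    genotype_pcs: int = 2
    n_perm_eqtl: int = 1000
    n_perm_enrich: int = 1000
    n_perm_tad: int = 5000
    eqtl_fdr: float = 0.05
    twas_fdr: float = 0.05
    smr_fdr: float = 0.05
    coloc_gwas_p: float = 1e-5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key, sub in (("pleiotropic_block", PleiotropicBlock),
                         ("sweep", SweepConfig), ("methylome", MethylomeConfig)):
            if key in sim_raw and isinstance(sim_raw[key], dict):
                sim_raw[key] = sub(**sim_raw[key])
        cfg = cls(**{k: v for k, v in raw.items() if k != "stages"})
        if "stages" in raw:
            cfg.stages.update(raw["stages"])
        cfg.sim = SimConfig(**sim_raw) if sim_raw else cfg.sim
        cfg.sim.seed = cfg.seed
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(obj) -> str:
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig, outdir):
        self.cfg = config
        self.dir = Path(outdir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}, "seed": config.seed}
        self.state: dict = {}

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        self.manifest["stages"][stage] = {
            "params": _params_hash(self.cfg),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
        }

    def write_manifest(self) -> None:
        with open(self.dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


class StageDependencyError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, outdir) -> PipelineRun:
    """Execute the enabled stages in dependency order."""
    config.sim.seed = config.seed
    run = PipelineRun(config, outdir)
    enabled = {s: config.stages.get(s, True) for s in STAGES}
    for s in STAGES:
        if not enabled[s]:
            continue
        missing = [d for d in DEPENDENCIES[s] if not enabled[d]]
        if missing:
            raise StageDependencyError(
                f"stage {s!r} requires disabled stage(s) {missing}"
            )
    for s in STAGES:
        if enabled[s]:
            logger.info("stage %s", s)
            globals()[f"_stage_{s}"](run)
    run.write_manifest()
    return run


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(run: PipelineRun) -> None:
    paths, manifest = simulate_cohort(run.cfg.sim, run.dir / "simdata")
    run.state["paths"] = paths
    run.state["truth"] = manifest
    run.record("simulate", paths)


def _stage_qc(run: PipelineRun) -> None:
    panel = io_qc.load_genotypes(run.state["paths"]["vcf"])
    panel, ledger = io_qc.variant_qc(panel, run.cfg.qc)
    run.state["panel"] = panel
    out = run.dir / "qc_ledger.json"
    with open(out, "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
    run.record("qc", {"ledger": out})


def _stage_gwas(run: PipelineRun) -> None:
    cfg = run.cfg
    panel = run.state["panel"]
    pheno = io_qc.read_table(run.state["paths"]["phenotypes"])
    covs = _pheno_covariates(pheno)
    grm = assoc.build_grm(panel)
    run.state["grm"] = grm
    run.state["pheno"] = pheno
    run.state["covs"] = covs
    stats_by_trait, vcs = {}, {}
    outputs = {}
    for trait in [c for c in pheno.columns if c.startswith("trait_")]:
        y = pheno[trait].to_numpy()
        vc = assoc.reml_variance(y, covs, grm)
        ss = assoc.snp_association(panel, y, covs, variance=vc, grm=grm)
        stats_by_trait[trait] = ss
        vcs[trait] = vc
        p = run.dir / f"gwas.{trait}.tsv"
        io_qc.write_table(ss, p)
        outputs[trait] = p
    run.state["gwas"] = stats_by_trait
    run.state["variance_components"] = vcs
    run.record("gwas", outputs)


def _pheno_covariates(pheno: pd.DataFrame) -> np.ndarray:
    farm = pd.get_dummies(pheno["farm"], drop_first=True, dtype=float)
    return np.column_stack([farm.to_numpy(), pheno["sex"].to_numpy(dtype=float)])


def _stage_gene_gwas(run: PipelineRun) -> None:
    cfg = run.cfg
    panel = run.state["panel"]
    genes = io_qc.read_table(run.state["paths"]["gene_models"])
    ss = run.state["gwas"][cfg.gwas_trait]
    out = geneassoc.gene_gwas(
        panel, genes, ss, seed=substream(cfg.seed, "gene_gwas"), n_draws=2000
    )
    p = run.dir / "gene_gwas.tsv"
    io_qc.write_table(out, p)
    run.state["gene_gwas"] = out
    run.record("gene_gwas", {"table": p})


def _stage_multitrait(run: PipelineRun) -> None:
    out, V = assoc.multitrait_chi2(run.state["gwas"])
    p = run.dir / "multitrait.tsv"
    io_qc.write_table(out, p)
    run.state["multitrait"] = out
    run.record("multitrait", {"table": p})


def _stage_sweep(run: PipelineRun) -> None:
    panel = run.state["panel"]
    scores = sweep.ihs_scan(panel)
    scores = sweep.standardize_ihs(scores)
    windows = sweep.call_sweep_windows(scores)
    p1, p2 = run.dir / "ihs.tsv", run.dir / "sweep_windows.tsv"
    io_qc.write_table(scores, p1)
    io_qc.write_table(windows, p2)
    run.state["ihs"] = scores
    run.state["sweep_windows"] = windows
    run.record("sweep", {"scores": p1, "windows": p2})


def _stage_eqtl(run: PipelineRun) -> None:
    cfg = run.cfg
    panel = run.state["panel"]
    tpm = io_qc.read_table(run.state["paths"]["tpm"]).set_index("gene_id")
    expr_samples = [s for s in tpm.columns if s in set(panel.samples)]
    tpm = tpm[expr_samples]
    sample_ix = [panel.samples.index(s) for s in expr_samples]
    epanel = panel.subset(sample_idx=sample_ix)
    genes = io_qc.read_table(run.state["paths"]["gene_models"])

    kept = io_qc.filter_expressed_genes(tpm)
    norm = eqtl.normalize_expression(kept)
    k = min(cfg.hidden_k, max(norm.shape[1] - 2, 0))
    factors = eqtl.hidden_factors(norm, k=k)
    gpcs = eqtl.genotype_pcs(epanel, k=cfg.genotype_pcs)
    covs = np.column_stack([factors, gpcs])

    results = eqtl.cis_scan(epanel, norm, genes, covs)
    seed0 = substream(cfg.seed, "eqtl_perm")
    for i, (gid, res) in enumerate(sorted(results.items())):
        if len(res.pairs):
            eqtl.permutation_pass(
                epanel, norm, res, covs, n_perm=cfg.n_perm_eqtl, seed=seed0 + i
            )
    eqtl.egene_calling(results, fdr=cfg.eqtl_fdr)
    rows = []
    for gid, res in sorted(results.items()):
        top = None
        if len(res.pairs):
            top = res.pairs.iloc[res.pairs["p"].idxmin() if res.pairs["p"].notna().any() else 0]
            top_id = res.pairs.loc[res.pairs["p"].idxmin(), "id"] if res.pairs["p"].notna().any() else None
        else:
            top_id = None
        if res.egene and top_id is not None:
            res.afc_log2 = eqtl.afc(epanel, kept, gid, top_id, covs)
        rows.append(
            (gid, len(res.pairs), res.beta_a, res.beta_b, res.empirical_p,
             res.direct_p, res.egene, res.nominal_threshold, top_id, res.afc_log2)
        )
    summary = pd.DataFrame(rows, columns=[
        "gene_id", "n_cis", "beta_a", "beta_b", "empirical_p", "direct_p",
        "egene", "nominal_threshold", "top_variant", "afc_log2",
    ])
    p = run.dir / "eqtl_genes.tsv"
    io_qc.write_table(summary, p)
    run.state.update(
        eqtl_results=results, eqtl_summary=summary, expr_panel=epanel,
        expr_norm=norm, expr_tpm=kept, expr_covs=covs, gene_models=genes,
    )
    run.record("eqtl", {"summary": p})


def _stage_twas(run: PipelineRun) -> None:
    cfg = run.cfg
    if "eqtl_results" not in run.state:
        raise StageDependencyError("twas requires the eqtl stage outputs")
    epanel = run.state["expr_panel"]
    norm = run.state["expr_norm"]
    covs = run.state["expr_covs"]
    genes = run.state["gene_models"].set_index("gene_id")
    panel = run.state["panel"]
    pheno = run.state["pheno"]
    weights = []
    seed0 = substream(cfg.seed, "twas")
    for gid in norm.index:
        if gid not in genes.index:
            continue
        g = genes.loc[gid]
        y = norm.loc[gid].to_numpy()
        try:
            h2, p = cis_h2(epanel, y, g["chrom"], int(g["tss"]), covs)
        except ValueError:
            continue
        if not (h2 > 0 and p <= 0.05):
            continue
        gw = train_weights(gid, epanel, y, g["chrom"], int(g["tss"]), h2, covs,
                           seed=seed0)
        if gw is not None:
            weights.append(gw)
    tables = []
    for trait in run.state["gwas"]:
        out = twas_associate(
            weights, panel, pheno[trait].to_numpy(), run.state["covs"],
            fdr=cfg.twas_fdr,
        )
        out.insert(1, "trait", trait)
        tables.append(out)
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    p = run.dir / "twas.tsv"
    io_qc.write_table(out, p)
    run.state["twas"] = out
    run.state["twas_weights"] = weights
    run.record("twas", {"table": p})


def _stage_coloc_smr(run: PipelineRun) -> None:
    cfg = run.cfg
    if "eqtl_results" not in run.state:
        raise StageDependencyError("coloc_smr requires the eqtl stage outputs")
    genes = run.state["gene_models"].set_index("gene_id")
    results = run.state["eqtl_results"]
    coloc_rows, smr_frames = [], []
    for trait, gwas in run.state["gwas"].items():
        smr_rows = []
        for gid, res in sorted(results.items()):
            if not res.egene or not len(res.pairs):
                continue
            g = genes.loc[gid]
            region = gwas[(gwas["chrom"] == g["chrom"])
                          & (np.abs(gwas["pos"] - g["tss"]) <= eqtl.CIS_WINDOW_BP)]
            if region["p"].min() > cfg.coloc_gwas_p:
                continue
            try:
                cres = integrate.coloc_abf(region, res.pairs[["id", "beta", "se"]])
            except ValueError:
                continue
            coloc_rows.append((gid, trait, cres.pp["PP.H0"], cres.pp["PP.H1"],
                               cres.pp["PP.H2"], cres.pp["PP.H3"],
                               cres.pp["PP.H4"], cres.n_snps))
            # SMR instrument: top cis-eQTL passing the gene's nominal threshold
            top = res.pairs.loc[res.pairs["p"].idxmin()]
            if np.isfinite(res.nominal_threshold) and top["p"] < res.nominal_threshold:
                grow = gwas[gwas["id"] == top["id"]]
                if len(grow):
                    smr_rows.append((gid, top["id"], float(grow["beta"].iloc[0]),
                                     float(grow["se"].iloc[0]), float(top["beta"]),
                                     float(top["se"])))
        smr_in = pd.DataFrame(smr_rows, columns=[
            "gene_id", "instrument", "beta_gwas", "se_gwas", "beta_eqtl", "se_eqtl"])
        smr_trait = integrate.smr_table(smr_in, fdr=cfg.smr_fdr)
        smr_trait.insert(1, "trait", trait)
        smr_frames.append(smr_trait)
    coloc_df = pd.DataFrame(coloc_rows, columns=[
        "gene_id", "trait", "pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4", "n_snps"])
    smr_df = (pd.concat(smr_frames, ignore_index=True)
              if smr_frames else pd.DataFrame(columns=[
                  "gene_id", "trait", "instrument", "b_xy", "t_smr", "p",
                  "fdr_significant"]))
    p1, p2 = run.dir / "coloc.tsv", run.dir / "smr.tsv"
    io_qc.write_table(coloc_df, p1)
    io_qc.write_table(smr_df, p2)
    run.state["coloc"] = coloc_df
    run.state["smr"] = smr_df
    run.record("coloc_smr", {"coloc": p1, "smr": p2})


def _stage_enrich(run: PipelineRun) -> None:
    cfg = run.cfg
    panel = run.state["panel"]
    gwas = run.state["gwas"][cfg.gwas_trait]
    cand = gwas.loc[gwas["suggestive"], "id"].tolist()
    peaks = io_qc.read_bed(run.state["paths"]["peaks"], "peaks")
    rows = []
    seed0 = substream(cfg.seed, "enrich")
    if cand:
        r = enrich.interval_enrichment(
            cand, panel, peaks, n_perm=cfg.n_perm_enrich, seed=seed0,
            set_name=cfg.gwas_trait,
        )
        rows.append(dataclasses.asdict(r))
        evars = set()
        for gid, res in run.state.get("eqtl_results", {}).items():
            if res.egene and np.isfinite(res.nominal_threshold):
                sig = res.pairs[res.pairs["p"] < res.nominal_threshold]
                evars.update(sig["id"].tolist())
        if evars:
            r2 = enrich.gwas_in_eqtl_enrichment(
                cand, evars, panel, n_perm=cfg.n_perm_enrich, seed=seed0 + 1,
                set_name=cfg.gwas_trait,
            )
            rows.append(dataclasses.asdict(r2))
    # TAD co-occurrence of eGene / top-eVariant pairs
    summary = run.state.get("eqtl_summary")
    tad_result = None
    if summary is not None:
        pairs = summary.loc[summary["egene"] & summary["top_variant"].notna(),
                            ["gene_id", "top_variant"]]
        pairs = pairs.rename(columns={"top_variant": "variant_id"})
        if len(pairs):
            tads = io_qc.read_bed(run.state["paths"]["tads"], "tads")
            obs, null, p = enrich.tad_cooccurrence(
                pairs, run.state["gene_models"], panel, tads,
                n_perm=cfg.n_perm_tad, seed=seed0 + 2,
            )
            tad_result = {"observed": obs, "null_mean": float(null.mean()), "p": p}
    out = run.dir / "enrichment.tsv"
    io_qc.write_table(pd.DataFrame(rows), out)
    outputs = {"table": out}
    if tad_result is not None:
        p_tad = run.dir / "tad_cooccurrence.json"
        with open(p_tad, "w") as fh:
            json.dump(tad_result, fh, indent=1, sort_keys=True)
        outputs["tad"] = p_tad
        run.state["tad"] = tad_result
    run.state["enrichment"] = rows
    run.record("enrich", outputs)


def _stage_methylome(run: PipelineRun) -> None:
    from pyfaidx import Fasta

    cfg = run.cfg
    fa = Fasta(str(run.state["paths"]["fasta"]))
    mc = cfg.sim.methylome
    seqs = {mc.chrom: str(fa[mc.chrom][: mc.region_bp])}
    ccgi = methylome.cgi_scan(seqs)
    cpg = {
        k.split(".", 1)[1]: io_qc.read_table(p)
        for k, p in run.state["paths"].items()
        if k.startswith("methylation.")
    }
    ecgi = methylome.ecgi_filter(ccgi, cpg)
    merged, per_sample, _ = methylome.hmr_call(cpg)
    p1, p2, p3 = (run.dir / f"{n}.bed" for n in ("ccgi", "ecgi", "hmr_merged"))
    io_qc.write_bed(ccgi, p1)
    io_qc.write_bed(ecgi, p2)
    io_qc.write_bed(merged, p3)
    run.state.update(ccgi=ccgi, ecgi=ecgi, hmr=merged)
    run.record("methylome", {"ccgi": p1, "ecgi": p2, "hmr": p3})


def _stage_report(run: PipelineRun) -> None:
    report = make_report(run)
    p = run.dir / "report_evidence.tsv"
    io_qc.write_table(report, p)
    run.state["report"] = report
    run.record("report", {"evidence": p})


def make_report(run: PipelineRun) -> pd.DataFrame:
    """Per-gene evidence matrix across the analyses, with row sums.

    Missing stage outputs are listed as absent (all-False columns), not
    errors.  The GWAS/multi-trait columns flag genes whose +/-50 kb
    window holds a significant variant; sweep flags overlap with a
    candidate window.
    """
    genes = run.state.get("gene_models")
    if genes is None:
        try:
            genes = io_qc.read_table(run.state["paths"]["gene_models"])
        except Exception:
            return pd.DataFrame()
    ev = pd.DataFrame({"gene_id": genes["gene_id"]})
    chrom = genes["chrom"].to_numpy()
    lo = genes["start"].to_numpy() - 50_000
    hi = genes["end"].to_numpy() + 50_000

    def window_hit(table, pcol, thr):
        hits = np.zeros(len(genes), dtype=bool)
        sig = table[table[pcol] < thr]
        for c in np.unique(chrom):
            pos = sig.loc[sig["chrom"] == c, "pos"].to_numpy()
            if len(pos) == 0:
                continue
            m = chrom == c
            hits[m] |= [(pos >= l) .any() and ((pos >= l) & (pos <= h)).any()
                        for l, h in zip(lo[m], hi[m])]
        return hits

    gwas = run.state.get("gwas")
    if gwas:
        any_hit = np.zeros(len(genes), dtype=bool)
        for t, ss in gwas.items():
            any_hit |= window_hit(ss, "p", assoc.GENOME_WIDE_P)
        ev["gwas"] = any_hit
    else:
        ev["gwas"] = False
    gg = run.state.get("gene_gwas")
    ev["gene_gwas"] = ev["gene_id"].isin(
        gg.loc[gg["significant"], "gene_id"]) if gg is not None else False
    mt = run.state.get("multitrait")
    if mt is not None:
        thr = 0.05 / max(len(mt), 1)
        ev["multitrait"] = window_hit(mt, "p", thr)
    else:
        ev["multitrait"] = False
    sw = run.state.get("sweep_windows")
    if sw is not None:
        cand = sw[sw["candidate"]]
        hits = np.zeros(len(genes), dtype=bool)
        for c, grp in cand.groupby("chrom"):
            m = chrom == c
            for s, e in zip(grp["start"], grp["end"]):
                hits[m] |= (lo[m] <= e) & (hi[m] >= s)
        ev["sweep"] = hits
    else:
        ev["sweep"] = False
    summ = run.state.get("eqtl_summary")
    ev["egene"] = ev["gene_id"].isin(
        summ.loc[summ["egene"], "gene_id"]) if summ is not None else False
    tw = run.state.get("twas")
    ev["twas"] = ev["gene_id"].isin(
        tw.loc[tw["fdr_significant"], "gene_id"]) if tw is not None else False
    co = run.state.get("coloc")
    ev["coloc"] = ev["gene_id"].isin(
        co.loc[co["pp_h4"] > 0.8, "gene_id"]) if co is not None else False
    sm = run.state.get("smr")
    ev["smr"] = ev["gene_id"].isin(
        sm.loc[sm["fdr_significant"], "gene_id"]) if sm is not None else False
    flag_cols = [c for c in ev.columns if c != "gene_id"]
    ev["n_evidence"] = ev[flag_cols].sum(axis=1)
    return ev
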