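"""End-to-end pipeline orchestration with manifests and resumable stages.

Stage order follows the method: qc -> normalize -> h2 -> train -> assoc ->
refine -> expand.  Each stage writes its outputs plus a ``manifest.json``
(parameters, input-file hashes, row counts) under the run directory; a rerun
with an identical manifest skips the stage, which makes runs resumable and
hash-stable.  No stage mutates a previous stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import association as assoc_mod
from . import expression as expr_mod
from . import genotype_qc as qc_mod
from . import geneset as gs_mod
from . import heritability as h2_mod
from . import locus as locus_mod
from . import weights as w_mod

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report", "training_design", "ALL_STAGES"]

ALL_STAGES = ("qc", "normalize", "h2", "train", "assoc", "refine", "expand")


@dataclass
class PipelineConfig:
    """Paths, thresholds, seed, and stage toggles for one pipeline run."""

    genotypes: str = ""  # PLINK prefix
    tissues: dict = field(default_factory=dict)  # tissue -> {expression, covariates, sample_map}
    gwas: str = ""
    annotation: str = ""  # TSV: gene, chrom, tss
    markers: str = ""  # optional 2-col TSV: term, gene
    edges: str = ""  # optional 2-col TSV edge list
    reference_ids: str = ""  # optional newline list of reference sample ids

    maf_min: float = 0.01
    miss_max: float = 0.1
    maf_max: float = 0.40
    prune_window_kb: float = 50.0
    prune_step_kb: float = 5.0
    prune_r2: float = 0.2
    pca_var_threshold: float = 0.01
    n_clusters: int = 8
    h2_p: float = 0.01
    fdr: float = 0.05
    flank: int = 500_000
    k_folds: int = 5
    B_bootstrap: int = 50
    sd_multiplier: float = 1.3
    top_k: int = 50
    models: tuple = w_mod.DEFAULT_MODELS
    seed: int = 0
    stages: tuple = ALL_STAGES

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.models = tuple(cfg.models)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def validate(self) -> None:
        for p in [self.genotypes + ".bed", self.gwas, self.annotation]:
            if p and not os.path.exists(p):
                raise FileNotFoundError(p)
        if not 0 < self.h2_p <= 1 or not 0 < self.fdr <= 1:
            raise ValueError("h2_p and fdr must be in (0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(stage_dir: str, params: dict, inputs: list[str], counts: dict) -> dict:
    return {
        "stage": os.path.basename(stage_dir),
        "params": params,
        "inputs": {p: _hash_file(p) for p in inputs if p and os.path.exists(p)},
        "row_counts": counts,
    }


def _write_manifest(stage_dir: str, manifest: dict) -> None:
    with open(os.path.join(stage_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_fresh(stage_dir: str, params: dict, inputs: list[str]) -> bool:
    path = os.path.join(stage_dir, "manifest.json")
    if not os.path.exists(path):
        return False
    with open(path) as fh:
        old = json.load(fh)
    cur = {p: _hash_file(p) for p in inputs if p and os.path.exists(p)}
    return old.get("params") == json.loads(json.dumps(params)) and old.get("inputs") == cur


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_qc(cfg: PipelineConfig, run_dir: str) -> None:
    d = os.path.join(run_dir, "qc")
    os.makedirs(d, exist_ok=True)
    params = {"maf_min": cfg.maf_min, "miss_max": cfg.miss_max, "maf_max": cfg.maf_max,
              "prune_window_kb": cfg.prune_window_kb, "prune_r2": cfg.prune_r2,
              "pca_var_threshold": cfg.pca_var_threshold, "n_clusters": cfg.n_clusters,
              "seed": cfg.seed}
    inputs = [cfg.genotypes + ext for ext in (".bed", ".bim", ".fam")]
    if _stage_fresh(d, params, inputs):
        logger.info("qc: manifest unchanged, skipping")
        return
    panel = qc_mod.read_plink(cfg.genotypes)
    panel = qc_mod.filter_variants(panel, cfg.maf_min, cfg.miss_max, cfg.maf_max)
    pruned_idx = qc_mod.ld_prune(panel, cfg.prune_window_kb, cfg.prune_step_kb,
                                 cfg.prune_r2)
    pruned = panel.subset_variants(pruned_idx)
    result = qc_mod.pca_cluster(pruned, cfg.pca_var_threshold,
                                min(cfg.n_clusters, pruned.n_samples), cfg.seed)
    if cfg.reference_ids and os.path.exists(cfg.reference_ids):
        with open(cfg.reference_ids) as fh:
            refs = [ln.strip() for ln in fh if ln.strip()]
        retained = qc_mod.select_reference_clusters(result, refs)
    else:
        retained = list(result.sample_ids)
    anc = pd.DataFrame({
        "sample": result.sample_ids,
        "pc1": result.pcs[:, 0],
        "pc2": result.pcs[:, 1] if result.pcs.shape[1] > 1 else 0.0,
        "cluster": result.cluster_labels,
        "retained": [s in set(retained) for s in result.sample_ids],
    })
    anc.to_csv(os.path.join(d, "ancestry.tsv"), sep="\t", index=False)
    qc_mod.write_plink(panel.subset_samples(retained), os.path.join(d, "panel"))
    m = _manifest(d, params, inputs,
                  {"variants_kept": panel.n_variants, "samples_retained": len(retained)})
    _write_manifest(d, m)


def _load_panel(run_dir: str) -> qc_mod.GenotypePanel:
    return qc_mod.read_plink(os.path.join(run_dir, "qc", "panel"))


def _stage_normalize(cfg: PipelineConfig, run_dir: str) -> None:
    d = os.path.join(run_dir, "normalize")
    os.makedirs(d, exist_ok=True)
    params = {"seed": cfg.seed}
    inputs = [p for t in cfg.tissues.values() for p in t.values()]
    if _stage_fresh(d, params, inputs):
        logger.info("normalize: manifest unchanged, skipping")
        return
    panel = _load_panel(run_dir)
    keep_inds = set(panel.individual_ids)
    counts = {}
    for tissue, paths in cfg.tissues.items():
        es = expr_mod.ExpressionSet.from_tsv(
            tissue, paths["expression"], paths["covariates"], paths["sample_map"])
        keep = [s for s in es.samples if es.sample_to_individual[s] in keep_inds]
        sel = [es.samples.index(s) for s in keep]
        es = expr_mod.ExpressionSet(
            tissue, es.genes, keep, es.values[:, sel], es.covariates.loc[keep],
            {s: es.sample_to_individual[s] for s in keep})
        prepared = expr_mod.prepare(es)
        prepared.to_tsv(
            os.path.join(d, f"{tissue}.expr.tsv"),
            os.path.join(d, f"{tissue}.cov.tsv"),
            os.path.join(d, f"{tissue}.map.tsv"))
        counts[tissue] = len(prepared.samples)
    _write_manifest(d, _manifest(d, params, inputs, counts))


def _load_prepared(cfg: PipelineConfig, run_dir: str) -> list[expr_mod.ExpressionSet]:
    d = os.path.join(run_dir, "normalize")
    out = []
    for tissue in cfg.tissues:
        out.append(expr_mod.ExpressionSet.from_tsv(
            tissue,
            os.path.join(d, f"{tissue}.expr.tsv"),
            os.path.join(d, f"{tissue}.cov.tsv"),
            os.path.join(d, f"{tissue}.map.tsv")))
    return out


def training_design(panel: qc_mod.GenotypePanel,
                    sets: list[expr_mod.ExpressionSet]) -> dict:
    """Pooled multi-tissue training design: one row per tissue sample, the
    individual's genotype row repeated for each of their samples."""
    ind_row = {ind: i for i, ind in enumerate(panel.individual_ids)}
    samples, rows, s2i = [], [], {}
    gene_sets = []
    for es in sets:
        for s in es.samples:
            ind = es.sample_to_individual[s]
            if ind in ind_row:
                samples.append(s)
                rows.append(ind_row[ind])
                s2i[s] = ind
        gene_sets.append(es)
    genes = sorted(set.intersection(*[set(es.genes) for es in gene_sets]))
    Y = np.full((len(genes), len(samples)), np.nan)
    col = {s: j for j, s in enumerate(samples)}
    for es in gene_sets:
        gi = {g: i for i, g in enumerate(es.genes)}
        for s in es.samples:
            if s in col:
                Y[:, col[s]] = [es.values[gi[g], es.samples.index(s)] for g in genes]
    return {"samples": samples, "rows": np.array(rows), "s2i": s2i,
            "genes": genes, "Y": Y}


def _stage_h2(cfg: PipelineConfig, run_dir: str) -> None:
    d = os.path.join(run_dir, "h2")
    os.makedirs(d, exist_ok=True)
    params = {"h2_p": cfg.h2_p, "flank": cfg.flank}
    inputs = [cfg.annotation]
    if _stage_fresh(d, params, inputs):
        logger.info("h2: manifest unchanged, skipping")
        return
    panel = _load_panel(run_dir)
    sets = _load_prepared(cfg, run_dir)
    tr = training_design(panel, sets)
    ann = pd.read_csv(cfg.annotation, sep="\t", dtype={"chrom": str})
    estimates = []
    for r in ann.itertuples(index=False):
        if r.gene not in tr["genes"]:
            continue
        win = h2_mod.cis_window(panel, r.gene, r.chrom, int(r.tss), cfg.flank)
        if not win.variant_indices:
            continue
        gi = tr["genes"].index(r.gene)
        y = tr["Y"][gi]
        ok = ~np.isnan(y)
        X = panel.dosages[np.ix_(tr["rows"][ok], list(win.variant_indices))]
        try:
            est = h2_mod.reml_h2(y[ok], genotypes=X, gene=r.gene)
        except ValueError as exc:
            logger.info("%s: h2 estimation skipped (%s)", r.gene, exc)
            continue
        estimates.append(est)
    frame = h2_mod.estimates_to_frame(estimates)
    frame.to_csv(os.path.join(d, "estimates.tsv"), sep="\t", index=False)
    gated = h2_mod.heritability_gate(estimates, cfg.h2_p)
    pd.Series(gated, name="gene").to_csv(os.path.join(d, "gated_genes.tsv"),
                                         sep="\t", index=False)
    _write_manifest(d, _manifest(d, params, inputs,
                                 {"tested": len(estimates), "gated": len(gated)}))


def _stage_train(cfg: PipelineConfig, run_dir: str) -> None:
    d = os.path.join(run_dir, "train")
    os.makedirs(d, exist_ok=True)
    params = {"k_folds": cfg.k_folds, "seed": cfg.seed, "models": list(cfg.models),
              "flank": cfg.flank}
    inputs = [os.path.join(run_dir, "h2", "estimates.tsv")]
    if _stage_fresh(d, params, inputs):
        logger.info("train: manifest unchanged, skipping")
        return
    panel = _load_panel(run_dir)
    sets = _load_prepared(cfg, run_dir)
    tr = training_design(panel, sets)
    ann = pd.read_csv(cfg.annotation, sep="\t", dtype={"chrom": str}).set_index("gene")
    est = pd.read_csv(os.path.join(run_dir, "h2", "estimates.tsv"), sep="\t")
    gated = pd.read_csv(os.path.join(run_dir, "h2", "gated_genes.tsv"), sep="\t")
    h2_of = dict(zip(est["gene"], est["h2"]))
    folds = w_mod.make_group_folds(tr["s2i"], cfg.k_folds, cfg.seed)
    index_rows = []
    os.makedirs(os.path.join(d, "weights"), exist_ok=True)
    for gene in gated["gene"]:
        if gene not in tr["genes"] or gene not in ann.index:
            continue
        win = h2_mod.cis_window(panel, gene, ann.at[gene, "chrom"],
                                int(ann.at[gene, "tss"]), cfg.flank)
        gi = tr["genes"].index(gene)
        y = tr["Y"][gi]
        ok = ~np.isnan(y)
        idx = list(win.variant_indices)
        X = qc_mod.standardize_dosages(panel.dosages[np.ix_(tr["rows"][ok], idx)])
        samples = [s for s, o in zip(tr["samples"], ok) if o]
        vids = panel.variants["id"].iloc[idx].tolist()
        wm = w_mod.cross_validate_and_select(
            X, y[ok], folds, h2_of.get(gene, 0.5), samples, gene=gene,
            variant_ids=vids, models=cfg.models)
        if wm is None:
            continue
        sub = panel.variants.iloc[idx]
        pd.DataFrame({
            "variant": vids, "chrom": sub["chrom"].values, "pos": sub["pos"].values,
            "allele_effect": sub["allele_effect"].values,
            "allele_other": sub["allele_other"].values,
            "weight": wm.weights,
        }).to_csv(os.path.join(d, "weights", f"{gene}.tsv"), sep="\t", index=False)
        index_rows.append({"gene": gene, "model": wm.model_name, "cv_r2": wm.cv_r2,
                           "cv_p": wm.cv_p, "h2": wm.h2})
    pd.DataFrame(index_rows).to_csv(os.path.join(d, "index.tsv"), sep="\t", index=False)
    _write_manifest(d, _manifest(d, params, inputs, {"genes_with_weights": len(index_rows)}))


def _load_weight(run_dir: str, gene: str, meta: pd.Series) -> w_mod.WeightModel:
    t = pd.read_csv(os.path.join(run_dir, "train", "weights", f"{gene}.tsv"), sep="\t")
    return w_mod.WeightModel(
        gene=gene, model_name=str(meta["model"]), weights=t["weight"].to_numpy(),
        cv_r2=float(meta["cv_r2"]), cv_p=float(meta["cv_p"]), h2=float(meta["h2"]),
        variant_ids=t["variant"].astype(str).tolist(),
    )


def _stage_assoc(cfg: PipelineConfig, run_dir: str) -> None:
    d = os.path.join(run_dir, "assoc")
    os.makedirs(d, exist_ok=True)
    params = {"fdr": cfg.fdr}
    inputs = [cfg.gwas, os.path.join(run_dir, "train", "index.tsv")]
    if _stage_fresh(d, params, inputs):
        logger.info("assoc: manifest unchanged, skipping")
        return
    panel = _load_panel(run_dir)
    gwas = assoc_mod.read_gwas_tsv(cfg.gwas)
    index = pd.read_csv(os.path.join(run_dir, "train", "index.tsv"), sep="\t")
    results = []
    for _, meta in index.iterrows():
        wm = _load_weight(run_dir, meta["gene"], meta)
        aligned = assoc_mod.harmonize_alleles(wm, gwas, panel)
        if aligned is None:
            continue
        V = assoc_mod.ld_matrix(panel, aligned.panel_indices)
        res = assoc_mod.twas_z(aligned.weights, aligned.z, V, gene=wm.gene,
                               best_model=wm.model_name)
        if res is None:
            continue
        results.append(res)
    if results:
        q = assoc_mod.bh_fdr(np.array([r.p for r in results]))
        for r, qv in zip(results, q):
            r.q = float(qv)
    pd.DataFrame([asdict(r) for r in results]).to_csv(
        os.path.join(d, "results.tsv"), sep="\t", index=False)
    _write_manifest(d, _manifest(d, params, inputs, {"genes_tested": len(results)}))


def _marginal_eqtl(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP marginal eQTL beta (= r on standardized data) and se."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sx[sx == 0] = np.inf
    r = (Xc.T @ yc) / (sx * np.sqrt((yc ** 2).sum()))
    r = np.clip(r, -0.999999, 0.999999)
    df = n - 2
    se = np.sqrt((1.0 - r ** 2) / df)
    return r, se


def _stage_refine(cfg: PipelineConfig, run_dir: str) -> None:
    d = os.path.join(run_dir, "refine")
    os.makedirs(d, exist_ok=True)
    params = {"fdr": cfg.fdr, "flank": cfg.flank}
    inputs = [os.path.join(run_dir, "assoc", "results.tsv")]
    if _stage_fresh(d, params, inputs):
        logger.info("refine: manifest unchanged, skipping")
        return
    res = pd.read_csv(os.path.join(run_dir, "assoc", "results.tsv"), sep="\t")
    out_rows: list[dict] = []
    if len(res):
        sig = res[res["q"] < cfg.fdr]
    else:
        sig = res
    if len(sig):
        panel = _load_panel(run_dir)
        sets = _load_prepared(cfg, run_dir)
        tr = training_design(panel, sets)
        gwas = assoc_mod.read_gwas_tsv(cfg.gwas)
        index = pd.read_csv(os.path.join(run_dir, "train", "index.tsv"),
                            sep="\t").set_index("gene")
        ann = pd.read_csv(cfg.annotation, sep="\t", dtype={"chrom": str}).set_index("gene")
        wins = ann.loc[[g for g in sig["gene"] if g in ann.index]].reset_index()
        loci = locus_mod.define_loci(wins, cfg.flank)
        zmap = dict(zip(res["gene"], res["z_twas"]))
        for locus_id in sorted(loci.unique()):
            genes = [g for g in loci.index if loci[g] == locus_id]
            aligned = {}
            for g in genes:
                wm = _load_weight(run_dir, g, index.loc[g])
                a = assoc_mod.harmonize_alleles(wm, gwas, panel)
                if a is not None:
                    aligned[g] = a
            genes = [g for g in genes if g in aligned]
            if not genes:
                continue
            union = sorted({i for g in genes for i in aligned[g].panel_indices})
            upos = {v: j for j, v in enumerate(union)}
            V = assoc_mod.ld_matrix(panel, np.array(union))
            W = np.zeros((len(genes), len(union)))
            for gi, g in enumerate(genes):
                for i, w in zip(aligned[g].panel_indices, aligned[g].weights):
                    W[gi, upos[i]] = w
            omega = locus_mod.predicted_expression_correlation(W, V)
            rep = locus_mod.LocusReport(
                locus=int(locus_id), genes=genes, omega=omega,
                z_marginal=np.array([zmap[g] for g in genes]))
            rep = locus_mod.jcp(rep, cfg.fdr)
            for g in genes:
                gi = tr["genes"].index(g) if g in tr["genes"] else None
                smr_T = smr_p = np.nan
                pp = [np.nan] * 5
                if gi is not None:
                    y = tr["Y"][gi]
                    ok = ~np.isnan(y)
                    idx = aligned[g].panel_indices
                    X = panel.dosages[np.ix_(tr["rows"][ok], idx)]
                    X = qc_mod.standardize_dosages(X)
                    r, se_e = _marginal_eqtl(X, y[ok])
                    top = int(np.argmax(np.abs(r)))
                    df = ok.sum() - 2
                    z_e = r[top] * np.sqrt(df / max(1 - r[top] ** 2, 1e-12))
                    z_g = aligned[g].z[top]
                    smr_T, smr_p = locus_mod.smr(float(z_e), float(z_g))
                    pp = locus_mod.coloc_abf(
                        aligned[g].beta, aligned[g].se, r, se_e).tolist()
                out_rows.append({
                    "gene": g, "locus": int(locus_id),
                    "z_marginal": zmap[g],
                    "z_joint": rep.z_joint.get(g, np.nan),
                    "z_conditional": rep.z_conditional.get(g, np.nan),
                    "jcp_p": rep.jcp_p.get(g, np.nan),
                    "class": rep.classification.get(g, ""),
                    "smr_T": smr_T, "smr_p": smr_p,
                    "pp_h0": pp[0], "pp_h1": pp[1], "pp_h2": pp[2],
                    "pp_h3": pp[3], "pp_h4": pp[4],
                })
    cols = ["gene", "locus", "z_marginal", "z_joint", "z_conditional", "jcp_p",
            "class", "smr_T", "smr_p", "pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4"]
    pd.DataFrame(out_rows, columns=cols).to_csv(
        os.path.join(d, "locus_report.tsv"), sep="\t", index=False)
    _write_manifest(d, _manifest(d, params, inputs, {"genes_refined": len(out_rows)}))


def _stage_expand(cfg: PipelineConfig, run_dir: str) -> None:
    d = os.path.join(run_dir, "expand")
    os.makedirs(d, exist_ok=True)
    params = {"B": cfg.B_bootstrap, "sd_multiplier": cfg.sd_multiplier,
              "top_k": cfg.top_k, "seed": cfg.seed}
    inputs = [os.path.join(run_dir, "refine", "locus_report.tsv")]
    if _stage_fresh(d, params, inputs):
        logger.info("expand: manifest unchanged, skipping")
        return
    rep = pd.read_csv(os.path.join(run_dir, "refine", "locus_report.tsv"), sep="\t")
    keep = rep[rep["class"] == "joint"]["gene"].tolist() if len(rep) else []
    sets = _load_prepared(cfg, run_dir)
    ann = pd.read_csv(cfg.annotation, sep="\t", dtype={"chrom": str})
    universe = sorted({g for es in sets for g in es.genes})
    edges = pd.read_csv(cfg.edges, sep="\t") if cfg.edges and os.path.exists(cfg.edges) else None
    markers = None
    if cfg.markers and os.path.exists(cfg.markers):
        mt = pd.read_csv(cfg.markers, sep="\t")
        markers = {t: sub.iloc[:, 1].astype(str).tolist()
                   for t, sub in mt.groupby(mt.columns[0])}
    rows, enr_rows = [], []
    for gene in keep:
        exp = gs_mod.expand_gene(
            gene, sets, ann, flank=cfg.flank, B=cfg.B_bootstrap, seed=cfg.seed,
            sd_multiplier=cfg.sd_multiplier, top_k=cfg.top_k, edges=edges,
            expressed_universe=universe)
        rows.append({"gene": gene, "n_included": len(exp.included_genes),
                     "cis_coregulated": ",".join(exp.cis_coregulated),
                     "n_broad": len(exp.broad_set), "n_narrow": len(exp.narrow_set)})
        if markers:
            seed_set = ([gene] + exp.cis_coregulated
                        + list(exp.mean_partial_corr.abs().nlargest(cfg.top_k).index))
            for rec in gs_mod.marker_enrichment(exp.included_genes or seed_set,
                                                markers, universe):
                enr_rows.append({"gene": gene, "term": rec.term_id,
                                 "overlap": rec.overlap, "odds_ratio": rec.odds_ratio,
                                 "p": rec.p, "q": rec.q})
    pd.DataFrame(rows, columns=["gene", "n_included", "cis_coregulated",
                                "n_broad", "n_narrow"]).to_csv(
        os.path.join(d, "expansion.tsv"), sep="\t", index=False)
    pd.DataFrame(enr_rows, columns=["gene", "term", "overlap", "odds_ratio",
                                    "p", "q"]).to_csv(
        os.path.join(d, "enrichment.tsv"), sep="\t", index=False)
    _write_manifest(d, _manifest(d, params, inputs, {"genes_expanded": len(rows)}))


_STAGE_FUNCS = {
    "qc": _stage_qc, "normalize": _stage_normalize, "h2": _stage_h2,
    "train": _stage_train, "assoc": _stage_assoc, "refine": _stage_refine,
    "expand": _stage_expand,
}


def run_pipeline(config: PipelineConfig, run_dir: str) -> str:
    """Execute the enabled stages in order; abort with context on failure."""
    config.validate()
    os.makedirs(run_dir, exist_ok=True)
    for stage in ALL_STAGES:
        if stage not in config.stages:
            logger.info("stage %s toggled off", stage)
            continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    return run_dir


def report(run_dir: str) -> dict:
    """Summary tables: gene results sorted by q, QQ data, locus classes.

    The QQ table pairs expected vs observed -log10 p over the tested genes;
    ``lambda_gc`` is the median-chi-square genomic-inflation factor of the
    TWAS z-scores.
    """
    res_path = os.path.join(run_dir, "assoc", "results.tsv")
    if not os.path.exists(res_path):
        raise FileNotFoundError("assoc outputs missing; run the assoc stage first")
    res = pd.read_csv(res_path, sep="\t")
    if len(res) == 0:
        empty = pd.DataFrame(columns=["gene", "z_twas", "p", "q", "n_snps_used",
                                      "best_model"])
        qq = pd.DataFrame(columns=["expected", "observed"])
        return {"genes": empty, "qq": qq, "lambda_gc": np.nan, "loci": pd.DataFrame()}
    genes = res.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
    p = np.sort(res["p"].to_numpy(dtype=float))
    k = len(p)
    qq = pd.DataFrame({
        "expected": -np.log10((np.arange(1, k + 1) - 0.5) / k),
        "observed": -np.log10(np.clip(p, 1e-300, None)),
    })
    z = res["z_twas"].to_numpy(dtype=float)
    lam = float(np.median(z ** 2) / stats.chi2.ppf(0.5, 1))
    loc_path = os.path.join(run_dir, "refine", "locus_report.tsv")
    loci = pd.read_csv(loc_path, sep="\t") if os.path.exists(loc_path) else pd.DataFrame()
    return {"genes": genes, "qq": qq, "lambda_gc": lam, "loci": loci}
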