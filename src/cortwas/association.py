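"""Summary-statistic TWAS association, FDR, validation, and GWAS binning.

Given per-gene cis-SNP weights w, a GWAS z-vector z over the same SNPs, and
an LD matrix V from the reference panel, the gene association statistic is

    z_twas = w' z / sqrt(w' V w),

standard-normal under the null of no association.  V is shrunk towards the
identity (0.95 V + 0.05 I) before quadratic forms, which regularizes the
denominator against sampling noise in the reference LD.  Allele harmonization
sign-flips z where the GWAS effect/other alleles are swapped relative to the
panel and drops strand-ambiguous (A/T, C/G) SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionSet
from .genotype_qc import GenotypePanel, standardize_dosages
from .weights import WeightModel

logger = logging.getLogger(__name__)

__all__ = [
    "GwasSummary",
    "TwasResult",
    "AlignedGene",
    "read_gwas_tsv",
    "harmonize_alleles",
    "impute_expression",
    "twas_z",
    "bh_fdr",
    "validate_imputation",
    "gwas_bin_enrichment",
    "LD_SHRINK",
]

LD_SHRINK = 0.05
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

GWAS_COLUMNS = ["id", "chrom", "pos", "allele_effect", "allele_other",
                "beta", "se", "z", "n"]


@dataclass
class GwasSummary:
    """Per-SNP GWAS summary statistics (beta, se, z = beta/se, N)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS table missing columns: {missing}")
        t = self.table
        both = t["beta"].notna() & t["se"].notna() & t["z"].notna()
        if both.any():
            delta = (t.loc[both, "beta"] / t.loc[both, "se"] - t.loc[both, "z"]).abs()
            if (delta > 1e-6).any():
                raise ValueError("z inconsistent with beta/se")
        if (t["allele_effect"] == t["allele_other"]).any():
            raise ValueError("effect and other allele identical for some SNPs")


def read_gwas_tsv(path: str) -> GwasSummary:
    t = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    if "z" not in t.columns and {"beta", "se"} <= set(t.columns):
        t["z"] = t["beta"] / t["se"]
    return GwasSummary(t)


@dataclass
class TwasResult:
    gene: str
    z_twas: float
    p: float
    q: float
    n_snps_used: int
    best_model: str


@dataclass
class AlignedGene:
    """Weights, GWAS z, and panel indices harmonized to panel allele coding."""

    gene: str
    variant_ids: list[str]
    panel_indices: np.ndarray
    weights: np.ndarray
    z: np.ndarray
    beta: np.ndarray
    se: np.ndarray


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1.upper(), a2.upper()} in _AMBIGUOUS


def harmonize_alleles(
    weights: WeightModel, gwas: GwasSummary, ld_panel: GenotypePanel
) -> AlignedGene | None:
    """Intersect the gene's variants with the GWAS on the panel's coding.

    Ordering follows the LD panel.  GWAS z/beta are negated where the GWAS
    alleles are swapped relative to the panel (directly or after strand
    complement); SNPs with irreconcilable or strand-ambiguous alleles are
    dropped.  Returns None (logged) when no SNP survives.
    """
    pv = ld_panel.variants
    panel_pos = {vid: i for i, vid in enumerate(pv["id"])}
    gt = gwas.table.set_index("id")
    wmap = dict(zip(weights.variant_ids, weights.weights))

    idx, ws, zs, betas, ses, ids = [], [], [], [], [], []
    for vid in pv["id"]:
        if vid not in wmap or vid not in gt.index:
            continue
        i = panel_pos[vid]
        pa, po = str(pv.at[i, "allele_effect"]).upper(), str(pv.at[i, "allele_other"]).upper()
        ga, go = str(gt.at[vid, "allele_effect"]).upper(), str(gt.at[vid, "allele_other"]).upper()
        if _is_ambiguous(pa, po) or _is_ambiguous(ga, go):
            continue
        sign = None
        if (ga, go) == (pa, po):
            sign = 1.0
        elif (ga, go) == (po, pa):
            sign = -1.0
        else:
            ca = _COMPLEMENT.get(ga, "?")
            co = _COMPLEMENT.get(go, "?")
            if (ca, co) == (pa, po):
                sign = 1.0
            elif (ca, co) == (po, pa):
                sign = -1.0
        if sign is None:
            continue
        idx.append(i)
        ids.append(vid)
        ws.append(wmap[vid])
        zs.append(sign * float(gt.at[vid, "z"]))
        betas.append(sign * float(gt.at[vid, "beta"]))
        ses.append(float(gt.at[vid, "se"]))
    if not idx:
        logger.info("%s: no harmonizable SNP overlap with GWAS; gene skipped",
                    weights.gene)
        return None
    return AlignedGene(
        gene=weights.gene, variant_ids=ids, panel_indices=np.array(idx, dtype=int),
        weights=np.array(ws), z=np.array(zs), beta=np.array(betas), se=np.array(ses),
    )


def impute_expression(weights: WeightModel, panel: GenotypePanel) -> np.ndarray:
    """Per-sample imputed cis-genetic expression component Z_std @ w."""
    pos = {vid: i for i, vid in enumerate(panel.variants["id"])}
    try:
        cols = [pos[v] for v in weights.variant_ids]
    except KeyError as exc:
        raise ValueError(f"variant {exc} absent from panel") from exc
    Z = standardize_dosages(panel.dosages[:, cols])
    comp = Z @ weights.weights
    if np.std(comp) == 0:
        logger.warning("%s: imputed component has zero variance", weights.gene)
    return comp


def ld_matrix(panel: GenotypePanel, indices: np.ndarray, shrink: float = LD_SHRINK
              ) -> np.ndarray:
    Z = standardize_dosages(panel.dosages[:, indices])
    n = Z.shape[0]
    V = (Z.T @ Z) / (n - 1)
    return (1.0 - shrink) * V + shrink * np.eye(V.shape[0])


def twas_z(weights: np.ndarray, z: np.ndarray, V: np.ndarray, gene: str = "",
           best_model: str = "") -> TwasResult | None:
    """Gene association statistic w'z / sqrt(w'Vw); None if degenerate."""
    denom2 = float(weights @ V @ weights)
    if denom2 <= 1e-12:
        logger.info("%s: degenerate predictor (w'Vw ~ 0); skipped", gene)
        return None
    zt = float(weights @ z) / np.sqrt(denom2)
    p = 2.0 * float(stats.norm.sf(abs(zt)))
    return TwasResult(gene=gene, z_twas=zt, p=p, q=np.nan,
                      n_snps_used=int(np.sum(weights != 0)), best_model=best_model)


def bh_fdr(p: np.ndarray | list, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``m`` overrides the number of comparisons (>= len(p)) for conventions
    where the correction counts all matched comparisons, not just those with a
    computed p-value.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    k = p.size
    m = k if m is None else int(m)
    if m < k:
        raise ValueError("m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def validate_imputation(
    imputed: pd.DataFrame, observed: ExpressionSet, m_comparisons: int | None = None
) -> pd.DataFrame:
    """Kendall tau-b between imputed components and observed expression.

    ``imputed``: genes x samples frame (sample columns must overlap the
    observed set's samples; >= 10 shared required).  Returns a frame with
    per-gene tau, two-sided p, and BH q over the tested genes (or over
    ``m_comparisons`` when given).
    """
    shared = [s for s in observed.samples if s in imputed.columns]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples (< 10)")
    obs = pd.DataFrame(observed.values, index=observed.genes, columns=observed.samples)
    genes = [g for g in imputed.index if g in obs.index]
    rows = []
    for g in genes:
        tau, p = stats.kendalltau(imputed.loc[g, shared].to_numpy(),
                                  obs.loc[g, shared].to_numpy())
        rows.append({"gene": g, "tau": tau, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy(), m=m_comparisons)
    return out


# ---------------------------------------------------------------------------
# GWAS p-value binning around gene windows
# ---------------------------------------------------------------------------

@dataclass
class BinEnrichment:
    n_weighted: int
    n_unweighted: int
    n_intergenic: int
    p_weighted_vs_unweighted: float
    p_weighted_vs_intergenic: float
    bins: np.ndarray  # per-SNP label: 'weighted' | 'unweighted' | 'intergenic'


def _merge_windows(windows: pd.DataFrame, flank: int) -> dict:
    merged: dict = {}
    for chrom, sub in windows.groupby("chrom", sort=False):
        iv = np.column_stack([
            sub["tss"].to_numpy(dtype=np.int64) - flank,
            sub["tss"].to_numpy(dtype=np.int64) + flank,
        ])
        out = []
        for s, e in iv[np.argsort(iv[:, 0])]:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[str(chrom)] = np.array(out, dtype=np.int64)
    return merged


def _in_windows(chroms: np.ndarray, pos: np.ndarray, merged: dict) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for chrom, iv in merged.items():
        mask = chroms == chrom
        if not mask.any() or not len(iv):
            continue
        p = pos[mask]
        j = np.searchsorted(iv[:, 0], p, side="right") - 1
        ok = (j >= 0) & (p <= iv[np.clip(j, 0, len(iv) - 1), 1])
        hit[np.flatnonzero(mask)[ok]] = True
    return hit


def gwas_bin_enrichment(
    gwas: GwasSummary,
    weighted_genes: pd.DataFrame,
    unweighted_genes: pd.DataFrame,
    flank: int = 500_000,
) -> BinEnrichment:
    """Three-bin Wilcoxon enrichment of GWAS p-values around gene windows.

    Each SNP is assigned to exactly one bin with precedence weighted >
    unweighted > intergenic; one-sided rank-sum tests ask whether the weighted
    bin carries *lower* p-values than each other bin.  Gene frames need
    columns (gene, chrom, tss).
    """
    t = gwas.table
    chroms = t["chrom"].astype(str).to_numpy()
    pos = t["pos"].to_numpy(dtype=np.int64)
    pvals = 2.0 * stats.norm.sf(np.abs(t["z"].to_numpy(dtype=float)))
    in_w = _in_windows(chroms, pos, _merge_windows(weighted_genes, flank))
    in_u = _in_windows(chroms, pos, _merge_windows(unweighted_genes, flank)) & ~in_w
    bins = np.where(in_w, "weighted", np.where(in_u, "unweighted", "intergenic"))
    pw, pu, pi = pvals[in_w], pvals[in_u], pvals[~in_w & ~in_u]

    def _test(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) == 0 or len(b) == 0:
            return np.nan
        return float(stats.mannwhitneyu(a, b, alternative="less").pvalue)

    return BinEnrichment(
        n_weighted=int(in_w.sum()), n_unweighted=int(in_u.sum()),
        n_intergenic=int(len(pvals) - in_w.sum() - in_u.sum()),
        p_weighted_vs_unweighted=_test(pw, pu),
        p_weighted_vs_intergenic=_test(pw, pi),
        bins=bins,
    )
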