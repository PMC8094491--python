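"""Co-expression gene-set expansion and cell-type / process enrichment.

Each trait-associated gene is expanded into a functional gene set in four
steps: (1) bootstrapped sparse partial regression of the target gene on all
other genes, per tissue, averaged into one mean partial-correlation vector;
(2) a cis co-regulation check that flags neighbors within the cis-window whose
mean correlation exceeds 0.1 (candidate co-regulated drivers); (3) inclusion
cutoffs expressed as standard deviations of the mean partial correlations away
from their center, with an elbow diagnostic for choosing the multiplier;
(4) expansion through a protein-interaction edge list into broad (appearing
more than once) and narrow (more than twice) sets, filtered to the
expressed-gene universe.  Enrichment of the resulting sets against marker or
term lists uses a two-sided exact binomial test with an observed/expected
odds ratio and BH correction over the comparisons.

The sparse estimator inside the bootstrap is pluggable; the default selects a
support by elastic net and converts OLS-refit t-statistics to partial
correlations (r = t / sqrt(t^2 + df)), a statistic that does not depend on the
particular sparse fitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet

from .expression import ExpressionSet
from .heritability import CisWindow

logger = logging.getLogger(__name__)

__all__ = [
    "ExpansionResult",
    "EnrichmentRecord",
    "bootstrap_partial_regression",
    "cis_coregulation_check",
    "sd_cutoff_inclusion",
    "elbow_curve",
    "network_expand",
    "marker_enrichment",
    "expand_gene",
]


@dataclass
class ExpansionResult:
    seed_gene: str
    mean_partial_corr: pd.Series
    sd_cutoff: float
    included_genes: list[str] = field(default_factory=list)
    cis_coregulated: list[str] = field(default_factory=list)
    broad_set: list[str] = field(default_factory=list)
    narrow_set: list[str] = field(default_factory=list)


@dataclass
class EnrichmentRecord:
    set_id: str
    term_id: str
    overlap: int
    odds_ratio: float
    p: float
    q: float = np.nan
    zero_overlap: bool = False


def _partial_corr_one(x: np.ndarray, G: np.ndarray, alpha_frac: float = 0.1,
                      max_support: int | None = None) -> np.ndarray:
    """Sparse partial-correlation vector of target x against predictor rows G.

    Elastic net selects a support; OLS refit on the support yields
    t-statistics converted to partial correlations.  Genes outside the
    support get 0.
    """
    n = len(x)
    p = G.shape[0]
    out = np.zeros(p)
    Xp = G.T  # (n, p)
    lam_max = np.max(np.abs(Xp.T @ (x - x.mean()))) / (n * 0.5)
    if lam_max <= 0:
        return out
    model = ElasticNet(alpha=alpha_frac * lam_max, l1_ratio=0.5, max_iter=2000)
    model.fit(Xp, x)
    support = np.flatnonzero(model.coef_)
    if support.size == 0:
        return out
    cap = max_support or max(2, n // 3)
    if support.size > cap:
        support = support[np.argsort(-np.abs(model.coef_[support]))[:cap]]
        support = np.sort(support)
    Xs = np.column_stack([np.ones(n), Xp[:, support]])
    df = n - Xs.shape[1]
    if df < 2:
        return out
    coef, _, rank, _ = np.linalg.lstsq(Xs, x, rcond=None)
    resid = x - Xs @ coef
    s2 = float(resid @ resid) / df
    XtX_inv = np.linalg.pinv(Xs.T @ Xs)
    se = np.sqrt(np.clip(s2 * np.diag(XtX_inv), 1e-300, None))
    t = coef / se
    out[support] = t[1:] / np.sqrt(t[1:] ** 2 + df)
    return out


def bootstrap_partial_regression(
    target: str,
    expression_sets: list[ExpressionSet],
    B: int = 100,
    seed: int = 0,
    estimator=_partial_corr_one,
) -> pd.Series:
    """Mean partial correlation of every other gene with the target.

    Per tissue and bootstrap replicate (individuals resampled with
    replacement, all their samples carried along), the sparse partial
    regression of the target on all other genes is computed; partial
    correlations are averaged over replicates, then tissues.  The target gene
    itself is never in the output.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    per_tissue: list[pd.Series] = []
    for es in expression_sets:
        if target not in es.genes:
            logger.info("%s absent from tissue %s; tissue skipped", target, es.tissue)
            continue
        gi = es.genes.index(target)
        others = [g for g in es.genes if g != target]
        oi = [es.genes.index(g) for g in others]
        inds = np.array(es.individuals)
        uniq = np.unique(inds)
        cols_of = {u: np.flatnonzero(inds == u) for u in uniq}
        acc = np.zeros(len(others))
        for _ in range(B):
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            cols = np.concatenate([cols_of[u] for u in chosen])
            x = es.values[gi, cols]
            G = es.values[oi][:, cols]
            if x.std() == 0:
                continue
            acc += estimator(x, G)
        per_tissue.append(pd.Series(acc / B, index=others))
    if not per_tissue:
        raise ValueError(f"target {target} absent from every tissue")
    mat = pd.concat(per_tissue, axis=1)
    return mat.mean(axis=1)


def cis_coregulation_check(
    target: str,
    mean_corr: pd.Series,
    window: CisWindow,
    annotation: pd.DataFrame,
    threshold: float = 0.1,
) -> list[str]:
    """Genes in the target's cis-window whose mean correlation exceeds the
    threshold (candidate co-regulated drivers to add to the seed set).

    ``annotation`` needs columns (gene, chrom, tss).
    """
    lo, hi = window.tss - window.flank, window.tss + window.flank
    in_cis = annotation[
        (annotation["chrom"].astype(str) == str(window.chrom))
        & (annotation["tss"] >= lo) & (annotation["tss"] <= hi)
        & (annotation["gene"] != target)
    ]["gene"]
    return [g for g in in_cis if g in mean_corr.index and mean_corr[g] > threshold]


def sd_cutoff_inclusion(mean_corr: pd.Series, s: float) -> list[str]:
    """Genes whose mean partial correlation lies more than s standard
    deviations from the vector's mean."""
    if s <= 0:
        raise ValueError("sd multiplier must be positive")
    v = mean_corr.to_numpy(dtype=float)
    sd = v.std()
    if sd == 0:
        return []
    mu = v.mean()
    keep = np.abs(v - mu) > s * sd
    return [g for g, k in zip(mean_corr.index, keep) if k]


def elbow_curve(mean_corr: pd.Series, s_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Set size as a function of the SD multiplier (diagnostic for choosing s)."""
    if s_grid is None:
        s_grid = np.arange(0.1, 3.01, 0.1)
    return pd.DataFrame({
        "s": s_grid,
        "set_size": [len(sd_cutoff_inclusion(mean_corr, s)) for s in s_grid],
    })


def network_expand(
    seed_set: list[str],
    edges: pd.DataFrame,
    expressed_universe: list[str],
) -> tuple[list[str], list[str]]:
    """Broad/narrow interaction-network expansion of a seed gene set.

    All (deduplicated, undirected) edges touching the seed set are extracted;
    every non-seed gene is counted by the number of extracted edges it sits
    on.  Broad = count > 1, narrow = count > 2, both intersected with the
    expressed-gene universe.  ``edges`` needs two columns (gene_a, gene_b).
    """
    seed = set(seed_set)
    universe = set(expressed_universe)
    a = edges.iloc[:, 0].astype(str)
    b = edges.iloc[:, 1].astype(str)
    canon = {tuple(sorted(e)) for e in zip(a, b) if e[0] != e[1]}
    counts: dict = {}
    for u, v in canon:
        if u in seed or v in seed:
            for g in (u, v):
                if g not in seed:
                    counts[g] = counts.get(g, 0) + 1
    broad = sorted(g for g, c in counts.items() if c > 1 and g in universe)
    narrow = sorted(g for g, c in counts.items() if c > 2 and g in universe)
    return broad, narrow


def marker_enrichment(
    gene_set: list[str],
    markers: dict,
    universe: list[str],
) -> list[EnrichmentRecord]:
    """Over-representation of a gene set in each marker/term list.

    Genes outside the universe are dropped (logged).  For marker list M,
    universe U, and test set S (after intersection with U):
    OR = (|S & M| / |S|) / (|M| / |U|), p from the two-sided exact binomial
    test of k = |S & M| successes in n = |S| trials at p0 = |M| / |U|; q is BH
    over the marker lists.
    """
    uni = set(universe)
    S = [g for g in dict.fromkeys(gene_set) if g in uni]
    dropped = len(set(gene_set)) - len(S)
    if dropped:
        logger.info("marker_enrichment: dropped %d set genes outside universe", dropped)
    records = []
    n = len(S)
    for term, genes in markers.items():
        M = set(genes) & uni
        if not M or n == 0:
            records.append(EnrichmentRecord(
                set_id="set", term_id=term, overlap=0, odds_ratio=0.0, p=1.0,
                zero_overlap=True))
            continue
        k = len(set(S) & M)
        p0 = len(M) / len(uni)
        pv = float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
        orat = (k / n) / p0
        records.append(EnrichmentRecord(
            set_id="set", term_id=term, overlap=k, odds_ratio=orat, p=pv,
            zero_overlap=(k == 0)))
    if records:
        from .association import bh_fdr
        q = bh_fdr(np.array([r.p for r in records]))
        for r, qv in zip(records, q):
            r.q = float(qv)
    return records


def expand_gene(
    target: str,
    expression_sets: list[ExpressionSet],
    annotation: pd.DataFrame,
    *,
    flank: int = 500_000,
    B: int = 100,
    seed: int = 0,
    sd_multiplier: float = 1.3,
    top_k: int = 50,
    edges: pd.DataFrame | None = None,
    expressed_universe: list[str] | None = None,
) -> ExpansionResult:
    """Full expansion for one associated gene: bootstrap partial regression,
    cis co-regulation check, SD-cutoff inclusion, and optional network growth."""
    corr = bootstrap_partial_regression(target, expression_sets, B=B, seed=seed)
    universe = (expressed_universe if expressed_universe is not None
                else sorted({g for es in expression_sets for g in es.genes}))
    cis: list[str] = []
    arow = annotation[annotation["gene"] == target]
    if len(arow):
        win = CisWindow(target, str(arow.iloc[0]["chrom"]),
                        int(arow.iloc[0]["tss"]), flank, ())
        cis = cis_coregulation_check(target, corr, win, annotation)
    included = sd_cutoff_inclusion(corr, sd_multiplier)
    seed_set = [target] + cis + list(corr.abs().nlargest(top_k).index)
    broad: list[str] = []
    narrow: list[str] = []
    if edges is not None:
        broad, narrow = network_expand(seed_set, edges, universe)
    return ExpansionResult(
        seed_gene=target, mean_partial_corr=corr, sd_cutoff=sd_multiplier,
        included_genes=included, cis_coregulated=cis,
        broad_set=broad, narrow_set=narrow,
    )
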