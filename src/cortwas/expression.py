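"""Per-tissue expression preparation: covariate regression and scaling.

Bulk RNA-seq expression is adjusted within tissue before weight training:
significant covariates are regressed out iteratively (diagnosis always, as is
standard in TWAS/eQTL work since cis-genetic regulation is largely
condition-independent), then each gene is standardized to mean 0, sd 1 so the
trainer can consume pre-scaled values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ExpressionSet", "iterative_covariate_regression", "scale_expression", "prepare"]


@dataclass
class ExpressionSet:
    """Gene-by-sample expression for one tissue, plus sample metadata.

    ``sample_to_individual`` carries the repeated-measure design: several
    samples (tissues) may map to the same genotyped individual.
    """

    tissue: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray  # (n_genes, n_samples)
    covariates: pd.DataFrame  # indexed by sample id
    sample_to_individual: dict

    def __post_init__(self) -> None:
        g, s = self.values.shape
        if len(self.genes) != g or len(self.samples) != s:
            raise ValueError("values shape inconsistent with gene/sample lists")
        if len(set(self.samples)) != s:
            raise ValueError("sample ids must be unique")
        missing = [s_ for s_ in self.samples if s_ not in self.sample_to_individual]
        if missing:
            raise ValueError(f"samples without individual mapping: {missing[:5]}")

    @property
    def individuals(self) -> list[str]:
        return [self.sample_to_individual[s] for s in self.samples]

    def to_tsv(self, expr_path: str, cov_path: str | None = None,
               map_path: str | None = None) -> None:
        pd.DataFrame(self.values, index=self.genes, columns=self.samples).to_csv(
            expr_path, sep="\t", index_label="gene")
        if cov_path is not None:
            self.covariates.to_csv(cov_path, sep="\t", index_label="sample")
        if map_path is not None:
            pd.DataFrame({
                "sample": self.samples,
                "individual": [self.sample_to_individual[s] for s in self.samples],
            }).to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, tissue: str, expr_path: str, cov_path: str,
                 map_path: str) -> "ExpressionSet":
        mat = pd.read_csv(expr_path, sep="\t", index_col=0)
        cov = pd.read_csv(cov_path, sep="\t", index_col=0)
        smap = pd.read_csv(map_path, sep="\t", dtype=str)
        mapping = dict(zip(smap["sample"], smap["individual"]))
        return cls(
            tissue=tissue,
            genes=[str(g) for g in mat.index],
            samples=[str(s) for s in mat.columns],
            values=mat.to_numpy(dtype=float),
            covariates=cov.loc[[str(s) for s in mat.columns]],
            sample_to_individual=mapping,
        )


def _residualize(values: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each gene row after regressing on columns of X (+intercept)."""
    n = values.shape[1]
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    return values - (design @ coef).T


def _median_p(values: np.ndarray, x: np.ndarray) -> float:
    """Median across genes of the per-gene p-value for covariate x."""
    n = values.shape[1]
    xc = x - x.mean()
    sx = np.sqrt((xc ** 2).sum())
    if sx == 0:
        return 1.0
    yc = values - values.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc ** 2).sum(axis=1))
    sy[sy == 0] = np.inf
    r = (yc @ xc) / (sy * sx)
    r = np.clip(r, -0.999999999, 0.999999999)
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return float(np.median(p))


def iterative_covariate_regression(
    es: ExpressionSet,
    alpha: float = 0.05,
    max_iter: int = 10,
    always_regress: tuple[str, ...] = ("diagnosis",),
) -> ExpressionSet:
    """Iteratively regress out covariates that are significant across genes.

    Each round, every remaining candidate covariate is tested per gene against
    the current residuals; its significance is summarized by the *median*
    per-gene p-value.  All covariates with median p < ``alpha`` are regressed
    out jointly and removed from the candidate pool; the loop repeats on the
    residuals until nothing is significant or ``max_iter`` rounds have run.
    Diagnosis is regressed regardless of significance.  Constant covariates
    are dropped with a warning.
    """
    cov = es.covariates.loc[es.samples]
    if cov.isna().any().any():
        raise ValueError("covariates must be complete for all samples")
    values = es.values.astype(float).copy()

    candidates: list[str] = []
    for c in cov.columns:
        x = cov[c].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("covariate %s is constant in tissue %s; dropped", c, es.tissue)
            continue
        candidates.append(c)

    regressed = [c for c in always_regress if c in candidates]
    candidates = [c for c in candidates if c not in regressed]
    if regressed:
        values = _residualize(es.values, cov[regressed].to_numpy(dtype=float))

    for _ in range(max_iter):
        sig = [c for c in candidates
               if _median_p(values, cov[c].to_numpy(dtype=float)) < alpha]
        if not sig:
            break
        regressed.extend(sig)
        candidates = [c for c in candidates if c not in sig]
        # joint refit on the original values keeps residuals exactly
        # orthogonal to every covariate regressed so far
        values = _residualize(es.values, cov[regressed].to_numpy(dtype=float))

    return replace(es, values=values)


def scale_expression(es: ExpressionSet) -> ExpressionSet:
    """Standardize each gene row to mean 0, sd 1 (sample sd, n-1).

    Zero-variance genes are dropped and logged; the operation is idempotent.
    """
    mu = es.values.mean(axis=1, keepdims=True)
    sd = es.values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("scale_expression: dropped %d zero-variance genes in %s",
                    dropped, es.tissue)
    scaled = (es.values[keep] - mu[keep]) / sd[keep]
    return replace(es, genes=[g for g, k in zip(es.genes, keep) if k], values=scaled)


def prepare(es: ExpressionSet, alpha: float = 0.05, max_iter: int = 10) -> ExpressionSet:
    """Covariate regression followed by scaling: the trainer's input contract."""
    return scale_expression(iterative_covariate_regression(es, alpha, max_iter))
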