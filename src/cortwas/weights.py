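"""Per-gene cis-SNP predictive weights with repeated-measure-aware CV.

Four models are fit per gene on standardized cis genotypes and scaled
expression — top1 (single best marginal eQTL), blup (ridge with shrinkage set
by the estimated h2), lasso, and enet (elastic net, mixing 0.5) — and the
model with the best group-aware cross-validated R2 is kept and refit on all
data.  Because several tissue samples can come from one genotyped individual,
folds are assigned to *individuals* (greedy bin-packing by descending sample
count), so no individual's samples ever straddle a train/test split, and fold
sizes stay within 5% of one another whenever n/k >= 20.

The CV significance is computed with the number of *individuals* as the
effective sample size, not the number of samples, to respect the repeated
measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import enet_path, lasso_path

logger = logging.getLogger(__name__)

__all__ = [
    "WeightModel",
    "FoldAssignment",
    "make_group_folds",
    "fit_top1",
    "fit_blup",
    "fit_lasso_enet",
    "cross_validate_and_select",
    "DEFAULT_MODELS",
]

DEFAULT_MODELS = ("top1", "blup", "lasso", "enet")
_N_LAMBDA = 15
_LAMBDA_MIN_RATIO = 0.01
_ENET_L1_RATIO = 0.5


@dataclass
class WeightModel:
    """Trained cis-SNP weights for one gene (standardized-genotype scale)."""

    gene: str
    model_name: str
    weights: np.ndarray
    cv_r2: float
    cv_p: float
    h2: float
    variant_ids: list[str]
    allele_effect: list[str] | None = None
    allele_other: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.variant_ids):
            raise ValueError("weights length must equal variant id count")


@dataclass
class FoldAssignment:
    sample_fold: dict  # sample id -> fold 1..k
    individual_fold: dict  # individual id -> fold 1..k
    k: int
    sample_to_individual: dict | None = None

    def fold_ids(self, samples: list[str]) -> np.ndarray:
        return np.array([self.sample_fold[s] for s in samples], dtype=int)

    def n_individuals(self, samples: list[str]) -> int:
        if self.sample_to_individual is None:
            return len(set(samples))
        return len({self.sample_to_individual[s] for s in samples})


def make_group_folds(sample_to_individual: dict, k: int, seed: int = 0) -> FoldAssignment:
    """Assign individuals (hence all their samples) to k folds.

    Greedy bin-packing: individuals sorted by descending sample count with a
    seeded random tie order, each placed into the currently smallest fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: dict = {}
    for s, ind in sample_to_individual.items():
        counts[ind] = counts.get(ind, 0) + 1
    individuals = list(counts)
    if k > len(individuals):
        raise ValueError(f"k={k} exceeds number of individuals ({len(individuals)})")
    rng = np.random.default_rng(seed)
    order = sorted(individuals, key=lambda i: (-counts[i], rng.random()))
    fold_sizes = np.zeros(k, dtype=int)
    individual_fold: dict = {}
    for ind in order:
        f = int(np.argmin(fold_sizes))
        individual_fold[ind] = f + 1
        fold_sizes[f] += counts[ind]
    sample_fold = {s: individual_fold[ind] for s, ind in sample_to_individual.items()}
    n = len(sample_to_individual)
    if n / k >= 20:
        mean = n / k
        spread = np.max(np.abs(fold_sizes - mean)) / mean
        if spread > 0.05:
            logger.warning("fold sizes deviate %.1f%% from the mean", 100 * spread)
    return FoldAssignment(sample_fold, individual_fold, k, dict(sample_to_individual))


# ---------------------------------------------------------------------------
# Individual models (X standardized columns, y scaled)
# ---------------------------------------------------------------------------

def _corr_with_y(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    denom[denom == 0] = np.inf
    return (Xc.T @ yc) / denom


def fit_top1(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Single nonzero weight at the variant with max |marginal correlation|.

    The weight is the marginal OLS slope on standardized data; ties break to
    the lowest variant index (np.argmax convention).
    """
    r = _corr_with_y(X, y)
    j = int(np.argmax(np.abs(r)))
    w = np.zeros(X.shape[1])
    xj = X[:, j] - X[:, j].mean()
    ss = float(xj @ xj)
    if ss > 0:
        w[j] = float(xj @ (y - y.mean())) / ss
    return w


def fit_blup(X: np.ndarray, y: np.ndarray, h2: float) -> np.ndarray:
    """Ridge solution w = (X'X + m (1-h2)/h2 I)^-1 X'y on standardized X."""
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"blup requires h2 in (0, 1); got {h2}")
    m = X.shape[1]
    shrink = m * (1.0 - h2) / h2
    A = X.T @ X + shrink * np.eye(m)
    return np.linalg.solve(A, X.T @ y)


def _lambda_grid(X: np.ndarray, y: np.ndarray, l1_ratio: float) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * l1_ratio)
    lam_max = max(lam_max, 1e-8)
    return lam_max * np.logspace(0.0, np.log10(_LAMBDA_MIN_RATIO), _N_LAMBDA)


def _path_fit(X: np.ndarray, y: np.ndarray, model_name: str,
              alphas: np.ndarray) -> np.ndarray:
    """Coefficient matrix (m, n_alphas) along a penalty path."""
    if model_name == "lasso":
        _, coefs, _ = lasso_path(X, y, alphas=alphas)
    elif model_name == "enet":
        _, coefs, _ = enet_path(X, y, l1_ratio=_ENET_L1_RATIO, alphas=alphas)
    else:
        raise ValueError(f"unknown sparse model {model_name!r}")
    # sklearn returns coefficients ordered by the alphas given
    return coefs


def fit_lasso_enet(
    X: np.ndarray, y: np.ndarray, model_name: str, folds: np.ndarray
) -> np.ndarray:
    """Coordinate-descent lasso/enet weights, lambda chosen by group-aware CV.

    The penalty grid spans [lambda_max, 0.01*lambda_max] (15 log-spaced
    points); the inner CV reuses exactly the fold labels supplied, and the
    final weights are refit on all provided rows at the chosen lambda.
    Returns the zero vector when every lambda yields an all-zero solution
    (callers flag and drop the gene).
    """
    l1_ratio = 1.0 if model_name == "lasso" else _ENET_L1_RATIO
    alphas = _lambda_grid(X, y, l1_ratio)
    uniq = np.unique(folds)
    oof = np.zeros((len(y), len(alphas)))
    for f in uniq:
        test = folds == f
        if test.all() or (~test).sum() < 2:
            continue
        coefs = _path_fit(X[~test], y[~test], model_name, alphas)
        oof[test] = X[test] @ coefs + y[~test].mean()
    r2 = np.empty(len(alphas))
    for a in range(len(alphas)):
        pred = oof[:, a]
        if np.std(pred) == 0:
            r2[a] = -np.inf
            continue
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2[a] = 1.0 - ss_res / ss_tot
    best = int(np.argmax(r2))
    coefs = _path_fit(X, y, model_name, alphas)
    w = coefs[:, best]
    if not np.any(w):
        logger.info("%s produced an all-zero path solution", model_name)
    return w


# ---------------------------------------------------------------------------
# Cross-validated model selection
# ---------------------------------------------------------------------------

def _fit_model(model_name: str, X: np.ndarray, y: np.ndarray, h2: float,
               folds: np.ndarray) -> np.ndarray:
    if model_name == "top1":
        return fit_top1(X, y)
    if model_name == "blup":
        return fit_blup(X, y, h2)
    if model_name in ("lasso", "enet"):
        return fit_lasso_enet(X, y, model_name, folds)
    raise ValueError(f"unknown model {model_name!r}")


def cross_validate_and_select(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    h2: float,
    sample_ids: list[str],
    gene: str = "",
    variant_ids: list[str] | None = None,
    models: tuple[str, ...] = DEFAULT_MODELS,
) -> WeightModel | None:
    """Out-of-fold evaluation of each model, selection, and full refit.

    cv_r2 is the squared correlation between assembled out-of-fold predictions
    and y; cv_p comes from the correlation t-test with the number of
    *individuals* as the effective n.  Genes whose best cv_r2 is not positive
    are dropped (``None``) — they would impute a zero-variance component.
    """
    fold_ids = folds.fold_ids(sample_ids)
    n_eff = folds.n_individuals(sample_ids)
    usable = h2 if 0.0 < h2 < 1.0 else 0.5
    results: dict[str, tuple[float, float]] = {}
    for model_name in models:
        oof = np.full(len(y), np.nan)
        for f in np.unique(fold_ids):
            test = fold_ids == f
            train = ~test
            assert not np.any(test & train), "train/test overlap"
            w = _fit_model(model_name, X[train], y[train], usable, fold_ids[train])
            oof[test] = X[test] @ w
        if np.isnan(oof).any() or np.std(oof) == 0:
            results[model_name] = (0.0, 1.0)
            continue
        r = float(np.corrcoef(oof, y)[0, 1])
        if not np.isfinite(r):
            results[model_name] = (0.0, 1.0)
            continue
        cv_r2 = r * r
        df = max(n_eff - 2, 1)
        t = abs(r) * np.sqrt(df / max(1.0 - r * r, 1e-12))
        cv_p = 2.0 * float(stats.t.sf(t, df))
        results[model_name] = (cv_r2, cv_p)

    best_model = max(results, key=lambda mdl: results[mdl][0])
    best_r2, best_p = results[best_model]
    if best_r2 <= 0.0:
        logger.info("%s: best cv_r2 <= 0; gene dropped", gene)
        return None
    w_full = _fit_model(best_model, X, y, usable, fold_ids)
    if not np.any(w_full):
        logger.info("%s: selected model refit to all-zero weights; dropped", gene)
        return None
    ids = variant_ids if variant_ids is not None else [f"v{j}" for j in range(X.shape[1])]
    return WeightModel(
        gene=gene, model_name=best_model, weights=w_full,
        cv_r2=best_r2, cv_p=best_p, h2=h2, variant_ids=list(ids),
    )


def weights_to_frame(models: list[WeightModel]) -> pd.DataFrame:
    rows = []
    for wm in models:
        for vid, w in zip(wm.variant_ids, wm.weights):
            rows.append({"gene": wm.gene, "variant": vid, "weight": w,
                         "model": wm.model_name, "cv_r2": wm.cv_r2,
                         "cv_p": wm.cv_p, "h2": wm.h2})
    return pd.DataFrame(rows)
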