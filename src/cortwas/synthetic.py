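"""Synthetic cohort generator with known ground truth.

Emulates the study design the pipeline is built for: a merged genotype panel
of European-ancestry individuals, multi-tissue neocortical RNA-seq with a
shared cis-genetic expression component per individual, and GWAS summary
statistics whose signal at simulated loci is (optionally) mediated by gene
expression.  Every downstream stage — QC, normalization, heritability,
weight training, association, refinement — can therefore be tested against
parameters the generator knows exactly.

Model
-----
Genotypes: per locus, two haplotypes per individual from a first-order Markov
"mosaic": the allele at variant j copies the allele at variant j-1 with
probability ``ld_decay`` and is otherwise drawn fresh at that variant's target
allele frequency.  Adjacent-variant allele (and hence dosage) correlation
equals the decay constant, and correlation decays geometrically with variant
distance — an AR(1)-correlation panel on the scale the downstream math
consumes (the LD matrix).

Expression: one gene per locus; y_tissue = X beta + diagnosis shift + noise,
with the genetic component X beta *shared* across tissues of the same
individual and scaled so its sample variance is exactly ``h2_cis``.

GWAS: z-scores generated analytically at the summary level,
z = sqrt(N) * Lambda @ alpha + MVN(0, Lambda), where Lambda is the locus LD
matrix and alpha the SNP-level mediated effect beta * gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_qc import GenotypePanel, variant_stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_gwas_summary",
    "locus_annotation",
    "simulate_cohort",
]

# allele pairs cycled over variants; all strand-unambiguous
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))

_LOCUS_SPACING = 2_500_000  # bp between locus starts; keeps +-500 kb windows disjoint
_VARIANT_SPACING = 2_000  # bp between variants within a locus


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the training design the pipeline targets: 790 genotyped
    individuals supplying ~888 tissue samples over six neocortical regions
    (DLPFC/TCX dominating), moderate cis-heritability, and a large external
    GWAS.
    """

    n_individuals: int = 790
    n_variants_per_locus: int = 20
    n_loci: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.6
    h2_cis: float = 0.3
    n_causal_eqtl: int = 2
    tissues: tuple[str, ...] = ("DLPFC", "TCX", "FP", "IFG", "STG", "PHG")
    # per-tissue inclusion probabilities; defaults reproduce the 888-sample /
    # 790-individual repeated-measure design (481, 248, 50, 41, 34, 34)
    tissue_assignment_probs: tuple[float, ...] = (
        0.609, 0.314, 0.063, 0.052, 0.043, 0.043,
    )
    mediation_effect: float = 0.0
    n_mediated_genes: int = 10
    gwas_n: int = 63926
    diagnosis_effect: float = 0.25
    covariate_effects: dict = field(default_factory=dict)
    seed: int = 17

    def validate(self) -> None:
        if self.n_individuals < 2 or self.n_variants_per_locus < 1 or self.n_loci < 1:
            raise ConfigurationError("dimensions must be positive (>=2 individuals)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ConfigurationError("ld_decay must be in [0, 1)")
        if not 0.0 <= self.h2_cis <= 1.0:
            raise ConfigurationError("h2_cis must be in [0, 1]")
        if self.n_causal_eqtl > self.n_variants_per_locus:
            raise ConfigurationError("n_causal_eqtl exceeds n_variants_per_locus")
        if len(self.tissues) == 0:
            raise ConfigurationError("tissues must be non-empty")
        if len(self.tissue_assignment_probs) != len(self.tissues):
            raise ConfigurationError("one assignment probability per tissue required")
        if any(not 0.0 <= p <= 1.0 for p in self.tissue_assignment_probs):
            raise ConfigurationError("tissue probabilities must be in [0, 1]")
        if self.gwas_n < 2:
            raise ConfigurationError("gwas_n must be >= 2")


@dataclass
class GroundTruth:
    """What the generator knows: per-gene causal variants, effects, h2."""

    causal_variant_indices: dict  # gene -> global variant index list
    true_beta: dict  # gene -> effect vector on standardized-dosage scale
    true_h2: dict  # gene -> realized heritability
    mediated_genes: list
    noise_variances: dict  # tissue -> residual variance


def locus_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene/locus layout: one gene per locus, TSS at the locus
    midpoint, loci spaced so +-500 kb cis-windows never overlap."""
    rows = []
    span = (config.n_variants_per_locus - 1) * _VARIANT_SPACING
    for l in range(config.n_loci):
        chrom = str((l % 22) + 1)
        start = 1_000_000 + (l // 22) * _LOCUS_SPACING
        rows.append({
            "gene": f"gene{l:04d}",
            "chrom": chrom,
            "tss": start + span // 2,
            "locus": l,
            "start_index": l * config.n_variants_per_locus,
            "end_index": (l + 1) * config.n_variants_per_locus,
        })
    return pd.DataFrame(rows)


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Draw the genotype panel (doubles as the LD reference)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m_loc = config.n_individuals, config.n_variants_per_locus
    lo, hi = config.maf_range
    c = config.ld_decay
    blocks = []
    var_rows = []
    ann = locus_annotation(config)
    for l in range(config.n_loci):
        p = rng.uniform(lo, hi, size=m_loc)
        hap = np.empty((n, 2, m_loc), dtype=np.int8)
        hap[:, :, 0] = rng.random((n, 2)) < p[0]
        for j in range(1, m_loc):
            copy = rng.random((n, 2)) < c
            fresh = rng.random((n, 2)) < p[j]
            hap[:, :, j] = np.where(copy, hap[:, :, j - 1], fresh)
        blocks.append(hap.sum(axis=1).astype(float))
        chrom = ann.loc[l, "chrom"]
        start = int(ann.loc[l, "tss"]) - ((m_loc - 1) * _VARIANT_SPACING) // 2
        for j in range(m_loc):
            a_eff, a_oth = _ALLELE_PAIRS[(l * m_loc + j) % len(_ALLELE_PAIRS)]
            var_rows.append({
                "id": f"snp_l{l:04d}_{j:03d}",
                "chrom": chrom,
                "pos": start + j * _VARIANT_SPACING,
                "allele_effect": a_eff,
                "allele_other": a_oth,
            })
    dosages = np.concatenate(blocks, axis=1)
    variants = pd.DataFrame(var_rows)
    maf, miss = variant_stats(dosages)
    variants["maf"] = maf
    variants["missingness"] = miss
    ids = [f"ind{i:05d}" for i in range(n)]
    return GenotypePanel(list(ids), list(ids), variants, dosages)


def _standardize_cols(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return Xc / sd


def _assign_tissues(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """tissue -> individual indices; everyone gets one primary tissue, a
    subset gets extra tissues (repeated measures).

    Primary tissues follow the normalized assignment probabilities; extra
    memberships are Bernoulli with the excess mass (S - 1)/S per tissue, so
    expected per-tissue sample counts are n * p_t and the expected total is
    n * S (e.g. ~888 samples from 790 individuals at the defaults).
    """
    n = config.n_individuals
    probs = np.asarray(config.tissue_assignment_probs, dtype=float)
    S = probs.sum()
    if S <= 0:
        raise ConfigurationError("tissue probabilities sum to zero")
    primary = rng.choice(len(probs), size=n, p=probs / S)
    member = np.zeros((n, len(probs)), dtype=bool)
    member[np.arange(n), primary] = True
    if S > 1.0:
        # scale extra-membership odds so E[new memberships] = S - 1 per
        # individual after discounting overlap with the primary tissue
        denom = S - float((probs ** 2).sum()) / S
        c = (S - 1.0) / denom if denom > 0 else 0.0
        extra = rng.random((n, len(probs))) < np.clip(c * probs, 0.0, 1.0)
        member |= extra
    return {t: np.flatnonzero(member[:, k]) for k, t in enumerate(config.tissues)}


def simulate_expression(panel: GenotypePanel, config: SimulationConfig):
    """Per-tissue expression with a shared per-individual genetic component.

    Returns ``(expression_sets, truth)`` where ``expression_sets`` is a list of
    :class:`~cortwas.expression.ExpressionSet`, one per tissue with at least
    one sample.
    """
    from .expression import ExpressionSet  # local import to avoid a cycle

    config.validate()
    if panel.n_samples < 2:
        raise ConfigurationError("panel must hold >= 2 individuals")
    rng = np.random.default_rng(config.seed + 1)
    n = panel.n_samples
    ann = locus_annotation(config)
    h2 = config.h2_cis

    genetic = np.zeros((config.n_loci, n))
    causal_idx: dict = {}
    true_beta: dict = {}
    true_h2: dict = {}
    for l in range(config.n_loci):
        gene = ann.loc[l, "gene"]
        s0, s1 = int(ann.loc[l, "start_index"]), int(ann.loc[l, "end_index"])
        if h2 == 0.0:
            causal_idx[gene] = []
            true_beta[gene] = np.zeros(0)
            true_h2[gene] = 0.0
            continue
        chosen = np.sort(rng.choice(np.arange(s0, s1), size=config.n_causal_eqtl,
                                    replace=False))
        Z = _standardize_cols(panel.dosages[:, chosen])
        beta = rng.standard_normal(config.n_causal_eqtl)
        g = Z @ beta
        sd = g.std(ddof=1)
        if sd == 0:
            beta = np.zeros_like(beta)
            g = np.zeros(n)
        else:
            scale = np.sqrt(h2) / sd
            beta = beta * scale
            g = g * scale
        genetic[l] = g
        causal_idx[gene] = chosen.tolist()
        true_beta[gene] = beta
        v = g.var(ddof=1)
        true_h2[gene] = float(v / (v + (1.0 - h2))) if h2 < 1.0 else 1.0

    diagnosis = (rng.random(n) < 0.45).astype(float)
    age = rng.normal(80.0, 8.0, size=n)
    sex = (rng.random(n) < 0.55).astype(float)
    pmi = np.clip(rng.normal(8.0, 3.0, size=n), 0.5, None)
    batch = rng.integers(0, 3, size=n).astype(float)
    cov_all = pd.DataFrame({
        "diagnosis": diagnosis, "age_at_death": age, "sex": sex,
        "pmi": pmi, "batch": batch,
    })

    assignment = _assign_tissues(config, rng)
    noise_var = 1.0 - h2
    sets: list[ExpressionSet] = []
    noise_variances: dict = {}
    genes = ann["gene"].tolist()
    for t in config.tissues:
        ind = assignment[t]
        if ind.size == 0:
            logger.warning("tissue %s received no samples; skipped", t)
            continue
        sample_ids = [f"{panel.sample_ids[i]}_{t}" for i in ind]
        values = genetic[:, ind] + config.diagnosis_effect * diagnosis[ind]
        for cov_name, eff in config.covariate_effects.items():
            x = cov_all[cov_name].to_numpy()[ind]
            xs = (x - x.mean()) / (x.std(ddof=1) if x.std(ddof=1) > 0 else 1.0)
            values = values + eff * xs
        if noise_var > 0:
            values = values + rng.normal(0.0, np.sqrt(noise_var), size=values.shape)
        cov = cov_all.iloc[ind].copy()
        cov.index = sample_ids
        sets.append(ExpressionSet(
            tissue=t,
            genes=list(genes),
            samples=sample_ids,
            values=values,
            covariates=cov,
            sample_to_individual={s: panel.sample_ids[i] for s, i in zip(sample_ids, ind)},
        ))
        noise_variances[t] = noise_var

    mediated: list = []
    if config.mediation_effect != 0.0 and h2 > 0.0:
        k = min(config.n_mediated_genes, config.n_loci)
        mediated = sorted(rng.choice(genes, size=k, replace=False).tolist())
    truth = GroundTruth(causal_idx, true_beta, true_h2, mediated, noise_variances)
    return sets, truth


def simulate_gwas_summary(
    panel: GenotypePanel, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Analytic GWAS summary statistics at the z-score level.

    For each locus, z = sqrt(N) * Lambda @ alpha + MVN(0, Lambda) with Lambda
    the realized LD correlation matrix and alpha the SNP-level joint effect
    gamma * beta on the standardized-genotype / standardized-trait scale.
    ``beta``/``se`` are reported on that same scale (se = 1/sqrt(N)).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    ann = locus_annotation(config)
    N = config.gwas_n
    gamma = config.mediation_effect
    mediated = set(truth.mediated_genes)
    # total trait variance: sum of mediated genetic variances + residual 1
    var_trait = 1.0 + sum(
        gamma ** 2 * truth.true_h2[g] for g in mediated
    )
    z_all = np.empty(panel.n_variants)
    for l in range(config.n_loci):
        gene = ann.loc[l, "gene"]
        s0, s1 = int(ann.loc[l, "start_index"]), int(ann.loc[l, "end_index"])
        Z = _standardize_cols(panel.dosages[:, s0:s1])
        lam = (Z.T @ Z) / (panel.n_samples - 1)
        alpha = np.zeros(s1 - s0)
        if gene in mediated and gamma != 0.0:
            local = np.array(truth.causal_variant_indices[gene]) - s0
            alpha[local] = gamma * truth.true_beta[gene] / np.sqrt(var_trait)
        try:
            L = np.linalg.cholesky(lam + 1e-9 * np.eye(len(lam)))
        except np.linalg.LinAlgError:
            logger.warning("locus %d LD matrix singular; ridge-regularized draw", l)
            L = np.linalg.cholesky(lam + 1e-3 * np.eye(len(lam)))
        z_all[s0:s1] = np.sqrt(N) * (lam @ alpha) + L @ rng.standard_normal(len(lam))
    se = 1.0 / np.sqrt(N)
    out = panel.variants[["id", "chrom", "pos", "allele_effect", "allele_other"]].copy()
    out["beta"] = z_all * se
    out["se"] = se
    out["z"] = z_all
    out["n"] = N
    return out


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: (panel, expression_sets, truth, gwas, annotation)."""
    panel = simulate_genotypes(config)
    sets, truth = simulate_expression(panel, config)
    gwas = simulate_gwas_summary(panel, truth, config)
    ann = locus_annotation(config)[["gene", "chrom", "tss"]]
    return panel, sets, truth, gwas, ann


def write_cohort(config: SimulationConfig, out_dir: str) -> dict:
    """Write the simulated cohort to disk in the pipeline's input formats.

    Emits PLINK bed/bim/fam, per-tissue expression/covariate/sample-map TSVs,
    a GWAS summary TSV, and a gene annotation TSV; returns a dict of paths
    suitable for building a :class:`~cortwas.pipeline.PipelineConfig`.
    """
    import dataclasses
    import os

    import yaml

    from .genotype_qc import write_plink

    os.makedirs(out_dir, exist_ok=True)
    raw = dataclasses.asdict(config)
    raw["maf_range"] = list(config.maf_range)
    raw["tissues"] = list(config.tissues)
    raw["tissue_assignment_probs"] = list(config.tissue_assignment_probs)
    with open(os.path.join(out_dir, "simulation.yaml"), "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    panel, sets, truth, gwas, ann = simulate_cohort(config)
    prefix = os.path.join(out_dir, "genotypes")
    write_plink(panel, prefix)
    tissues = {}
    for es in sets:
        paths = {
            "expression": os.path.join(out_dir, f"{es.tissue}.expr.tsv"),
            "covariates": os.path.join(out_dir, f"{es.tissue}.cov.tsv"),
            "sample_map": os.path.join(out_dir, f"{es.tissue}.map.tsv"),
        }
        es.to_tsv(paths["expression"], paths["covariates"], paths["sample_map"])
        tissues[es.tissue] = paths
    gwas_path = os.path.join(out_dir, "gwas.tsv")
    gwas.to_csv(gwas_path, sep="\t", index=False)
    ann_path = os.path.join(out_dir, "annotation.tsv")
    ann.to_csv(ann_path, sep="\t", index=False)
    return {"genotypes": prefix, "tissues": tissues, "gwas": gwas_path,
            "annotation": ann_path, "truth": truth}
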