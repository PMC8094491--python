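"""Allele harmonization, the TWAS z statistic, FDR, validation, and binning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortwas.association import (
    GwasSummary,
    bh_fdr,
    gwas_bin_enrichment,
    harmonize_alleles,
    impute_expression,
    ld_matrix,
    twas_z,
    validate_imputation,
)
from cortwas.expression import ExpressionSet
from cortwas.genotype_qc import GenotypePanel, standardize_dosages, variant_stats
from cortwas.synthetic import SimulationConfig, simulate_cohort
from cortwas.weights import WeightModel


def _panel(rng, m=4, n=50, alleles=None):
    dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    maf, miss = variant_stats(dos)
    if alleles is None:
        alleles = [("A", "G")] * m
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)], "chrom": "1",
        "pos": np.arange(m) * 1000 + 1,
        "allele_effect": [a for a, _ in alleles],
        "allele_other": [b for _, b in alleles],
        "maf": maf, "missingness": miss,
    })
    ids = [f"s{i}" for i in range(n)]
    return GenotypePanel(ids, list(ids), variants, dos)


def _gwas_for(panel, z, swap=None, alleles_override=None):
    v = panel.variants
    a_eff = v["allele_effect"].tolist()
    a_oth = v["allele_other"].tolist()
    if swap:
        for j in swap:
            a_eff[j], a_oth[j] = a_oth[j], a_eff[j]
            z = np.array(z, dtype=float)
            z[j] = -z[j]
    if alleles_override:
        for j, pair in alleles_override.items():
            a_eff[j], a_oth[j] = pair
    z = np.asarray(z, dtype=float)
    se = 0.01
    return GwasSummary(pd.DataFrame({
        "id": v["id"], "chrom": v["chrom"], "pos": v["pos"],
        "allele_effect": a_eff, "allele_other": a_oth,
        "beta": z * se, "se": se, "z": z, "n": 10000,
    }))


def _wm(panel, weights):
    return WeightModel("g", "top1", np.asarray(weights, float), 0.2, 1e-4, 0.3,
                       panel.variants["id"].tolist())


def test_harmonize_flip_is_involutive(rng):
    panel = _panel(rng)
    z = [1.0, -2.0, 0.5, 3.0]
    base = harmonize_alleles(_wm(panel, [0.1, 0.2, 0.3, 0.4]), _gwas_for(panel, z), panel)
    # swapping alleles at SNP 1 *and* negating its z is a no-op after harmonization
    swapped = harmonize_alleles(_wm(panel, [0.1, 0.2, 0.3, 0.4]),
                                _gwas_for(panel, z, swap=[1]), panel)
    np.testing.assert_allclose(base.z, swapped.z)
    np.testing.assert_allclose(base.weights, swapped.weights)


def test_ambiguous_snp_dropped(rng):
    panel = _panel(rng, alleles=[("A", "G"), ("A", "T"), ("C", "G"), ("C", "T")])
    out = harmonize_alleles(_wm(panel, [1, 1, 1, 1]), _gwas_for(panel, [1, 1, 1, 1]),
                            panel)
    assert out.variant_ids == ["v0", "v3"]


def test_harmonize_invariant_to_gwas_row_order(rng):
    panel = _panel(rng)
    gwas = _gwas_for(panel, [1.0, 2.0, 3.0, 4.0])
    perm = gwas.table.sample(frac=1, random_state=1).reset_index(drop=True)
    a = harmonize_alleles(_wm(panel, [0.1, 0.2, 0.3, 0.4]), gwas, panel)
    b = harmonize_alleles(_wm(panel, [0.1, 0.2, 0.3, 0.4]), GwasSummary(perm), panel)
    assert a.variant_ids == b.variant_ids
    np.testing.assert_allclose(a.z, b.z)


def test_no_overlap_returns_none(rng):
    panel = _panel(rng)
    gwas = _gwas_for(panel, [1, 1, 1, 1])
    gwas.table["id"] = ["x0", "x1", "x2", "x3"]
    wm = _wm(panel, [1, 0, 0, 0])
    assert harmonize_alleles(wm, gwas, panel) is None


def test_impute_top1_component_tracks_single_snp(rng):
    panel = _panel(rng, m=3, n=200)
    w = np.array([0.0, 0.8, 0.0])
    comp = impute_expression(_wm(panel, w), panel)
    r = np.corrcoef(comp, panel.dosages[:, 1])[0, 1]
    assert abs(abs(r) - 1.0) < 1e-12


def test_twas_z_single_snp_equals_snp_z(rng):
    z = np.array([2.5])
    res = twas_z(np.array([1.0]), z, np.array([[1.0]]))
    assert res.z_twas == pytest.approx(2.5)
    assert res.p == pytest.approx(2 * stats.norm.sf(2.5), abs=1e-12)


def test_twas_z_hand_computed_example():
    # w=(1,1), z=(2,2), V=[[1,.5],[.5,1]]: z = 4 / sqrt(3) ~ 2.3094
    w = np.array([1.0, 1.0])
    z = np.array([2.0, 2.0])
    V = np.array([[1.0, 0.5], [0.5, 1.0]])
    res = twas_z(w, z, V)
    assert res.z_twas == pytest.approx(4 / np.sqrt(3), abs=1e-12)


def test_twas_z_scale_invariance(rng):
    w = rng.standard_normal(5)
    z = rng.standard_normal(5)
    V = np.eye(5)
    a = twas_z(w, z, V).z_twas
    b = twas_z(10 * w, z, V).z_twas
    assert a == pytest.approx(b, abs=1e-12)


def test_twas_z_degenerate_predictor_skipped():
    assert twas_z(np.zeros(3), np.ones(3), np.eye(3)) is None


def test_bh_fdr_examples():
    np.testing.assert_allclose(bh_fdr([0.03]), [0.03])
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])


def test_bh_fdr_matches_brute_force_step_up(rng):
    p = rng.uniform(size=25)
    q = bh_fdr(p)
    m = len(p)
    order = np.argsort(p)
    brute = np.empty(m)
    for rank, i in enumerate(order, start=1):
        candidates = [p[j] * m / (list(order).index(j) + 1)
                      for j in order[rank - 1:]]
        brute[i] = min(1.0, min(candidates))
    np.testing.assert_allclose(q, brute, atol=1e-12)


def test_bh_fdr_custom_comparison_count():
    # correcting for more comparisons than supplied p-values scales q up
    q = bh_fdr([0.01, 0.02], m=4)
    np.testing.assert_allclose(q, [0.04, 0.04])
    with pytest.raises(ValueError):
        bh_fdr([0.1, 0.2], m=1)


def _observed_es(values, samples):
    return ExpressionSet(
        tissue="T", genes=[f"g{i}" for i in range(values.shape[0])],
        samples=samples, values=values,
        covariates=pd.DataFrame(index=samples),
        sample_to_individual={s: s for s in samples},
    )


def test_kendall_validation_examples():
    samples = [f"s{i}" for i in range(3)]
    obs = _observed_es(np.array([[1.0, 3.0, 2.0]]), samples)
    imp = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"], columns=samples)
    with pytest.raises(ValueError):
        validate_imputation(imp, obs)  # fewer than 10 shared samples
    samples = [f"s{i}" for i in range(12)]
    base = np.arange(12, dtype=float)
    obs = _observed_es(np.vstack([base, base[::-1]]), samples)
    imp = pd.DataFrame(np.vstack([base, base]), index=["g0", "g1"], columns=samples)
    out = validate_imputation(imp, obs).set_index("gene")
    assert out.loc["g0", "tau"] == pytest.approx(1.0)
    assert out.loc["g1", "tau"] == pytest.approx(-1.0)
    assert (out["q"] >= out["p"] - 1e-15).all()


def test_kendall_tau_matches_all_pairs_brute_force(rng):
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    samples = [f"s{i}" for i in range(12)]
    obs = _observed_es(y[None, :], samples)
    imp = pd.DataFrame(x[None, :], index=["g0"], columns=samples)
    tau = validate_imputation(imp, obs)["tau"].iloc[0]
    conc = disc = 0
    for i in range(12):
        for j in range(i + 1, 12):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            conc += s > 0
            disc += s < 0
    assert tau == pytest.approx((conc - disc) / (12 * 11 / 2), abs=1e-12)


# ---------------------------------------------------------------------------
# GWAS binning
# ---------------------------------------------------------------------------

def _bin_fixture(rng, z_weighted=None):
    n_snps = 900
    pos = np.arange(n_snps) * 10_000 + 1
    z = rng.standard_normal(n_snps)
    weighted = pd.DataFrame({"gene": ["gw"], "chrom": ["1"], "tss": [1_000_000]})
    unweighted = pd.DataFrame({"gene": ["gu"], "chrom": ["1"], "tss": [4_000_000]})
    if z_weighted is not None:
        in_w = np.abs(pos - 1_000_000) <= 500_000
        z[in_w] = z_weighted(rng, int(in_w.sum()))
    gwas = GwasSummary(pd.DataFrame({
        "id": [f"v{j}" for j in range(n_snps)], "chrom": "1", "pos": pos,
        "allele_effect": "A", "allele_other": "G",
        "beta": z * 0.01, "se": 0.01, "z": z, "n": 10000,
    }))
    return gwas, weighted, unweighted


def test_bin_precedence_weighted_wins(rng):
    gwas, weighted, _ = _bin_fixture(rng)
    # unweighted window overlapping the weighted one: shared SNPs stay weighted
    unweighted = pd.DataFrame({"gene": ["gu"], "chrom": ["1"], "tss": [1_200_000]})
    out = gwas_bin_enrichment(gwas, weighted, unweighted)
    assert out.n_weighted == np.sum(np.abs(gwas.table["pos"] - 1_000_000) <= 500_000)
    total = len(gwas.table)
    assert out.n_weighted + out.n_unweighted + out.n_intergenic == total


def test_bin_null_gives_flat_tests(rng):
    ps = []
    for s in range(20):
        r = np.random.default_rng(s)
        gwas, weighted, unweighted = _bin_fixture(r)
        out = gwas_bin_enrichment(gwas, weighted, unweighted)
        ps.append(out.p_weighted_vs_intergenic)
    ps = np.asarray(ps)
    assert 0.2 < ps.mean() < 0.8  # one-sided null: p ~ Uniform(0,1)


def test_bin_detects_enriched_weighted_windows():
    hits_u = hits_i = 0
    n_sims = 100
    for s in range(n_sims):
        r = np.random.default_rng(1000 + s)
        gwas, weighted, unweighted = _bin_fixture(
            r, z_weighted=lambda rr, k: rr.standard_normal(k) + 1.5)
        out = gwas_bin_enrichment(gwas, weighted, unweighted)
        hits_u += out.p_weighted_vs_unweighted < 0.05
        hits_i += out.p_weighted_vs_intergenic < 0.05
    assert hits_u >= 90 and hits_i >= 90


# ---------------------------------------------------------------------------
# summary-statistic shortcut vs individual-level regression
# ---------------------------------------------------------------------------

def test_twas_z_matches_individual_level_regression():
    """The quadratic-form z equals the z from regressing the simulated trait
    on the imputed component in an individual-level cohort (within MC error)."""
    rng = np.random.default_rng(12)
    n, m = 5000, 8
    dos = rng.binomial(2, rng.uniform(0.2, 0.4, m), size=(n, m)).astype(float)
    Z = standardize_dosages(dos)
    alpha = np.zeros(m)
    alpha[3] = 0.06
    trait = Z @ alpha + rng.standard_normal(n)
    # per-SNP marginal GWAS on the individual data
    zs = np.empty(m)
    for j in range(m):
        r = np.corrcoef(Z[:, j], trait)[0, 1]
        zs[j] = r * np.sqrt((n - 2) / (1 - r ** 2))
    w = np.zeros(m)
    w[3] = 1.0
    V = (Z.T @ Z) / (n - 1)
    z_summary = twas_z(w, zs, (0.95 * V + 0.05 * np.eye(m)))
    comp = Z @ w
    rc = np.corrcoef(comp, trait)[0, 1]
    z_direct = rc * np.sqrt((n - 2) / (1 - rc ** 2))
    assert abs(z_summary.z_twas - z_direct) < 0.15


def test_imputation_validates_in_held_out_cohort():
    """Synthetic validation-cohort design: imputed components correlate with
    observed expression for heritable genes at FDR < 0.05."""
    cfg = SimulationConfig(n_individuals=600, n_loci=40, n_variants_per_locus=8,
                           h2_cis=0.5, diagnosis_effect=0.0,
                           tissues=("T",), tissue_assignment_probs=(1.0,), seed=77)
    panel, sets, truth, _, _ = simulate_cohort(cfg)
    es = sets[0]
    rows = []
    for gi, gene in enumerate(es.genes):
        idx = truth.causal_variant_indices[gene]
        w = truth.true_beta[gene]
        wm = WeightModel(gene, "truth", np.asarray(w), 0.5, 1e-6, 0.5,
                         panel.variants["id"].iloc[idx].tolist())
        rows.append(impute_expression(wm, panel))
    samples = es.samples
    ind_col = {es.sample_to_individual[s]: j for j, s in enumerate(samples)}
    order = [panel.sample_ids.index(i) for i in ind_col]
    imp = pd.DataFrame(np.vstack(rows)[:, order], index=es.genes,
                       columns=list(ind_col.keys()))
    imp.columns = [samples[ind_col[i]] for i in ind_col]
    out = validate_imputation(imp, es)
    frac = np.mean((out["q"] < 0.05) & (out["tau"] > 0))
    assert frac >= 0.95
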