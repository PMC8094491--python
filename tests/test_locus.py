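"""Predicted-expression correlation, JCP forward selection, SMR, COLOC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortwas.genotype_qc import standardize_dosages
from cortwas.locus import (
    LocusReport,
    coloc_abf,
    conditional_snp_z,
    define_loci,
    jcp,
    predicted_expression_correlation,
    smr,
)


# ---------------------------------------------------------------------------
# omega
# ---------------------------------------------------------------------------

def test_identical_weights_give_unit_correlation(rng):
    V = np.eye(4)
    w = rng.standard_normal(4)
    omega = predicted_expression_correlation(np.vstack([w, w]), V)
    np.testing.assert_allclose(omega, np.ones((2, 2)), atol=1e-12)


def test_disjoint_weights_block_diagonal_V_give_zero(rng):
    V = np.eye(6)
    w1 = np.array([1.0, 0.5, 0, 0, 0, 0])
    w2 = np.array([0, 0, 0, 0.3, -0.2, 0.8])
    omega = predicted_expression_correlation(np.vstack([w1, w2]), V)
    assert omega[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_omega_matches_imputed_component_correlation(rng):
    # imputation oracle: omega from the quadratic form vs the empirical
    # correlation of explicitly imputed components on a simulated panel
    n, m = 4000, 10
    dos = rng.binomial(2, rng.uniform(0.2, 0.4, m), size=(n, m)).astype(float)
    Z = standardize_dosages(dos)
    V = (Z.T @ Z) / (n - 1)
    w1 = np.zeros(m); w1[[1, 2]] = [0.8, 0.3]
    w2 = np.zeros(m); w2[[2, 5]] = [0.5, -0.4]
    omega = predicted_expression_correlation(np.vstack([w1, w2]), V)
    c1, c2 = Z @ w1, Z @ w2
    emp = np.corrcoef(c1, c2)[0, 1]
    assert abs(omega[0, 1] - emp) < 0.02


# ---------------------------------------------------------------------------
# JCP
# ---------------------------------------------------------------------------

def _report(genes, z, omega):
    return LocusReport(locus=0, genes=list(genes), omega=np.asarray(omega, float),
                       z_marginal=np.asarray(z, float))


def test_single_gene_locus_is_joint():
    rep = jcp(_report(["a"], [5.0], [[1.0]]))
    assert rep.classification["a"] == "joint"
    assert rep.z_joint["a"] == pytest.approx(5.0)


def test_uncorrelated_genes_both_joint():
    rep = jcp(_report(["a", "b"], [5.0, 4.5], np.eye(2)))
    assert rep.classification == {"a": "joint", "b": "joint"}
    assert rep.z_joint["a"] == pytest.approx(5.0, abs=1e-9)
    assert rep.z_joint["b"] == pytest.approx(4.5, abs=1e-9)


def test_correlation_driven_gene_classified_marginal():
    """Gene B carries no signal of its own: its weights are a noisy copy of
    A's, so its marginal z comes entirely through Omega."""
    hits = 0
    n_sims = 100
    for s in range(n_sims):
        r = np.random.default_rng(s)
        m = 12
        wa = r.standard_normal(m)
        wb = wa + 1.0 * r.standard_normal(m)
        V = np.eye(m)
        omega = predicted_expression_correlation(np.vstack([wa, wb]), V)
        rho = omega[0, 1]
        za = 7.0 + r.standard_normal()
        zb = rho * za + np.sqrt(1 - rho ** 2) * r.standard_normal()
        rep = jcp(_report(["A", "B"], [za, zb], omega))
        if rep.classification["A"] == "joint" and rep.classification["B"] in (
                "marginal", "dropped"):
            hits += 1
    assert hits >= 90


def test_jcp_invariant_to_gene_input_order(rng):
    omega = np.array([[1.0, 0.6], [0.6, 1.0]])
    z = [6.0, 4.0]
    a = jcp(_report(["g1", "g2"], z, omega))
    b = jcp(_report(["g2", "g1"], z[::-1], omega[::-1, ::-1]))
    assert a.classification == b.classification


def test_collinear_gene_flagged_marginal():
    omega = np.array([[1.0, 1.0], [1.0, 1.0]])
    rep = jcp(_report(["a", "b"], [6.0, 6.0], omega))
    classes = sorted(rep.classification.values())
    assert "joint" in classes
    other = [g for g, c in rep.classification.items() if c != "joint"][0]
    assert rep.jcp_p[other] == 1.0 or np.isnan(rep.z_conditional[other])


def test_conditioning_shrinks_shared_signal_two_gene_case():
    omega = np.array([[1.0, 0.8], [0.8, 1.0]])
    z = np.array([6.0, 5.0])
    rep = jcp(_report(["a", "b"], z, omega))
    zc = rep.z_conditional.get("b", rep.z_joint.get("b"))
    assert abs(zc) <= abs(z[1]) + 1e-9


# ---------------------------------------------------------------------------
# conditional SNP z
# ---------------------------------------------------------------------------

def test_snp_uncorrelated_with_predictors_unchanged():
    V = np.eye(3)
    w = np.array([[0.0], [1.0], [0.0]])  # gene loads only on SNP 1
    z_snp = np.array([2.0, 4.0, -1.0])
    z_sel = np.array([4.0])
    out = conditional_snp_z(z_snp, V, w, z_sel)
    assert out[0] == pytest.approx(2.0)
    assert out[2] == pytest.approx(-1.0)


def test_top1_snp_self_conditioning_zeroes_out():
    V = np.eye(3)
    w = np.array([[0.0], [1.0], [0.0]])
    z_snp = np.array([2.0, 4.0, -1.0])
    out = conditional_snp_z(z_snp, V, w, np.array([4.0]))
    assert out[1] == pytest.approx(0.0, abs=1e-9)


def test_mediated_locus_signal_removed_by_conditioning():
    hits = 0
    n_sims = 50
    for s in range(n_sims):
        r = np.random.default_rng(s)
        m = 15
        A = r.standard_normal((m, m)) / np.sqrt(m)
        V = 0.5 * (A @ A.T) + 0.5 * np.eye(m)
        d = np.sqrt(np.diag(V)); V = V / np.outer(d, d)
        w = np.zeros(m); w[4] = 1.0
        gene_z = 8.0
        L = np.linalg.cholesky(V + 1e-10 * np.eye(m))
        # all GWAS signal mediated through the gene's component
        rho = (V @ w) / np.sqrt(w @ V @ w)
        z_snp = rho * gene_z + L @ r.standard_normal(m) * 0.3
        out = conditional_snp_z(z_snp, V, w[:, None], np.array([gene_z]))
        if np.max(np.abs(out)) < 1.96:
            hits += 1
    assert hits / n_sims >= 0.8


# ---------------------------------------------------------------------------
# SMR
# ---------------------------------------------------------------------------

def test_smr_symmetric_example():
    T, p = smr(2.0, 2.0)
    assert T == pytest.approx(2.0)
    assert p == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-12)


def test_smr_limit_large_eqtl():
    T, _ = smr(1e8, 3.0)
    assert T == pytest.approx(9.0, rel=1e-6)


def test_smr_worked_example_chi2_oracle():
    T, p = smr(5.0, 3.0)
    assert T == pytest.approx(225 / 34, abs=1e-9)
    assert p == pytest.approx(0.0101, abs=2e-4)


def test_smr_null_matches_monte_carlo():
    """chi2_1 calibration of the SMR p-value under the composite null the
    method actually tests: a strong eQTL instrument (large z_e) with no
    trait mediation (z_g ~ N(0,1)), 10^6 draws, 2 MC standard errors."""
    r = np.random.default_rng(9)
    n = 10**6
    ze = r.normal(100.0, 1.0, n)  # strong instrument; T -> z_g^2 regime
    zg = r.standard_normal(n)
    T = ze**2 * zg**2 / (ze**2 + zg**2)
    for thr in (3.84, 6.63):
        emp = float((T > thr).mean())
        theo = float(stats.chi2.sf(thr, 1))
        mc_se = np.sqrt(theo * (1 - theo) / n)
        assert abs(emp - theo) < 2 * mc_se


# ---------------------------------------------------------------------------
# COLOC
# ---------------------------------------------------------------------------

def test_coloc_null_favors_h0(rng):
    k = 40
    se = np.full(k, 0.05)
    pp = coloc_abf(rng.normal(0, 0.001, k), se, rng.normal(0, 0.001, k), se)
    assert pp[0] > 0.9


def test_coloc_posteriors_normalize(rng):
    for _ in range(20):
        k = 30
        se1 = np.abs(rng.normal(0.05, 0.01, k)) + 0.01
        se2 = np.abs(rng.normal(0.1, 0.02, k)) + 0.01
        pp = coloc_abf(rng.normal(0, 0.2, k), se1, rng.normal(0, 0.3, k), se2)
        assert pp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(pp >= 0)


def _ld_panel(r, n=2000, m=50, decay=0.9):
    from cortwas.synthetic import SimulationConfig, simulate_genotypes
    cfg = SimulationConfig(n_individuals=n, n_loci=1, n_variants_per_locus=m,
                           ld_decay=decay, seed=int(r.integers(2**31)))
    return standardize_dosages(simulate_genotypes(cfg).dosages)


def test_coloc_recovers_shared_and_distinct_causal_variants():
    h4_hits = h3_hits = 0
    n_sims = 100
    for s in range(n_sims):
        r = np.random.default_rng(s)
        m = 50
        Z = _ld_panel(r, n=1000, m=m)
        n = Z.shape[0]
        V = (Z.T @ Z) / (n - 1)
        L = np.linalg.cholesky(V + 1e-8 * np.eye(m))
        se = np.full(m, 1 / np.sqrt(50000))

        def draw(causal_idx, effect):
            alpha = np.zeros(m); alpha[causal_idx] = effect
            z = (V @ alpha) / se + L @ r.standard_normal(m)
            return z * se, se

        # shared causal SNP -> H4
        c = int(r.integers(5, m - 5))
        b1, s1 = draw(c, 0.05)
        b2, s2 = draw(c, 0.08)
        pp = coloc_abf(b1, s1, b2, s2)
        h4_hits += np.argmax(pp) == 4

        # distinct causal SNPs in low LD -> H3
        corr = np.abs(V[c])
        far = [j for j in range(m) if corr[j] < 0.2]
        if far:
            c2 = far[int(r.integers(len(far)))]
            b3, s3 = draw(c2, 0.08)
            pp2 = coloc_abf(b1, s1, b3, s3)
            h3_hits += np.argmax(pp2) == 3
    assert h4_hits >= 90
    assert h3_hits >= 90


def test_coloc_degenerate_with_single_snp():
    pp = coloc_abf([0.1], [0.05], [0.2], [0.05])
    assert pp[0] == 1.0


# ---------------------------------------------------------------------------
# locus definition
# ---------------------------------------------------------------------------

def test_define_loci_connected_components():
    windows = pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "chrom": ["1", "1", "1", "2"],
        "tss": [1_000_000, 1_600_000, 5_000_000, 1_000_000],
    })
    loci = define_loci(windows, flank=500_000)
    assert loci["a"] == loci["b"]  # windows overlap
    assert loci["c"] != loci["a"]
    assert loci["d"] != loci["c"]
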