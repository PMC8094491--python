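import numpy as np
import pytest

from cortwas.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Modest multi-tissue cohort with mediated loci, shared across tests."""
    cfg = SimulationConfig(
        n_individuals=300, n_loci=20, n_variants_per_locus=12,
        h2_cis=0.4, mediation_effect=0.25, n_mediated_genes=4, seed=7,
    )
    panel, sets, truth, gwas, ann = simulate_cohort(cfg)
    return {"config": cfg, "panel": panel, "sets": sets, "truth": truth,
            "gwas": gwas, "annotation": ann}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
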