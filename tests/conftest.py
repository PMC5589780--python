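import numpy as np
import pytest

from txgc.grm import compute_grm
from txgc.greml import GRMEigen
from txgc.simulate import SimConfig, StudyConfig, simulate_genotypes, simulate_study


@pytest.fixture(scope="session")
def small_cohort():
    """Genotypes + GRM + eigendecomposition for a modest unrelated cohort."""
    cfg = SimConfig(
        n_individuals=300, n_snps=800, n_causal=80,
        h2_i=0.5, h2_j=0.5, r_G=0.5, r_E=0.2, seed=42,
    )
    genotypes = simulate_genotypes(cfg)
    grm = compute_grm(genotypes)
    return cfg, genotypes, grm, GRMEigen.from_grm(grm)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A cohort small enough for dense-matrix and grid-search oracles."""
    cfg = SimConfig(
        n_individuals=40, n_snps=120, n_causal=30,
        h2_i=0.5, h2_j=0.5, r_G=0.6, r_E=0.2, seed=3,
    )
    genotypes = simulate_genotypes(cfg)
    grm = compute_grm(genotypes)
    return cfg, genotypes, grm, GRMEigen.from_grm(grm)


@pytest.fixture(scope="session")
def study_bundle():
    """Full synthetic study with planted shared eSNPs and contacts."""
    cfg = StudyConfig(
        sim=SimConfig(
            n_individuals=700, n_snps=5000, n_causal=60,
            h2_i=0.5, h2_j=0.5, r_G=0.0, r_E=0.2, seed=7,
        ),
        n_pairs=8,
        n_shared_esnp_pairs=4,
        n_planted_contact_pairs=4,
        n_background_contacts=30,
    )
    return cfg, simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
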