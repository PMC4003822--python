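import warnings

import numpy as np
import pytest

import bcrgt
from bcrgt import (
    EngineConfig,
    SimConfig,
    build_generic_prior,
    center_snp,
    segments_covering,
    simulate_dataset,
)

# prior-variance calibration warns when < 100 monomorphic SNPs exist in the
# small cohorts used for testing; that is expected at these sizes
warnings.filterwarnings(
    "ignore", message="only .* monomorphic SNPs available", category=UserWarning
)


@pytest.fixture(scope="session")
def clean_sim():
    """Centered CNA-free cohort of 400 SNPs x 100 samples with truth."""
    dataset, cna, truth = simulate_dataset(SimConfig(n_snps=400, n_samples=100, seed=101))
    return center_snp(dataset), cna, truth


@pytest.fixture(scope="session")
def generic_prior(clean_sim):
    dataset, _, _ = clean_sim
    return build_generic_prior(dataset, seed=202)


@pytest.fixture(scope="session")
def loss_sim():
    """Cohort with a recurrent copy loss over 20% of SNPs in half the samples."""
    config = SimConfig(
        n_snps=400,
        n_samples=80,
        seed=303,
        cna_segments=segments_covering(400, 80, 0.2, status=-1),
    )
    dataset, cna, truth = simulate_dataset(config)
    dataset = center_snp(dataset)
    prior = build_generic_prior(dataset, seed=404)
    constant = bcrgt.estimate_cn_constant(dataset)
    cna_filled = bcrgt.assign_cn_covariate(dataset, cna, constant)
    return dataset, cna_filled, truth, prior


@pytest.fixture
def forced_call_config():
    """Engine configuration with a 100% call rate (threshold 0)."""
    return EngineConfig(threshold=0.0)
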