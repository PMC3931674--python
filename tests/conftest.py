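import numpy as np
import pytest

import crcprog as cp


@pytest.fixture(scope="session")
def small_config():
    """A small but fully structured study used across module tests."""
    # deliberately strong signal: these fixtures exercise plumbing and
    # qualitative behaviour, not statistical power at scale
    return cp.SimulationConfig(
        n_genes=120,
        samples_per_stage={"II": 10, "III": 10, "IV": 10},
        n_up_amplified=12,
        n_down_deleted=12,
        n_de_only=12,
        n_cna_only=12,
        de_effect=2.0,
        cna_penetrance=1.0,
        noise_sd=0.4,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    expression, cna, truth = cp.generate_study(small_config)
    return expression, cna, truth


@pytest.fixture(scope="session")
def small_artifacts(small_study):
    """DE sets, alterations and signatures of the small study (cheap n_perm)."""
    expression, cna, _ = small_study
    de_sets, alterations, signatures = cp.build_signatures(
        expression, cna, n_perm=30, seed=7
    )
    return de_sets, alterations, signatures


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
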