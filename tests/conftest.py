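import numpy as np
import pytest

import cismed as cm


@pytest.fixture(scope="session")
def planted_study():
    """Small study with one mediated trans-eQTL, one direct, and null probes.

    snp1 (chr1) -> probe1 (chr1, cis, R2=0.3) -> probe2 (chr2, mediated, beta=0.6)
    snp2 (chr2) -> probe3 (chr1, direct trans across chromosomes, beta=0.35)
    """
    cfg = cm.StudyConfig(
        n_samples=400,
        n_variants=40,
        n_probes=20,
        seed=11,
        planted_cis=(cm.CisEffect("snp1", "probe1", 0.3),),
        planted_trans=(
            cm.TransEffect("snp1", "probe2", "mediated", 0.6, "probe1"),
            cm.TransEffect("snp2", "probe3", "direct", 0.35),
        ),
    )
    return cm.simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """Global-null study: no planted effects at all."""
    return cm.simulate_study(
        cm.StudyConfig(n_samples=200, n_variants=60, n_probes=30, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
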