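import numpy as np
import pytest

from hdxdock.fixtures import FixtureSpec, make_decoy_ensemble, make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """Default toy complex and its docking configuration."""
    spec = FixtureSpec(seed=11)
    reference, config = make_toy_complex(spec)
    return spec, reference, config


@pytest.fixture(scope="session")
def small_ensemble(toy):
    """30 decoys with base scores and true iRMSDs (noisy score-iRMSD coupling)."""
    spec, reference, config = toy
    spec30 = FixtureSpec(seed=11, n_decoys=30)
    models, base_scores, irmsd = make_decoy_ensemble(reference, spec30)
    return reference, config, models, base_scores, irmsd


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
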