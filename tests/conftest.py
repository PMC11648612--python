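import numpy as np
import pytest

from sonoresponse import (
    EphysSimParams,
    JitterConfig,
    PsthParams,
    build_psth,
    compute_bands,
    simulate_spikes,
)


@pytest.fixture(scope="session")
def null_session():
    """One simulated null multiunit session (no evoked modulation)."""
    rec, truth = simulate_spikes(EphysSimParams(seed=11))
    return rec, truth


@pytest.fixture(scope="session")
def null_bands(null_session):
    """Jitter bands of the null session, shared across tests (read-only)."""
    rec, _ = null_session
    params = PsthParams()
    cfg = JitterConfig(rng_seed=5, n_surrogates=250)
    return build_psth(rec, params), compute_bands(rec, params, cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
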