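import numpy as np
import pytest

from methperm import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-probe cohort with 20 strong spikes; study-design group sizes."""
    return simulate_cohort(
        CohortConfig(n_probes=300, n_spiked=20, spike_delta=-0.4, seed=7)
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Spike-free cohort with independent per-probe noise.

    Shared sample-level components are disabled so that per-probe signs
    of the case/control difference are independent fair coins — the
    regime where binomial error bounds on direction tallies apply.
    """
    return simulate_cohort(
        CohortConfig(n_probes=300, n_spiked=0, sample_effect_sd=0.0,
                     n_latent_factors=0, seed=13)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
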