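import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def headings45():
    return np.arange(0.0, 360.0, 45.0)


@pytest.fixture(scope="session")
def validation_suite():
    """One full estimator-validation simulation (10 sets), shared."""
    from headingshift.synthetic_neurons import simulate_validation_suite

    return simulate_validation_suite(n_sets=10, seed=0)


@pytest.fixture(scope="session")
def small_temporal_population():
    """Small spiking dataset for reference-frame unit tests."""
    from headingshift.synthetic_neurons import (
        NeuronSpec,
        VonMisesParams,
        simulate_temporal_dataset,
    )

    rng = np.random.default_rng(7)
    pop = [
        NeuronSpec(
            base=VonMisesParams(
                A=float(rng.uniform(40, 80)),
                phi_deg=float(rng.uniform(0, 360)),
                k=3.0,
            ),
            frame_weight=1.0,
            baseline_sps=5.0,
        )
        for _ in range(12)
    ]
    return simulate_temporal_dataset(pop, reps=4, seed=13)
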