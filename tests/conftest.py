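import pytest

from mirdecay import (
    DecayDataset,
    REFERENCE_RATES,
    analytic_decay_curve,
    condition_network,
    generate_experiment,
)
from mirdecay.simulate import DEFAULT_TIME_GRID

STAR_CONDITIONS = ("control_negative", "mirisc_only", "pan3_kd", "control_positive")


@pytest.fixture(scope="session")
def networks():
    """The four experimental star networks with the reference rates bound."""
    return {c: condition_network(c, REFERENCE_RATES) for c in STAR_CONDITIONS}


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Exact survival curves for all five conditions (no noise, 1 replicate)."""
    return generate_experiment(
        REFERENCE_RATES, sigma_log=0.0, n_replicates=1, seed=0
    )


@pytest.fixture(scope="session")
def noisy_control():
    """Negative-control data with the default replicate noise model."""
    net = condition_network("control_negative", REFERENCE_RATES)
    base = analytic_decay_curve(net, DEFAULT_TIME_GRID)
    from mirdecay import add_measurement_noise

    noisy = add_measurement_noise(base, 0.05, 3, seed=42)
    return DecayDataset("control_negative", noisy.observations, normalized=True)
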