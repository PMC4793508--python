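import pytest

from splicequant.simulate import (
    AmpSimConfig,
    MixtureScenario,
    simulate_amplification,
    simulate_mixture_experiment,
)


@pytest.fixture(scope="session")
def default_curve():
    """Noiseless 40-cycle curve, E = 1.9, 10^4 starting copies."""
    return simulate_amplification(AmpSimConfig())


@pytest.fixture(scope="session")
def mixture_dataset():
    """Noiseless five-ratio mixture titration (1:9 ... 9:1), triplicates."""
    return simulate_mixture_experiment(MixtureScenario(seed=42))
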