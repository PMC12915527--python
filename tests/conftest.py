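import pytest
from hypothesis import HealthCheck, settings

from durens.synthetic_data import (
    EffectSizes,
    GeneratorConfig,
    generate_dataset,
    worked_example_fixture,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_data():
    """The hand-written worked-example dataset."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def recovery_peaks():
    """50 planted induced peaks (log2 effect 4) among 1950 nulls, 3 replicates."""
    return generate_dataset(
        GeneratorConfig(
            n_peaks=2000,
            n_genes=50,
            replicates=3,
            class_fractions={"persistent": 0.025},
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def durability_peaks():
    """100 fully-persistent + 100 decaying induced peaks among 1800 nulls, 2 reps.

    The persistent class retains the complete 8-h signal after washout
    (washout drop 0) so the planted dichotomy is persiste-vs-reverted.
    """
    return generate_dataset(
        GeneratorConfig(
            n_peaks=2000,
            n_genes=50,
            effect_sizes=EffectSizes(persistent_washout_drop=0.0),
            class_fractions={"persistent": 0.05, "decaying": 0.05},
            seed=12,
        )
    )


@pytest.fixture(scope="session")
def trajectory_peaks():
    """Persistent / decaying / further-increasing classes for clustering."""
    return generate_dataset(
        GeneratorConfig(
            n_peaks=3000,
            n_genes=50,
            class_fractions={"persistent": 0.04, "decaying": 0.04, "increasing": 0.04},
            seed=13,
        )
    )


@pytest.fixture(scope="session")
def memory_dataset():
    """Default class mix with potentiated / tolerized genes and couplings."""
    return generate_dataset(GeneratorConfig(n_peaks=3000, n_genes=3000, seed=21))


@pytest.fixture(scope="session")
def null_peaks():
    """All-null peak matrix for p-value calibration."""
    return generate_dataset(
        GeneratorConfig(n_peaks=2000, n_genes=50, class_fractions={}, seed=5)
    )
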