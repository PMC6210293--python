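import pytest

from wristcal.profiles import reference_profiles
from wristcal.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def profiles():
    return {p.name: p for p in reference_profiles()}


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-child cohort over all nine activities, clean (no contamination)."""
    cfg = GeneratorConfig(
        n_children=12,
        epochs_per_activity=30,
        activities=reference_profiles(),
        p_stand=0.0,
        seed=42,
    )
    return generate_dataset(cfg)
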