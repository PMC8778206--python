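import logging

import pytest

from grain_ionome.simulate import default_config, simulate_trial

# the generator logs every zero-clip; keep test output readable
logging.getLogger("grain_ionome.simulate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_trial():
    """Full-size default trial (135 genotypes × 2 years × 4 reps), seed 0."""
    records, truth = simulate_trial(default_config(seed=0))
    return records, truth


@pytest.fixture(scope="session")
def small_config():
    """Reduced trial for fast per-test simulation: 30 genotypes, 2 reps."""
    return default_config(
        seed=0,
        n_genotypes=30,
        reps=2,
        group_counts={
            "CIMMYT_synthetic": 8,
            "Japan_synthetic": 4,
            "USA": 4,
            "KASIB_early": 4,
            "KASIB_intermediate": 4,
            "KASIB_late": 4,
            "check": 2,
        },
    )


@pytest.fixture(scope="session")
def small_trial(small_config):
    records, truth = simulate_trial(small_config)
    return records, truth
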