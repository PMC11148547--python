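import pytest

from smokesig.simulate import ARCHETYPES, TISSUES, SimConfig, build_truth, simulate_dataset


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """Compact cohort used by most unit tests: 100 CpGs, 60 samples/tissue."""
    base = dict(
        n_cpgs=100,
        archetype_sizes={a: 20 for a in ARCHETYPES},
        n_samples={t: {"never": 30, "current": 30} for t in TISSUES},
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_truth():
    """Truth ledger at the reference study conditions (500 CpGs, effect 0.2)."""
    return build_truth(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_dataset(default_truth):
    return simulate_dataset(default_truth)


@pytest.fixture(scope="session")
def small_truth():
    return build_truth(small_config())


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return simulate_dataset(small_truth)
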