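import numpy as np
import pytest

from corefit import (
    Compendium,
    RankedProfile,
    SyntheticSpec,
    extract_signatures,
    generate_compendium,
    support_counts,
)


@pytest.fixture(scope="session")
def small_world():
    """Scaled-down planted world for fast unit tests (not the stated defaults)."""
    spec = SyntheticSpec(
        universe_size=600,
        n_correctors=8,
        n_background=60,
        n_core_down=40,
        n_core_up=0,
        support_prob=0.85,
        core_strength=2.5,
        n_moa_clusters=3,
        moa_module_size=60,
        background_module_size=60,
        seed=11,
    )
    compendium, truth = generate_compendium(spec)
    return compendium, truth


@pytest.fixture(scope="session")
def small_correctors(small_world):
    compendium, truth = small_world
    return compendium.subset(truth.corrector_ids)


@pytest.fixture(scope="session")
def small_background(small_world):
    compendium, truth = small_world
    return compendium.subset(truth.background_ids)


@pytest.fixture(scope="session")
def small_support(small_correctors):
    return support_counts(extract_signatures(small_correctors))


def random_compendium(rng: np.random.Generator, universe_size: int, n: int) -> Compendium:
    """Uniformly random ranked lists over a shared universe."""
    probes = np.array([f"P{i:04d}" for i in range(universe_size)], dtype=object)
    return Compendium(
        [
            RankedProfile(f"D{j:03d}", tuple(probes[rng.permutation(universe_size)]))
            for j in range(n)
        ]
    )
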