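import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def point_mutate(rng, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append("ACGT"[("ACGT".index(ch) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(ch)
    return "".join(out)


@pytest.fixture
def small_sim_config():
    """Down-scaled race panel for fast end-to-end tests."""
    from repeatome.simulate import SimConfig

    return SimConfig(
        seed=7,
        n_races=4,
        n_sat_families=6,
        shared_fraction=0.67,
        monomer_len_range=(60, 150),
        genome_len=200_000,
        n_pairs=8_000,
    )
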