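import numpy as np
import pytest

from pcrmarkers import generate_fixture, load_panel


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def fixture_small():
    """Seeded 2-contig fixture: 30 variants, half engineered CAPS."""
    return generate_fixture(
        seed=101, n_contigs=2, contig_length=2500, n_variants=30,
        planted_caps_fraction=0.5, neighbour_fraction=0.2,
    )


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
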