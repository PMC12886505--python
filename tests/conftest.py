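import numpy as np
import pytest

from rnai_nto.synthetic_data import PathwaySpec, SimulationConfig, simulate_dataset

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded synthetic dataset shared by the integration-style tests."""
    config = SimulationConfig(
        seed=7,
        n_genes=80,
        transcript_length_range=(300, 500),
        planted_matches=((3, 8, "sense"), (5, 11, "antisense"), (8, 13, "sense")),
        planted_homologs=((10, 0.92),),
        de_fraction=0.05,
        mean_depth=3e5,
        pathway_spec=PathwaySpec(n_pathways=6, size_range=(4, 8)),
    )
    return simulate_dataset(config)
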