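import numpy as np
import pytest

from satdyn.library import SatFamily
from satdyn.simulate import FamilySpec, SimConfig, build_genome, make_consensus


@pytest.fixture(scope="session")
def small_sim():
    """A 200 kb genome with two planted families, plus its truth table."""
    config = SimConfig(
        genome_length=200_000,
        families=[
            FamilySpec(monomer_length=170, target_occupancy=0.05, divergence_rate=0.05),
            FamilySpec(monomer_length=300, target_occupancy=0.03, divergence_rate=0.15),
        ],
        coverage=0.2,
        seed=11,
    )
    genome, truth = build_genome(config)
    return config, genome, truth


@pytest.fixture(scope="session")
def small_library(small_sim):
    _, _, truth = small_sim
    return [
        SatFamily("SimSat01", truth.families["fam01"].consensus),
        SatFamily("SimSat02", truth.families["fam02"].consensus),
    ]


@pytest.fixture()
def random_seq():
    def _make(length, seed, gc=0.5):
        return make_consensus(max(10, length), gc, seed)[:length] if length >= 10 else \
            "".join(np.random.default_rng(seed).choice(list("ACGT"), size=length))

    return _make
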