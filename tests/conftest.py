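import numpy as np
import pytest
from hypothesis import settings

import ploidyclock as pc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def genome():
    return pc.toy_genome(n_chroms=4, chrom_length=10_000_000)


@pytest.fixture
def diploid_profile(genome):
    segs = [pc.Segment(c, 0, l, 1, 1) for c, l in genome.chromosomes]
    return pc.SegmentProfile("diploid", 1.0, segs, genome)


@pytest.fixture
def tetraploid_profile(genome):
    segs = [pc.Segment(c, 0, l, 2, 2) for c, l in genome.chromosomes]
    return pc.SegmentProfile("tetra", 1.0, segs, genome)



@pytest.fixture(scope="session")
def simulated_tumor(genome):
    """One well-powered tumor with a single doubling at pi = 0.6."""
    truth = pc.SimulationTruth(
        age_at_diagnosis=66.0, mutation_rate=50.0, wgd_times=(0.6,),
        purity=0.7, depth=60.0, seed=42,
    )
    profile, log, muts = pc.simulate_tumor(genome, truth, n_cna=8)
    return truth, profile, log, muts


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
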