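import numpy as np
import pytest

from quadmap.genomeio import Genome, Interval
from quadmap import synthgen


@pytest.fixture
def flat_genome():
    """1 kb all-A single-chromosome genome (neutral coordinate frame)."""
    return Genome({"chr1": "A" * 1000})


@pytest.fixture
def two_chrom_genome():
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return Genome(
        {
            name: bases[rng.integers(0, 4, size=5000)].tobytes().decode()
            for name in ("chrA", "chrB")
        }
    )


@pytest.fixture
def small_sim():
    """A small but complete simulation: genome + regions + replicates."""
    lengths = {"chr1": 200_000}
    regions = synthgen.default_peak_regions(lengths, 5, 1000)
    config = synthgen.SimConfig(
        chromosome_lengths=lengths,
        peak_regions=regions,
        fragments_per_replicate=2000,
        seed=11,
    )
    genome = synthgen.simulate_genome(config)
    replicates = synthgen.simulate_fragments(config, genome)
    return config, genome, replicates
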