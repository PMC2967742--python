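import pytest

from l1scout.simulate import SimulationConfig, simulate_trio

# Compact trio used by most integration-style tests: one 20 kb contig,
# 6 sites, 60x coverage so every junction has ample read support.
SMALL_CONFIG = SimulationConfig(
    genome_len=20_000,
    n_contigs=1,
    n_sites=6,
    cassette_len=1000,
    coverage=60.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_trio():
    return simulate_trio(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_truth_keys(small_trio):
    return {
        (t.contig, t.observed_position, t.l1_orientation) for t in small_trio.truth
    }
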