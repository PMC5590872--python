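import logging

import pytest

import sexmark as sm
from sexmark.simdata import SimGenomeSpec, simulate_genome

logging.getLogger("sexmark").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def params():
    return sm.PipelineParams()


@pytest.fixture(scope="session")
def small_genome():
    """300 kb chromosome pair, 6 segments, one autosome carrying a verbatim
    copy of segment 2 (a paralog decoy for the uniqueness screen)."""
    spec = SimGenomeSpec(
        chrom_len=300_000,
        n_gametolog_segments=6,
        seed=7,
        n_autosomes=1,
        autosome_len=60_000,
        planted_paralog_ids=(2,),
    )
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def small_markers(small_genome, params):
    pairs = sm.extract_markers(
        small_genome.seq_x, small_genome.seq_y, small_genome.autosomes, params
    )
    assert pairs, "fixture genome must yield markers"
    return pairs


@pytest.fixture(scope="session")
def small_index(small_markers, params):
    return sm.build_marker_index(small_markers, params.seed_k)
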