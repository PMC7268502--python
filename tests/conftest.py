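import pytest

from cnvmeta import (
    CallerRole,
    CallerTrack,
    IntervalCall,
    ScenarioConfig,
    ValueScale,
    make_arbitration_fixture,
    make_scenario,
)

#: reduced study conditions for unit tests that only need a valid scenario
SMALL_CONFIG = ScenarioConfig(
    n_chroms=1,
    chrom_length=2_000_000,
    segments_per_chrom=(10, 15),
    segment_length=(5_000, 20_000),
    genes_per_chrom=40,
    gene_length=(3_000, 15_000),
)


@pytest.fixture
def arbitration_scenario():
    return make_arbitration_fixture()


@pytest.fixture
def small_scenario():
    return make_scenario(seed=7, config=SMALL_CONFIG)


def make_track(values, role=CallerRole.COVERAGE, scale=ValueScale.ABSOLUTE_CN,
               chrom="1", bin_size=100):
    """Contiguous equal-sized bins with the given values."""
    calls = [
        IntervalCall(chrom, i * bin_size, (i + 1) * bin_size, float(v))
        for i, v in enumerate(values)
    ]
    return CallerTrack(role, scale, calls)
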