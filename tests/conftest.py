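import pytest

from idmrscan.genome_data import (
    CpGSiteCall,
    GenomicInterval,
    MethylomeTrack,
)
from idmrscan.synthetic_data import SimConfig, simulate_all


def make_track(levels, chrom="chr1", start=100, step=10, sample_id="s1", depth=30, **kw):
    """A small track with one site per level at start, start+step, ..."""
    sites = [
        CpGSiteCall(chrom, start + i * step, lv, depth if lv is not None else 0)
        for i, lv in enumerate(levels)
    ]
    return MethylomeTrack(sample_id=sample_id, sites=sites, **kw)


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic study under the default conditions, shared read-only."""
    return simulate_all(SimConfig(seed=7))


@pytest.fixture
def interval():
    return GenomicInterval("chr1", 100, 300)
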