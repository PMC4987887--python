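import numpy as np
import pytest

from trackmatch import GenomeLayout, SignalTrack


@pytest.fixture
def tiny_layout():
    return GenomeLayout([("chr1", 100_000), ("chr2", 50_000)])


@pytest.fixture
def track_builder(tiny_layout):
    """Build a native-resolution track from {chrom: [(start, end, value)]}."""

    def build(intervals, layout=None):
        return SignalTrack.from_interval_lists(layout or tiny_layout, intervals)

    return build


@pytest.fixture
def block_pair(tiny_layout):
    """Query/target pair sharing one 1500-bp variable-signal block on chr1,
    flat elsewhere."""
    rng = np.random.default_rng(42)
    start = 20_000
    ivs = []
    pos = start
    while pos < start + 1500:
        seg = min(150, start + 1500 - pos)
        ivs.append((pos, pos + seg, float(rng.uniform(1, 10))))
        pos += seg
    q = SignalTrack.from_interval_lists(tiny_layout, {"chr1": ivs})
    t = SignalTrack.from_interval_lists(tiny_layout, {"chr1": list(ivs)})
    return q, t, (start, start + 1500)
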