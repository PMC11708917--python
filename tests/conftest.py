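import numpy as np
import pandas as pd
import pytest

from recland.core_io import GenomeLayout, RateTrack


@pytest.fixture
def small_layout():
    return GenomeLayout([("lg1", 2_000_000, True), ("lg2", 1_000_000, True)])


@pytest.fixture
def flat_track(small_layout):
    """Uniform 1 cM/Mb track covering both lgs in 10 kb intervals."""
    rows = []
    for g in small_layout:
        starts = np.arange(0, g.length_bp, 10_000)
        rows += [
            (g.lg_id, s, min(s + 10_000, g.length_bp), 1e-8) for s in starts
        ]
    return RateTrack(
        pd.DataFrame(rows, columns=["lg", "start", "end", "value"]), small_layout
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
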