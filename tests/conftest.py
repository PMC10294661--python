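import dataclasses

import numpy as np
import pytest

from bindscan.chip import DepthTrack
from bindscan.spr import DuplexDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20230530)


@pytest.fixture
def flat_track():
    return DepthTrack("rep", np.full(9000, 10.0))


def annotate_intact(design: DuplexDesign, repeat_spans) -> DuplexDesign:
    """Record which labeled repeat spans are fully contained in a design."""
    start = design.region_start or 0
    end = design.region_end if design.region_end is not None else start + len(design.test_seq)
    intact = tuple(
        label for label, s, e in repeat_spans if start <= s and e <= end
    )
    return dataclasses.replace(design, intact_repeats=intact)
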