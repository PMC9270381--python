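import numpy as np
import pytest

from hothand.io_model import CareerRecord, Discipline, Format


@pytest.fixture
def make_career():
    def _make(scores, player_id="p1", fmt=Format.ODI, disc=Discipline.BATTING):
        return CareerRecord(player_id, fmt, disc, np.asarray(scores))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
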