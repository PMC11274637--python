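import numpy as np
import pytest

from handkin import JointAngleSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(angles, fps=30.0, finger="middle", rom_cap=180.0, **kw):
    return JointAngleSeries(
        finger=finger, fps=fps, angles=np.asarray(angles, dtype=float), rom_cap_deg=rom_cap, **kw
    )


@pytest.fixture
def series_factory():
    return make_series
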