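import numpy as np
import pytest

from saltatrack import RunConfig, Track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return RunConfig()


def make_track(positions, dt=5.0, cell_id="c1", group="WT"):
    """Build a Track from a list of (x, y) positions at uniform dt."""
    positions = np.asarray(positions, dtype=float)
    times = np.arange(len(positions)) * dt
    return Track(cell_id=cell_id, group=group, times=times, positions=positions)


def track_from_displacements(disps, dt=5.0, **kw):
    """A straight-line track whose per-interval displacements are ``disps``."""
    x = np.concatenate([[0.0], np.cumsum(disps)])
    return make_track(np.column_stack([x, np.zeros_like(x)]), dt=dt, **kw)
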