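import numpy as np
import pytest

from celltrax import AcquisitionConfig, Track


@pytest.fixture
def config_a1():
    """Acquisition at the standard pixel/frame calibration, interval size 1."""
    return AcquisitionConfig(pixel_size_um=1.314, frame_interval_min=7.0, interval_size=1)


@pytest.fixture
def config_a3():
    """Acquisition at the standard calibration with 3-frame binning."""
    return AcquisitionConfig(pixel_size_um=1.314, frame_interval_min=7.0, interval_size=3)


def make_track(xy, cell_id=0, frames=None):
    """Build a Track from a sequence of (x, y) pixel positions."""
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy), dtype=float)
    pts = np.column_stack([np.asarray(frames, dtype=float), xy])
    return Track(cell_id=cell_id, points=pts)


def straight_track(n_frames, step_px=3.0, direction_deg=0.0, start=(50.0, 50.0), cell_id=0):
    """A perfectly straight track heading at a compass (y-up) angle."""
    t = np.arange(n_frames)
    rad = np.radians(direction_deg)
    x = start[0] + step_px * t * np.cos(rad)
    y = start[1] - step_px * t * np.sin(rad)  # screen y is down
    return make_track(np.column_stack([x, y]), cell_id=cell_id)
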