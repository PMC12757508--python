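import numpy as np
import pytest

from ohdkit.paradigm import build_ohd_schedule, default_paradigm, windows_from_schedule
from ohdkit.telemetry import TrackingCalibration, TrackingTrace


@pytest.fixture(scope="session")
def paradigm_config():
    return default_paradigm()

@pytest.fixture(scope="session")
def schedule(paradigm_config):
    return build_ohd_schedule(paradigm_config)

@pytest.fixture(scope="session")
def windows(schedule):
    return windows_from_schedule(schedule)

@pytest.fixture
def calibration():
    """Study-like calibration: 0.458 mm/pixel at 30 fps, primary end at x=0."""
    return TrackingCalibration(mm_per_pixel=0.458, avg_fps=30.0,
                               primary_coord_px=0.0, primary_axis="x",
                               primary_direction=1)

def make_trace(x_mm, calibration, y_px=None):
    """Trace whose centroid follows the given mm distances from the primary end."""
    x_mm = np.asarray(x_mm, dtype=float)
    return TrackingTrace(
        frame_index=np.arange(len(x_mm)),
        x_px=x_mm / calibration.mm_per_pixel,
        y_px=np.full(len(x_mm), 80.0) if y_px is None else np.asarray(y_px, float),
        calibration=calibration,
    )
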