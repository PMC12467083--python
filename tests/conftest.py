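"""Shared fixtures: a compact four-channel probe setup for fast tests.

The full instrument spans 1510-1590 nm (40001 samples at 2 pm); unit tests
use a narrower grid with closer channels so each Gaussian fit touches ~2000
samples instead of ~10000, with identical physics.
"""

import numpy as np
import pytest

from fbgpalp import BraggChannel, NoiseModel, ShiftVector, WavelengthGrid


@pytest.fixture
def small_grid() -> WavelengthGrid:
    # 1528-1544 nm at the 2 pm hardware step
    return WavelengthGrid(start_nm=1528.0, step_pm=2.0, n_points=8001)


@pytest.fixture
def small_channels() -> list[BraggChannel]:
    centers = (1530.0, 1534.0, 1538.0, 1542.0)
    azimuths = (0.0, 90.0, 180.0, 270.0)
    return [
        BraggChannel(channel_id=i + 1, nominal_center_nm=centers[i],
                     azimuth_deg=azimuths[i])
        for i in range(4)
    ]


@pytest.fixture
def quiet() -> NoiseModel:
    return NoiseModel(sigma_rel=0.0)


def shift_vector(*values: float) -> ShiftVector:
    return ShiftVector(channel_ids=tuple(range(1, len(values) + 1)),
                       shifts_pm=tuple(float(v) for v in values))
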