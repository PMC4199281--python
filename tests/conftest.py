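"""Shared fixtures: small grids, rendered bumps, and full masks."""

from __future__ import annotations

import numpy as np
import pytest

from boldspread.synth import BumpSpec, render_bump
from boldspread.volumes import MaskVolume, StatVolume

GRID_SHAPE = (17, 17, 17)
VOXEL = (3.0, 3.0, 3.0)
CENTER_MM = (24.0, 24.0, 24.0)  # voxel (8, 8, 8)


@pytest.fixture
def full_mask() -> MaskVolume:
    return MaskVolume(data=np.ones(GRID_SHAPE, dtype=bool), voxel_size=VOXEL, label="brain")


@pytest.fixture
def bump_volume() -> StatVolume:
    """Noise-free sigma = 4 mm activation bump centred on voxel (8, 8, 8)."""
    spec = BumpSpec(center=CENTER_MM, amplitude=2.0, sigma=4.0, roi_label="roi")
    return render_bump(spec, GRID_SHAPE, VOXEL)


def make_bump(amplitude: float = 2.0, sigma: float = 4.0) -> StatVolume:
    spec = BumpSpec(center=CENTER_MM, amplitude=amplitude, sigma=sigma, roi_label="roi")
    return render_bump(spec, GRID_SHAPE, VOXEL)
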