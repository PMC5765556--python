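import numpy as np
import pytest

from fangmech import VoxelVolume, phenotype_presets


@pytest.fixture(scope="session")
def presets():
    return phenotype_presets()


def make_ball(radius_vox: int, voxel_size: float = 2.0) -> VoxelVolume:
    """Digital ball: voxels whose centres lie within the given radius."""
    n = 2 * radius_vox + 5
    c = n // 2
    g = np.indices((n, n, n)).reshape(3, -1).T - c
    mask = (np.linalg.norm(g, axis=1) <= radius_vox).reshape(n, n, n)
    return VoxelVolume(mask.astype(np.uint8), voxel_size)


def make_tube(length_vox: int, outer_vox: float, inner_vox: float = 0.0,
              voxel_size: float = 10.0, wedge_deg: float = 0.0) -> VoxelVolume:
    """Straight tube along x; optional coaxial bore and removed wedge.

    The wedge (about the +y direction, symmetric in z) emulates an open
    groove in a 2D annulus cross-section.
    """
    n = int(2 * outer_vox) + 5
    c = (n - 1) / 2.0
    y, z = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    r = np.hypot(y, z)
    sec = r <= outer_vox
    if inner_vox > 0:
        sec &= r >= inner_vox
    if wedge_deg > 0:
        ang = np.degrees(np.abs(np.arctan2(z, y)))
        sec &= ~(ang <= wedge_deg / 2.0)
    mask = np.broadcast_to(sec, (length_vox,) + sec.shape).copy()
    return VoxelVolume(mask.astype(np.uint8), voxel_size)


def axis_polyline(volume: VoxelVolume, n_points: int = 12) -> np.ndarray:
    """Centreline of a tube built by make_tube, base to tip, in μm."""
    nx = volume.shape[0]
    c = (volume.shape[1] - 1) / 2.0
    xs = np.linspace(0, (nx - 1) * volume.voxel_size, n_points)
    pts = np.column_stack([xs, np.full(n_points, c * volume.voxel_size),
                           np.full(n_points, c * volume.voxel_size)])
    return pts + volume.origin
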