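"""Voxel volumes and surface meshes: image-stack / STL I/O, segmentation, conversion.

Every downstream measurement and simulation operates on a :class:`VoxelVolume`:
a 3D scalar grid with an isotropic physical voxel size in micrometres.  Voxel
indices are 0-based and the physical coordinate of voxel ``(i, j, k)`` is
``origin + (i, j, k) * voxel_size`` (voxel-centre convention, right-handed
axes).  Binary volumes carry labels ``{0 = background, 1 = material}``.

Image stacks are single-channel TIFF slices stacked along the *third* axis in
lexicographic filename order.  Meshes are STL (both dialects read, binary
written), with vertex coordinates in micrometres.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
import trimesh
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes

logger = logging.getLogger("fangmech")

__all__ = [
    "VoxelVolume",
    "SurfaceMesh",
    "read_image_stack",
    "write_image_stack",
    "read_stl",
    "write_stl",
    "segment_material",
    "voxelize_mesh",
    "extract_surface",
]


class MissingInputError(FileNotFoundError):
    """No input files matched the requested pattern."""


class FormatError(ValueError):
    """Input data violates the expected file or array format."""


class GeometryError(ValueError):
    """Mesh or volume geometry is unusable (e.g. not watertight, empty)."""


@dataclass
class VoxelVolume:
    """A 3D image with physical scale.

    Parameters
    ----------
    data:
        3D array, grayscale intensity or material label per voxel.
    voxel_size:
        Edge length of one (cubic) voxel in micrometres.
    origin:
        Physical coordinate (μm) of the centre of voxel (0, 0, 0).
    axes:
        Convention tag; ``"xyz"`` means array axis 0 is physical x, etc.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: str = "xyz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(f"expected a non-empty 3D array, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Physical coordinates (μm) of voxel centres, optionally masked."""
        if mask is None:
            idx = np.indices(self.data.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.origin + idx * self.voxel_size

    def material_mask(self) -> np.ndarray:
        return self.data > 0


@dataclass
class SurfaceMesh:
    """Triangle mesh in micrometre coordinates."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise FormatError("face index exceeds vertex count")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def volume(self) -> float:
        """Signed enclosed volume in μm³ (positive for outward orientation)."""
        return float(abs(self.to_trimesh().volume))


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def read_image_stack(path_pattern: str, voxel_size: float) -> VoxelVolume:
    """Read TIFF slices matching a glob pattern into a volume.

    Slices are stacked along the third axis in lexicographic filename order;
    intensities are preserved as stored.
    """
    paths = sorted(glob.glob(path_pattern))
    if not paths:
        raise MissingInputError(f"no files match {path_pattern!r}")
    slices = [tifffile.imread(p) for p in paths]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1 or slices[0].ndim != 2:
        raise FormatError(f"inconsistent slice shapes in stack: {sorted(shapes)}")
    data = np.stack(slices, axis=2)
    logger.info("read stack %s: shape=%s voxel_size=%g um", path_pattern, data.shape, voxel_size)
    return VoxelVolume(data=data, voxel_size=float(voxel_size))


def write_image_stack(volume: VoxelVolume, directory: str, prefix: str = "slice") -> list[str]:
    """Write one TIFF per third-axis slice with zero-padded numeric filenames.

    Lossless for integer label/intensity data.  Returns the written paths.
    """
    os.makedirs(directory, exist_ok=True)
    n = volume.data.shape[2]
    width = max(4, len(str(n - 1)))
    paths = []
    for k in range(n):
        path = os.path.join(directory, f"{prefix}_{k:0{width}d}.tif")
        tifffile.imwrite(path, np.ascontiguousarray(volume.data[:, :, k]))
        paths.append(path)
    logger.info("wrote stack to %s: %d slices, shape=%s", directory, n, volume.shape)
    return paths


# ---------------------------------------------------------------------------
# STL meshes
# ---------------------------------------------------------------------------

def _validate_stl(path: str) -> None:
    """Cheap structural check so truncated binary files fail loudly."""
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
    if len(head) < 15:
        raise FormatError(f"STL file {path!r} is truncated")
    if head.lstrip()[:5].lower() == b"solid" and b"facet" in head:
        return  # ASCII dialect; the parser reports its own errors
    if len(head) < 84:
        raise FormatError(f"STL file {path!r} is truncated")
    n_tri = int.from_bytes(head[80:84], "little")
    expected = 84 + 50 * n_tri
    if size != expected:
        raise FormatError(
            f"binary STL {path!r} is truncated: {size} bytes, expected {expected}"
        )


def read_stl(path: str) -> SurfaceMesh:
    """Read an STL file (binary or ASCII dialect)."""
    _validate_stl(path)
    try:
        mesh = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise FormatError(f"cannot parse STL file {path!r}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"STL file {path!r} contains no triangles")
    logger.info("read STL %s: %d faces", path, len(mesh.faces))
    return SurfaceMesh.from_trimesh(mesh)


def write_stl(mesh: SurfaceMesh, path: str) -> None:
    """Write a mesh as binary STL (coordinates stored as float32)."""
    mesh.to_trimesh().export(path, file_type="stl")
    logger.info("wrote STL %s: %d faces", path, len(mesh.faces))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_material(
    volume: VoxelVolume,
    threshold: float | None = None,
    keep_largest: bool = False,
) -> VoxelVolume:
    """Binarise a grayscale volume into {0 = background, 1 = material}.

    If ``threshold`` is omitted it is chosen by between-class variance
    maximisation (Otsu) on the full intensity histogram.  Voxels with
    intensity strictly above the threshold become material.  With
    ``keep_largest`` only the largest 26-connected material component is
    retained.
    """
    data = volume.data
    if threshold is None:
        if np.ptp(data) == 0:
            raise ValueError("constant-intensity volume: supply an explicit threshold")
        threshold = float(threshold_otsu(np.asarray(data)))
    binary = (data > threshold).astype(np.uint8)
    if keep_largest and binary.any():
        labels, nlab = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
        if nlab > 1:
            counts = np.bincount(labels.ravel())[1:]
            binary = (labels == (int(np.argmax(counts)) + 1)).astype(np.uint8)
    logger.info(
        "segmented volume at threshold %g: material fraction %.4f",
        threshold, binary.mean(),
    )
    return VoxelVolume(data=binary, voxel_size=volume.voxel_size,
                       origin=volume.origin.copy(), axes=volume.axes)


# ---------------------------------------------------------------------------
# Mesh <-> voxel conversion
# ---------------------------------------------------------------------------

def voxelize_mesh(mesh: SurfaceMesh, voxel_size: float, pad: int = 1) -> VoxelVolume:
    """Rasterise a watertight mesh: voxel is material iff its centre is inside.

    Inside/outside is decided by ray-crossing parity along vertical (z)
    columns of voxel centres; the column grid is offset by a tiny irrational
    fraction of the voxel size so rays do not pass exactly through mesh edges
    or vertices.  The bounding grid is padded by ``pad`` background voxels on
    every side.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise GeometryError("mesh must be watertight for voxelization")
    h = float(voxel_size)
    lo = tm.bounds[0] - pad * h
    hi = tm.bounds[1] + pad * h
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    origin = lo + 0.5 * h

    eps = h * np.array([2 ** -0.5, 3 ** -0.5]) * 1e-6
    xs = origin[0] + np.arange(shape[0]) * h + eps[0]
    ys = origin[1] + np.arange(shape[1]) * h + eps[1]

    tris = np.asarray(tm.triangles)  # (n, 3, 3)
    col_idx: list[np.ndarray] = []
    col_z: list[np.ndarray] = []
    for v0, v1, v2 in tris:
        det = (v1[1] - v2[1]) * (v0[0] - v2[0]) + (v2[0] - v1[0]) * (v0[1] - v2[1])
        if det == 0.0:
            continue  # projects to a degenerate (vertical) triangle
        i0 = np.searchsorted(xs, min(v0[0], v1[0], v2[0]))
        i1 = np.searchsorted(xs, max(v0[0], v1[0], v2[0]), side="right")
        j0 = np.searchsorted(ys, min(v0[1], v1[1], v2[1]))
        j1 = np.searchsorted(ys, max(v0[1], v1[1], v2[1]), side="right")
        if i0 >= i1 or j0 >= j1:
            continue
        X, Y = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        a = ((v1[1] - v2[1]) * (X - v2[0]) + (v2[0] - v1[0]) * (Y - v2[1])) / det
        b = ((v2[1] - v0[1]) * (X - v2[0]) + (v0[0] - v2[0]) * (Y - v2[1])) / det
        c = 1.0 - a - b
        hit = (a >= 0) & (b >= 0) & (c >= 0)
        if not hit.any():
            continue
        z = a[hit] * v0[2] + b[hit] * v1[2] + c[hit] * v2[2]
        ii, jj = np.nonzero(hit)
        col_idx.append((ii + i0) * shape[1] + (jj + j0))
        col_z.append(z)

    binary = np.zeros(shape, dtype=np.uint8)
    if col_idx:
        cols = np.concatenate(col_idx)
        zs = np.concatenate(col_z)
        order = np.lexsort((zs, cols))
        cols, zs = cols[order], zs[order]
        z_centers = origin[2] + np.arange(shape[2]) * h
        starts = np.flatnonzero(np.r_[True, cols[1:] != cols[:-1]])
        bounds = np.r_[starts, len(cols)]
        for s, e in zip(bounds[:-1], bounds[1:]):
            crossings = zs[s:e]
            parity = np.searchsorted(crossings, z_centers, side="left") % 2 == 1
            i, j = divmod(int(cols[s]), shape[1])
            binary[i, j, :] = parity

    logger.info("voxelized mesh at %g um: grid %s, %d material voxels",
                h, tuple(shape), int(binary.sum()))
    return VoxelVolume(data=binary, voxel_size=h, origin=origin)


def extract_surface(volume: VoxelVolume) -> SurfaceMesh:
    """Closed triangulated isosurface of a binary volume at the 0.5 level.

    Marching cubes on a zero-padded copy of the grid, so the result is always
    watertight; vertices are returned in physical micrometres.
    """
    mask = volume.material_mask()
    if not mask.any():
        raise GeometryError("volume contains no material voxels")
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * volume.voxel_size + volume.origin
    logger.info("extracted surface: %d vertices, %d faces", len(verts), len(faces))
    return SurfaceMesh(vertices=verts, faces=faces)
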