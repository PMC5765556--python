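"""Morphometric statistics of a fang from a binary volume and a polyline.

Implements the five standard microCT fang statistics — relative fang length,
slender ratio (length / mid-fang diameter), size-corrected wall thickness
(mean wall thickness / mid-fang diameter), material volume fraction (BV/TV)
of the mid-fang section, and curvature expressed as the segment angle of the
centreline's best-fit circle — plus the intermediates each one needs.

The fang length is the polyline arc length (>= 10 points, base to tip).  The
mid-fang section is a region of interest spanning 10% of the fang length
around the arc-length midpoint.  Wall thickness uses the local-thickness
(largest inscribed sphere) definition standard in trabecular-bone analysis.
BV/TV closes the material mask morphologically so that internal cavities —
including the open groove's channel — count toward the total volume TV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, optimize

from .voxel_io import VoxelVolume

logger = logging.getLogger("fangmech")

__all__ = [
    "Polyline",
    "MorphometricsReport",
    "CollinearPointsError",
    "fang_length",
    "relative_fang_length",
    "best_fit_circle",
    "mid_section_roi",
    "mid_diameter",
    "bvtv",
    "wall_thickness",
    "local_thickness",
    "full_report",
]

MIN_POLYLINE_POINTS = 10


class CollinearPointsError(ValueError):
    """Circle fit requested on (near-)collinear points: radius diverges."""


def _as_polyline(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < MIN_POLYLINE_POINTS:
        raise ValueError(f"polyline needs >= {MIN_POLYLINE_POINTS} points, got {len(pts)}")
    if (np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0).any():
        raise ValueError("polyline contains repeated consecutive points")
    return pts


@dataclass
class Polyline:
    """Ordered 3D points (μm) along the top of the fang, base to tip."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = _as_polyline(self.points)

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def read(cls, path: str) -> "Polyline":
        return cls(np.loadtxt(path, ndmin=2))

    def write(self, path: str) -> None:
        np.savetxt(path, self.points, fmt="%.6f")


@dataclass
class MorphometricsReport:
    """The five fang statistics plus their intermediates, one specimen."""

    fang_length: float
    skull_length: float
    relative_fang_length: float
    mid_diameter: float
    slender_ratio: float
    mean_wall_thickness: float
    size_corrected_wall_thickness: float
    bvtv: float
    segment_angle: float
    circle_radius: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Length statistics
# ---------------------------------------------------------------------------

def fang_length(polyline) -> float:
    """Polyline length: sum of consecutive segment Euclidean lengths (μm)."""
    pts = polyline.points if isinstance(polyline, Polyline) else _as_polyline(polyline)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def relative_fang_length(fang_len: float, skull_length: float) -> float:
    """Size-corrected fang length: fang length / skull length."""
    if skull_length <= 0:
        raise ValueError("skull_length must be positive")
    return fang_len / skull_length


# ---------------------------------------------------------------------------
# Circle fitting and curvature
# ---------------------------------------------------------------------------

def _fit_circle_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) circle fit refined by geometric least squares."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    span = max(np.ptp(x), np.ptp(y), 1e-30)
    if rank < 3 or (sv[-1] / sv[0]) < 1e-12:
        raise CollinearPointsError("points are collinear: best-fit radius is infinite")
    cx, cy, c = sol
    r = np.sqrt(max(c + cx * cx + cy * cy, 0.0))
    if r > 1e8 * span:
        raise CollinearPointsError("points are (near-)collinear: best-fit radius diverges")

    def residuals(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    fit = optimize.least_squares(residuals, x0=[cx, cy, r], method="lm")
    cx, cy, r = fit.x
    return np.array([cx, cy]), float(abs(r))


def best_fit_circle(polyline) -> tuple[np.ndarray, float, float]:
    """Best-fit circle of a 3D polyline and the segment angle it subtends.

    The points are projected onto their total-least-squares plane, a circle
    is fitted in-plane (algebraic fit refined geometrically), and the segment
    angle is accumulated monotonically from the wrapped angle increments of
    consecutive points about the centre — so arcs beyond 180° are measured
    correctly.

    Returns ``(centre (3,), radius μm, segment_angle degrees)``.
    """
    pts = polyline.points if isinstance(polyline, Polyline) else _as_polyline(polyline)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    e1, e2 = vt[0], vt[1]
    xy = np.column_stack([centered @ e1, centered @ e2])
    centre2d, radius = _fit_circle_2d(xy)

    ang = np.arctan2(xy[:, 1] - centre2d[1], xy[:, 0] - centre2d[0])
    inc = np.diff(ang)
    inc = (inc + np.pi) % (2 * np.pi) - np.pi  # wrap to (-pi, pi]
    segment_angle = float(np.degrees(abs(inc.sum())))
    centre3d = centroid + centre2d[0] * e1 + centre2d[1] * e2
    return centre3d, radius, segment_angle


# ---------------------------------------------------------------------------
# Mid-fang section
# ---------------------------------------------------------------------------

def _arc_length_projection(coords: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Arc-length coordinate of each point's nearest position on a polyline."""
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d2 = np.full(len(coords), np.inf)
    best_lam = np.zeros(len(coords))
    for i in range(len(seg)):
        v = seg[i]
        t = np.clip((coords - pts[i]) @ v / (seg_len[i] ** 2), 0.0, 1.0)
        proj = pts[i] + t[:, None] * v
        d2 = np.einsum("ij,ij->i", coords - proj, coords - proj)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_lam[closer] = cum[i] + t[closer] * seg_len[i]
    return best_lam


def _interpolate_at(pts: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent of a polyline at arc-length lam."""
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    i = int(np.clip(np.searchsorted(cum, lam) - 1, 0, len(seg) - 1))
    t = (lam - cum[i]) / seg_len[i]
    point = pts[i] + t * seg[i]
    tangent = seg[i] / seg_len[i]
    return point, tangent


def mid_section_roi(
    volume: VoxelVolume,
    polyline,
    fraction: float = 0.10,
    margin: float = 0.05,
) -> tuple[VoxelVolume, dict]:
    """Material voxels within ±fraction/2 of the polyline's arc-length midpoint.

    Returns the cropped binary subvolume and a section frame: the midpoint,
    the local unit tangent there (the section-plane normal) and the ROI's
    arc-length window.  The frame also carries an axially *extended* copy of
    the ROI (``margin`` extra arc-length fraction per side) together with the
    core-window mask inside it; envelope-based statistics use the extended
    context so that the open venom canal at the slab's cut ends does not bias
    the closed envelope, while counting only core voxels.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    pts = polyline.points if isinstance(polyline, Polyline) else _as_polyline(polyline)
    total = fang_length(pts)
    mid = total / 2.0
    half = fraction * total / 2.0
    ext = half + margin * total

    mask = volume.material_mask()
    coords = volume.voxel_centers(mask)
    lam = _arc_length_projection(coords, pts)
    in_core = np.abs(lam - mid) <= half
    in_ext = np.abs(lam - mid) <= ext
    if not in_core.any():
        raise ValueError("empty mid-section ROI")

    all_idx = np.argwhere(mask)

    def _crop(sel):
        idx = all_idx[sel]
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        sub = np.zeros(hi - lo, dtype=np.uint8)
        sub[tuple((idx - lo).T)] = 1
        return VoxelVolume(data=sub, voxel_size=volume.voxel_size,
                           origin=volume.origin + lo * volume.voxel_size), lo

    roi, _ = _crop(in_core)
    extended, ext_lo = _crop(in_ext)
    core_in_ext = np.zeros(extended.shape, dtype=bool)
    core_in_ext[tuple((all_idx[in_core] - ext_lo).T)] = True

    # arc-length coordinate of every voxel of the extended crop (material or
    # not), so envelope statistics can be windowed axially
    grid_coords = extended.voxel_centers()
    lam_grid = _arc_length_projection(grid_coords, pts).reshape(extended.shape)

    midpoint, tangent = _interpolate_at(pts, mid)
    frame = {"midpoint": midpoint, "tangent": tangent,
             "window": (mid - half, mid + half), "total_length": total,
             "extended": extended, "core_in_extended": core_in_ext,
             "lambda_grid": lam_grid}
    return roi, frame


def mid_diameter(volume: VoxelVolume, polyline, n_bins: int = 72) -> float:
    """Outer diameter of the fang at its arc-length midpoint (μm).

    Takes the material voxels in a one-voxel slab normal to the polyline at
    the midpoint, projects them into the section plane, picks the outermost
    point in each angular bin around the section centroid (so internal
    cavities and a groove opening are ignored), and fits a circle to that
    outer outline with the same fitter used for curvature.
    """
    pts = polyline.points if isinstance(polyline, Polyline) else _as_polyline(polyline)
    mid = fang_length(pts) / 2.0
    midpoint, tangent = _interpolate_at(pts, mid)

    mask = volume.material_mask()
    coords = volume.voxel_centers(mask)
    axial = (coords - midpoint) @ tangent
    slab = np.abs(axial) <= 0.75 * volume.voxel_size
    if not slab.any():
        raise ValueError("empty cross-section at fang midpoint")
    # in-plane basis
    e1 = np.cross(tangent, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(tangent, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tangent, e1)
    rel = coords[slab] - midpoint
    uv = np.column_stack([rel @ e1, rel @ e2])

    ctr = uv.mean(axis=0)
    d = uv - ctr
    ang = np.arctan2(d[:, 1], d[:, 0])
    rad = np.hypot(d[:, 0], d[:, 1])
    bins = np.floor((ang + np.pi) / (2 * np.pi) * n_bins).astype(int).clip(0, n_bins - 1)
    outline = []
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            outline.append(uv[sel][np.argmax(rad[sel])])
    outline = np.asarray(outline)
    _, radius = _fit_circle_2d(outline)
    # outermost voxel centres sit half a voxel inside the true surface
    return 2.0 * radius + volume.voxel_size


# ---------------------------------------------------------------------------
# Local thickness and BV/TV
# ---------------------------------------------------------------------------

def local_thickness(mask: np.ndarray, voxel_size: float = 1.0,
                    step: float = 0.5) -> np.ndarray:
    """Local thickness map by the largest-inscribed-sphere definition.

    For each foreground element, the diameter of the largest sphere that fits
    entirely inside the foreground and contains it.  Computed by the
    distance-ridge sweep: candidate radii from the Euclidean distance
    transform are visited in descending order (quantised to ``step`` voxels)
    and each radius marks the region its spheres cover.  Works for 2D or 3D
    masks; returns thickness in the units of ``voxel_size``.
    """
    mask = np.asarray(mask).astype(bool)
    out = np.zeros(mask.shape, dtype=float)
    if not mask.any():
        return out
    dt = ndimage.distance_transform_edt(mask)
    rmax = dt.max()
    step = max(step, rmax / 40.0)  # cap the sweep at ~40 distance transforms
    radii = np.arange(np.floor(rmax / step) * step, 0.0, -step)
    remaining = mask.copy()
    for r in radii:
        centers = dt >= r
        if not centers.any():
            continue
        # dilation of the centre set by a ball of radius r
        covered = ndimage.distance_transform_edt(~centers) <= r
        newly = covered & remaining
        out[newly] = 2.0 * r
        remaining &= ~newly
        if not remaining.any():
            break
    # anything left (thin features below one step) gets its EDT diameter
    out[remaining] = 2.0 * dt[remaining]
    return out * voxel_size


def _ball_closing(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Morphological closing with a Euclidean ball, via distance transforms."""
    pad = int(np.ceil(radius_vox)) + 2
    padded = np.pad(mask, pad)
    dilated = ndimage.distance_transform_edt(~padded) <= radius_vox
    closed = ndimage.distance_transform_edt(dilated) > radius_vox
    closed |= padded  # closing is extensive; guard against discrete rounding
    sl = tuple(slice(pad, pad + n) for n in mask.shape)
    return closed[sl]


def _context_masks(roi: VoxelVolume, frame: dict | None):
    """(mask to analyse, mask of voxels to count) from a ROI and its frame."""
    if frame is not None and "extended" in frame:
        return frame["extended"].material_mask(), frame["core_in_extended"]
    mask = roi.material_mask()
    return mask, mask


def bvtv(roi: VoxelVolume, frame: dict | None = None,
         closing_factor: float = 1.5) -> float:
    """Material volume fraction of a section ROI.

    TV is the volume inside the closed outer envelope of the material mask:
    the mask is morphologically closed with a ball of radius
    ``closing_factor`` × the maximum local wall thickness (sealing groove and
    suture openings), then internal holes are filled.  BV is the material
    voxel count.  When the section frame carries the extended ROI context the
    envelope is built there and only core-window voxels are counted, so the
    open canal at the slab's cut ends does not recess the envelope.
    """
    mask, core = _context_masks(roi, frame)
    if not mask.any():
        raise ValueError("ROI contains no material")
    thick_vox = local_thickness(mask, 1.0)
    r_close = closing_factor * thick_vox.max()
    if r_close >= 4 * max(mask.shape):
        raise ValueError(
            f"closing radius {r_close:.1f} voxels is impractically large "
            f"for ROI extent {mask.shape}"
        )
    envelope = _ball_closing(mask, r_close)
    envelope = ndimage.binary_fill_holes(envelope)
    if frame is not None and "lambda_grid" in frame:
        # count only within the core arc-length window
        lo, hi = frame["window"]
        in_window = (frame["lambda_grid"] >= lo) & (frame["lambda_grid"] <= hi)
        tv = int((envelope & in_window).sum())
        bv = int((mask & in_window).sum())
    else:
        tv = int(envelope.sum())
        bv = int(mask.sum())
    logger.info("bvtv: BV=%d TV=%d closing_radius=%.1f vox", bv, tv, r_close)
    return float(bv / tv)


def wall_thickness(roi: VoxelVolume, frame: dict | None = None,
                   ) -> tuple[float, np.ndarray]:
    """Mean local wall thickness of a section ROI (μm) and the per-voxel
    thickness distribution over material voxels.

    With a section frame, thickness is evaluated on the axially extended ROI
    (so inscribed spheres are not clipped by the slab's cut faces) and
    averaged over the core-window voxels only.
    """
    mask, core = _context_masks(roi, frame)
    if not mask.any():
        raise ValueError("ROI contains no material")
    thick = local_thickness(mask, roi.voxel_size)
    values = thick[core]
    return float(values.mean()), values


# ---------------------------------------------------------------------------
# Composite report
# ---------------------------------------------------------------------------

def full_report(volume: VoxelVolume, polyline, skull_length: float,
                roi_fraction: float = 0.10) -> MorphometricsReport:
    """All five fang statistics for one specimen.

    The report's identities hold exactly by construction:
    ``relative_fang_length = fang_length / skull_length``,
    ``slender_ratio = fang_length / mid_diameter`` and
    ``size_corrected_wall_thickness = mean_wall_thickness / mid_diameter``.
    """
    length = fang_length(polyline)
    _, radius, angle = best_fit_circle(polyline)
    diameter = mid_diameter(volume, polyline)
    roi, frame = mid_section_roi(volume, polyline, fraction=roi_fraction)
    vf = bvtv(roi, frame)
    mean_wall, _ = wall_thickness(roi, frame)
    return MorphometricsReport(
        fang_length=length,
        skull_length=skull_length,
        relative_fang_length=relative_fang_length(length, skull_length),
        mid_diameter=diameter,
        slender_ratio=length / diameter,
        mean_wall_thickness=mean_wall,
        size_corrected_wall_thickness=mean_wall / diameter,
        bvtv=vf,
        segment_angle=angle,
        circle_radius=radius,
    )
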