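"""Parametric voxel fangs with known ground truth.

The generator sweeps a tapered circular cross-section along a circular arc
(the fang centreline) and carves the internal anatomy of a venom fang: a
venom canal running the full length and exiting at an orifice near the tip,
and a pulp cavity occupying the basal portion.  The three venom-delivery
phenotypes differ in the canal roof:

* ``open_groove``   — a wedge is removed along the canal, leaving an open
  surface channel;
* ``closed_nonfused`` — the canal is enclosed but a thin suture notch runs
  along the surface above it;
* ``closed_fused``  — the wall is intact.

Geometry is deterministic given the ground-truth parameters; the only
randomness in this module is the measurement noise of synthetic compression
records.  All lengths are micrometres.

Coordinate frame: the centreline arc lies in the x-y plane on a circle of
radius ``arc_radius`` centred at the origin; the base cross-section sits in
the plane ``y = 0`` and the arc advances counter-clockwise by
``segment_angle``.  The out-of-plane direction (z) is the normal of the
curvature plane.  The canal is offset toward the concave (inner-curve) side.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .voxel_io import VoxelVolume

__all__ = [
    "FangGroundTruth",
    "ResolutionError",
    "generate_fang",
    "phenotype_presets",
    "generate_compression_record",
    "reference_section_metrics",
]

PHENOTYPES = ("open_groove", "closed_nonfused", "closed_fused")

#: Canal (and pulp) centre offset, as a fraction of the local clearance
#: between the cavity radius and the outer radius.
OFFSET_FRACTION = 0.15
#: Pulp cavity occupies this basal fraction of the arc length.
PULP_EXTENT = 0.40
#: Arc-length fraction over which the canal closes beyond the orifice.
CANAL_CLOSE_SPAN = 0.05
#: Suture notch half-width as a fraction of the local outer radius.
SUTURE_HALFWIDTH_FRACTION = 0.08


class ResolutionError(ValueError):
    """Voxel size too coarse to resolve the thinnest wall (needs >= 2 voxels)."""


@dataclass(frozen=True)
class FangGroundTruth:
    """Generator parameters for one synthetic fang.

    ``canal_radius_fraction`` and ``pulp_radius_fraction`` are ratios of the
    cavity radius to the *local* outer radius, so cavities taper with the
    fang.  ``orifice_arc_fraction`` places the venom exit orifice that far
    (in arc length) from the tip.  ``skull_length`` is scalar metadata used
    only for the relative-fang-length statistic.
    """

    phenotype: str
    arc_radius: float
    segment_angle: float
    base_outer_radius: float
    tip_outer_radius: float
    canal_radius_fraction: float
    pulp_radius_fraction: float = 0.42
    groove_open_angle: float = 50.0
    suture_depth_fraction: float = 0.5
    orifice_arc_fraction: float = 0.1
    skull_length: float = 30000.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if not 0 < self.tip_outer_radius < self.base_outer_radius:
            raise ValueError("need 0 < tip_outer_radius < base_outer_radius")
        if not 0 < self.segment_angle < 360:
            raise ValueError("segment_angle must be in (0, 360) degrees")
        if not 0 <= self.canal_radius_fraction < 1:
            raise ValueError("canal_radius_fraction must be in [0, 1)")
        if not 0 < self.orifice_arc_fraction < 0.5:
            raise ValueError("orifice_arc_fraction must be in (0, 0.5)")

    @property
    def arc_length(self) -> float:
        """Centreline length: arc_radius * segment_angle in radians."""
        return self.arc_radius * np.radians(self.segment_angle)

    def outer_radius(self, s):
        """Local outer radius at arc-length fraction s (0 = base, 1 = tip)."""
        return self.base_outer_radius + (self.tip_outer_radius - self.base_outer_radius) * np.asarray(s)

    def min_wall_thickness(self) -> float:
        """Thinnest wall anywhere along the canal (at the orifice station)."""
        s = 1.0 - self.orifice_arc_fraction
        r_out = float(self.outer_radius(s))
        r_c = self.canal_radius_fraction * r_out
        offset = OFFSET_FRACTION * (r_out - r_c)
        return r_out - offset - r_c

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FangGroundTruth":
        return cls(**d)


# ---------------------------------------------------------------------------
# Cross-section membership (shared by the 3D generator and the 2D reference)
# ---------------------------------------------------------------------------

def _canal_taper(truth: FangGroundTruth, s):
    """Canal radius multiplier: 1 along the shaft, closing past the orifice."""
    s_orif = 1.0 - truth.orifice_arc_fraction
    return np.clip((s_orif + CANAL_CLOSE_SPAN - np.asarray(s)) / CANAL_CLOSE_SPAN, 0.0, 1.0)


def _section_material(truth: FangGroundTruth, s, rho, z):
    """Material membership in local cross-section coordinates.

    ``s`` is the arc-length fraction, ``rho`` the signed in-plane offset from
    the centreline (positive toward the convex/outer curve) and ``z`` the
    out-of-plane offset, all broadcastable arrays in μm.
    """
    s = np.asarray(s, dtype=float)
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    r_out = truth.outer_radius(s)
    material = rho * rho + z * z <= r_out * r_out

    # venom canal, offset toward the concave side (negative rho)
    f_c = truth.canal_radius_fraction
    if f_c > 0:
        r_c = f_c * r_out * _canal_taper(truth, s)
        d = OFFSET_FRACTION * (r_out - f_c * r_out)
        canal = (rho + d) ** 2 + z * z <= r_c * r_c
        material &= ~canal

        if truth.phenotype == "open_groove":
            # open the canal roof: wedge about the inward direction from the
            # canal centre, cutting through the concave wall
            half = np.radians(truth.groove_open_angle) / 2.0
            a = -(rho + d)  # inward component measured from the canal centre
            psi = np.arctan2(np.abs(z), a)
            material &= ~((psi <= half) & (r_c > 0))
        elif truth.phenotype == "closed_nonfused":
            # thin suture notch in the concave surface above the canal
            wall = r_out - d - r_c
            depth = truth.suture_depth_fraction * wall
            w = SUTURE_HALFWIDTH_FRACTION * r_out
            dist = np.sqrt(rho * rho + z * z)
            notch = (np.abs(z) <= w) & (rho < 0) & (dist >= r_out - depth) & (r_c > 0)
            material &= ~notch

    # pulp cavity in the basal portion, offset toward the convex side
    f_p = truth.pulp_radius_fraction
    if f_p > 0:
        ramp = np.clip(1.0 - s / PULP_EXTENT, 0.0, 1.0)
        r_p = f_p * r_out * ramp
        d_p = OFFSET_FRACTION * (r_out - r_p)
        pulp = (rho - d_p) ** 2 + z * z <= r_p * r_p
        material &= ~pulp

    return material


# ---------------------------------------------------------------------------
# 3D generation
# ---------------------------------------------------------------------------

def generate_fang(truth: FangGroundTruth, voxel_size: float) -> tuple[VoxelVolume, dict]:
    """Rasterise a fang and return the volume plus landmark ground truth.

    Landmarks: ``tip`` (centreline end point), ``orifice`` (surface point at
    the venom exit), ``base_point``/``base_normal`` (base cut plane),
    ``polyline`` (21 centreline points, base to tip), ``curvature_normal``
    (unit normal of the curvature plane) — all in the volume's physical frame.

    Raises :class:`ResolutionError` when the thinnest canal wall would span
    fewer than 2 voxels.
    """
    if truth.segment_angle <= 0:
        raise ValueError("degenerate arc: segment_angle must be positive")
    if truth.min_wall_thickness() < 2.0 * voxel_size:
        raise ResolutionError(
            f"minimum wall {truth.min_wall_thickness():.1f} um spans < 2 voxels "
            f"at voxel_size {voxel_size:g} um"
        )

    theta = np.radians(truth.segment_angle)
    R = truth.arc_radius
    r_max = truth.base_outer_radius

    # bounding box of the swept tube, padded by 2 voxels
    phis = np.linspace(0.0, theta, 256)
    arc = np.column_stack([R * np.cos(phis), R * np.sin(phis), np.zeros_like(phis)])
    lo = arc.min(axis=0) - (r_max + 2 * voxel_size)
    hi = arc.max(axis=0) + (r_max + 2 * voxel_size)
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    origin = lo

    ax = [origin[i] + np.arange(shape[i]) * voxel_size for i in range(3)]
    X = ax[0][:, None, None]
    Y = ax[1][None, :, None]
    Z = ax[2][None, None, :]

    phi = np.mod(np.arctan2(Y, X), 2.0 * np.pi)
    in_arc = phi <= theta
    s = phi / theta
    rho = np.sqrt(X * X + Y * Y) - R
    mask = _section_material(truth, s, rho, Z) & in_arc

    # carve the venom exit orifice: a hole through the concave wall at the
    # orifice station, of the local canal radius
    s_orif = 1.0 - truth.orifice_arc_fraction
    L = truth.arc_length
    r_out_o = float(truth.outer_radius(s_orif))
    r_orif = truth.canal_radius_fraction * r_out_o
    if r_orif > 0:
        lam = R * phi  # arc-length coordinate
        footprint = (lam - s_orif * L) ** 2 + Z * Z <= r_orif * r_orif
        mask &= ~(footprint & (rho < 0) & in_arc)

    volume = VoxelVolume(data=mask.astype(np.uint8), voxel_size=float(voxel_size), origin=origin)

    phi_poly = np.linspace(0.0, theta, 21)
    polyline = np.column_stack([
        R * np.cos(phi_poly), R * np.sin(phi_poly), np.zeros_like(phi_poly)
    ])
    phi_o = s_orif * theta
    landmarks = {
        "tip": np.array([R * np.cos(theta), R * np.sin(theta), 0.0]),
        "orifice": np.array([
            (R - r_out_o) * np.cos(phi_o), (R - r_out_o) * np.sin(phi_o), 0.0
        ]),
        "base_point": np.array([R, 0.0, 0.0]),
        "base_normal": np.array([0.0, 1.0, 0.0]),
        "curvature_normal": np.array([0.0, 0.0, 1.0]),
        "polyline": polyline,
        "phenotype": truth.phenotype,
    }
    return volume, landmarks


def voxel_size_for_arc_elements(truth: FangGroundTruth, n_arc: int) -> float:
    """Voxel size putting approximately ``n_arc`` voxels along the centreline."""
    return truth.arc_length / n_arc


# ---------------------------------------------------------------------------
# Phenotype presets
# ---------------------------------------------------------------------------

def phenotype_presets() -> list[FangGroundTruth]:
    """Two presets per phenotype, encoding the qualitative morphometric
    orderings observed across real fang types: closed-fused fangs are the
    most curved, most slender and relatively longest; open-groove fangs are
    the least curved and shortest but have the thickest (size-corrected)
    walls and the highest material volume fraction.
    """
    return [
        FangGroundTruth("open_groove", arc_radius=4000, segment_angle=65,
                        base_outer_radius=780, tip_outer_radius=520,
                        canal_radius_fraction=0.40, pulp_radius_fraction=0.42,
                        groove_open_angle=55, skull_length=30000,
                        name="open_groove_a"),
        FangGroundTruth("open_groove", arc_radius=3500, segment_angle=78,
                        base_outer_radius=800, tip_outer_radius=520,
                        canal_radius_fraction=0.42, pulp_radius_fraction=0.45,
                        groove_open_angle=50, skull_length=29000,
                        name="open_groove_b"),
        FangGroundTruth("closed_nonfused", arc_radius=4300, segment_angle=102,
                        base_outer_radius=950, tip_outer_radius=630,
                        canal_radius_fraction=0.50, pulp_radius_fraction=0.42,
                        suture_depth_fraction=0.50, skull_length=30000,
                        name="closed_nonfused_a"),
        FangGroundTruth("closed_nonfused", arc_radius=3800, segment_angle=112,
                        base_outer_radius=900, tip_outer_radius=590,
                        canal_radius_fraction=0.50, pulp_radius_fraction=0.45,
                        suture_depth_fraction=0.45, skull_length=28500,
                        name="closed_nonfused_b"),
        FangGroundTruth("closed_fused", arc_radius=2700, segment_angle=146,
                        base_outer_radius=700, tip_outer_radius=440,
                        canal_radius_fraction=0.55, pulp_radius_fraction=0.42,
                        skull_length=24000, name="closed_fused_a"),
        FangGroundTruth("closed_fused", arc_radius=2500, segment_angle=156,
                        base_outer_radius=680, tip_outer_radius=430,
                        canal_radius_fraction=0.55, pulp_radius_fraction=0.45,
                        skull_length=23000, name="closed_fused_b"),
    ]


def save_truths(truths: list[FangGroundTruth], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=1, sort_keys=True)


def load_truths(path: str) -> list[FangGroundTruth]:
    with open(path) as fh:
        return [FangGroundTruth.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# Reference cross-section metrics (fine 2D rasterization of the ground truth)
# ---------------------------------------------------------------------------

def reference_section_metrics(truth: FangGroundTruth, s: float = 0.5,
                              n: int = 1200) -> dict:
    """Ground-truth mid-section statistics from a fine 2D rasterization.

    Rasterises the analytic cross-section at arc-length fraction ``s`` on an
    ``n``×``n`` grid.  BV/TV uses the full outer disc as the total-volume
    envelope (the canal — and the groove opening — count as part of TV).
    Mean wall thickness uses the same largest-inscribed-sphere definition as
    the measurement pipeline, evaluated in-plane at fine resolution.
    """
    from .morphometrics import local_thickness

    r_out = float(truth.outer_radius(s))
    h = 2.0 * r_out * 1.02 / n
    coords = (np.arange(n) - (n - 1) / 2.0) * h
    rho, z = np.meshgrid(coords, coords, indexing="ij")
    material = _section_material(truth, np.full_like(rho, float(s)), rho, z)
    envelope = rho * rho + z * z <= r_out * r_out
    bvtv = float(material.sum() / envelope.sum())
    thick = local_thickness(material, h)
    mean_wall = float(thick[material].mean()) if material.any() else 0.0
    return {
        "bvtv": bvtv,
        "mean_wall_thickness": mean_wall,
        "outer_radius": r_out,
        "outer_diameter": 2.0 * r_out,
    }


# ---------------------------------------------------------------------------
# Synthetic compression records
# ---------------------------------------------------------------------------

def generate_compression_record(
    E_eff: float,
    yield_stress: float,
    area: float,
    length: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 600,
) -> np.ndarray:
    """Synthetic load–displacement record of a fang compression test.

    Emulates the shape of a dried-fang compression curve: a linear loading
    ramp of structural stiffness ``E_eff * area / length``, a smooth
    exponential roll-over to the yield plateau at ``yield_stress * area``,
    and a linear post-yield load drop.  Additive Gaussian noise of standard
    deviation ``noise_sd`` (newtons) is applied to the load channel.

    Parameters are structural: ``E_eff`` (Pa) is the effective modulus of the
    whole fang including cavities, ``area`` (μm²) the cross-section used for
    the stress conversion, ``length`` (μm) the gauge length.

    Returns an (n_points, 2) array: displacement (μm), load (N).
    """
    if min(E_eff, yield_stress, area, length) <= 0:
        raise ValueError("E_eff, yield_stress, area and length must be positive")
    eps_y = yield_stress / E_eff
    eps_end = 2.2 * eps_y
    strain = np.linspace(0.0, eps_end, n_points)

    roll_amp = 0.05              # roll-over spans the last 5% below the plateau
    eps_1 = (1.0 - roll_amp) * eps_y   # proportional limit of the synthetic curve
    eps_p = 1.5 * eps_y          # onset of the post-yield drop
    stress = np.where(strain <= eps_1, E_eff * strain, 0.0)
    roll = strain > eps_1
    # exponential roll-over: continuous value and slope at eps_1, asymptote
    # at the yield plateau
    stress = np.where(
        roll,
        yield_stress * (1.0 - roll_amp
                        * np.exp(-(E_eff / (roll_amp * yield_stress)) * (strain - eps_1))),
        stress,
    )
    drop = strain > eps_p
    stress = np.where(drop, stress - 0.3 * E_eff * (strain - eps_p), stress)
    stress = np.maximum(stress, 0.0)

    load = stress * area * 1e-12  # Pa * um^2 -> N
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        load = load + rng.normal(0.0, noise_sd, size=load.shape)
    displacement = strain * length
    return np.column_stack([displacement, load])
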