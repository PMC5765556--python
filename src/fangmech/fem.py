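"""Voxel-based static linear elasticity ("FEM without meshing").

Every material voxel of a binary volume becomes one 8-node hexahedral element
with trilinear displacement interpolation; the isotropic linear-elastic
element stiffness is integrated with 2x2x2 Gauss quadrature and assembled
into a sparse symmetric system.  The fang is held fixed at its base and a
point-load of nominal magnitude (5 N by default) is distributed over the
exposed surface nodes of a tip region — either parallel to the tip axis (the
direction from the venom exit orifice toward the tip) or laterally, at 90
degrees, along the normal of the fang's curvature plane.

Stress is recovered at element centroids; the summary statistic is the mean
of the top decile of per-element Von Mises values, which deliberately smooths
out hotspots at sharp voxel corners and characterises the bulk stress level
of the morphology.

Units: volumes are in micrometres, material moduli in pascal, loads in
newton.  Internally the solve runs in SI (metres); displacements are reported
in micrometres and stresses in pascal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import cg, splu, LinearOperator

from .voxel_io import VoxelVolume

logger = logging.getLogger("fangmech")

__all__ = [
    "MaterialModel",
    "LoadCase",
    "RoiSpec",
    "FemResult",
    "StiffnessSystem",
    "ConnectivityError",
    "coarsen_volume",
    "build_rois",
    "assemble_system",
    "solve_static",
    "top_decile_stress",
    "effective_modulus",
    "run_load_pair",
]

#: Above this number of free DOFs the default solver switches from a sparse
#: direct factorisation to Jacobi-preconditioned conjugate gradients.
DIRECT_DOF_LIMIT = 40_000


class ConnectivityError(ValueError):
    """Load and fixed regions are not connected through material."""


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic linear-elastic material: Young's modulus (Pa), Poisson ratio."""

    youngs_modulus: float = 20e9
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not -1 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")

    def elasticity_matrix(self) -> np.ndarray:
        """6x6 constitutive matrix in Voigt order (xx, yy, zz, xy, yz, zx)."""
        E, nu = self.youngs_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


@dataclass(frozen=True)
class LoadCase:
    """A tip load: magnitude (N), unit direction, and mode tag."""

    magnitude: float
    direction: np.ndarray
    mode: str = "parallel"

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("load direction must be nonzero")
        object.__setattr__(self, "direction", d / n)


@dataclass
class RoiSpec:
    """Fixed (base) and loaded (tip) voxel sets plus the tip axis."""

    fixed_voxels: np.ndarray
    load_voxels: np.ndarray
    tip_axis: np.ndarray


@dataclass
class FemResult:
    """Solution of one static load case."""

    displacements: np.ndarray      # (n_active_nodes, 3), micrometres
    node_ids: np.ndarray           # grid node id per active node
    von_mises: np.ndarray          # per element, Pa
    top_decile_stress: float       # Pa
    max_displacement: float        # micrometres
    diagnostics: dict = field(default_factory=dict)
    effective_modulus: float | None = None


@dataclass
class StiffnessSystem:
    """Assembled (unconstrained) global stiffness with its grid bookkeeping."""

    K: csr_matrix                  # active DOFs, SI units
    elems: np.ndarray              # (nel, 3) voxel indices
    edof: np.ndarray               # (nel, 24) active DOF indices
    active_nodes: np.ndarray       # grid node ids of active nodes
    node_coords: np.ndarray        # (n_active, 3) physical coords, micrometres
    shape: tuple                   # voxel grid shape
    volume: VoxelVolume            # the (possibly coarsened) binary volume
    material: MaterialModel
    B0: np.ndarray                 # centroid strain-displacement matrix (SI)
    D: np.ndarray                  # constitutive matrix


# ---------------------------------------------------------------------------
# Element matrices
# ---------------------------------------------------------------------------

# local corner offsets; node a of element (i,j,k) is grid node (i,j,k)+_OFFSETS[a]
_OFFSETS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
])
_XI = 2.0 * _OFFSETS - 1.0  # natural coordinates of the corners


def _shape_gradients(xi: np.ndarray, h: float) -> np.ndarray:
    """(8, 3) physical gradients dN_a/dx at natural point xi, cube edge h."""
    g = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        g[a, 0] = xa * (1 + ya * xi[1]) * (1 + za * xi[2]) / 8.0
        g[a, 1] = ya * (1 + xa * xi[0]) * (1 + za * xi[2]) / 8.0
        g[a, 2] = za * (1 + xa * xi[0]) * (1 + ya * xi[1]) / 8.0
    return g * (2.0 / h)


def _b_matrix(grad: np.ndarray) -> np.ndarray:
    """(6, 24) strain-displacement matrix from shape gradients."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def hex8_stiffness(material: MaterialModel, h: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Element stiffness (24x24), centroid B (6x24) and D for edge length h (m)."""
    D = material.elasticity_matrix()
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    detJ = (h / 2.0) ** 3
    KE = np.zeros((24, 24))
    for xi in gp:
        for eta in gp:
            for zeta in gp:
                B = _b_matrix(_shape_gradients(np.array([xi, eta, zeta]), h))
                KE += B.T @ D @ B * detJ
    B0 = _b_matrix(_shape_gradients(np.zeros(3), h))
    return KE, B0, D


# ---------------------------------------------------------------------------
# Grid bookkeeping
# ---------------------------------------------------------------------------

def coarsen_volume(volume: VoxelVolume, factor: int) -> VoxelVolume:
    """Downsample a binary volume by majority rule over factor³ blocks."""
    if factor == 1:
        return volume
    mask = volume.material_mask()
    pad = [(0, (-n) % factor) for n in mask.shape]
    padded = np.pad(mask, pad)
    s = padded.shape
    blocks = padded.reshape(s[0] // factor, factor, s[1] // factor, factor,
                            s[2] // factor, factor)
    frac = blocks.mean(axis=(1, 3, 5))
    coarse = (frac >= 0.5).astype(np.uint8)
    origin = volume.origin + (factor - 1) / 2.0 * volume.voxel_size
    return VoxelVolume(data=coarse, voxel_size=volume.voxel_size * factor,
                       origin=origin)


def _node_ids(elems: np.ndarray, shape: tuple) -> np.ndarray:
    """(nel, 8) grid node ids for elements given the voxel grid shape."""
    ny1, nz1 = shape[1] + 1, shape[2] + 1
    corners = elems[:, None, :] + _OFFSETS[None, :, :]
    return (corners[..., 0] * ny1 + corners[..., 1]) * nz1 + corners[..., 2]


def build_rois(volume: VoxelVolume, tip: np.ndarray, orifice: np.ndarray,
               base_point: np.ndarray, base_normal: np.ndarray,
               n_base_layers: int = 3) -> RoiSpec:
    """Fixed-base and loaded-tip voxel sets.

    The load region contains the material voxels within half the tip-to-
    orifice distance of the tip point; the fixed region contains the material
    voxels within ``n_base_layers`` voxel layers of the base plane.  The tip
    axis is the unit vector from the orifice toward the tip.
    """
    tip = np.asarray(tip, float)
    orifice = np.asarray(orifice, float)
    span = np.linalg.norm(tip - orifice)
    if span == 0:
        raise ValueError("tip and orifice coincide: tip axis undefined")
    tip_axis = (tip - orifice) / span

    mask = volume.material_mask()
    coords = volume.voxel_centers(mask)
    idx = np.argwhere(mask)

    load_sel = np.linalg.norm(coords - tip, axis=1) <= 0.5 * span
    n = np.asarray(base_normal, float)
    n = n / np.linalg.norm(n)
    fixed_sel = np.abs((coords - np.asarray(base_point, float)) @ n) \
        <= n_base_layers * volume.voxel_size

    load_mask = np.zeros(mask.shape, bool)
    fixed_mask = np.zeros(mask.shape, bool)
    load_mask[tuple(idx[load_sel].T)] = True
    fixed_mask[tuple(idx[fixed_sel].T)] = True
    if not load_mask.any() or not fixed_mask.any():
        raise ValueError("empty load or fixed ROI")
    if (load_mask & fixed_mask).any():
        raise ValueError("load and fixed ROIs overlap")
    return RoiSpec(fixed_voxels=fixed_mask, load_voxels=load_mask, tip_axis=tip_axis)


def assemble_system(volume: VoxelVolume, material: MaterialModel,
                    coarsen: int = 1) -> StiffnessSystem:
    """Assemble the global stiffness over all material voxels.

    With ``coarsen > 1`` the grid is first downsampled by majority rule
    (mirroring a simulation cell size larger than the scan voxel).  The
    returned system is unconstrained — symmetric positive semidefinite with
    the rigid-body modes in its nullspace.
    """
    if coarsen < 1:
        raise ValueError("coarsen must be >= 1")
    volume = coarsen_volume(volume, coarsen)
    mask = volume.material_mask()
    if not mask.any():
        raise ValueError("no material voxels to assemble")

    h = volume.voxel_size * 1e-6  # metres
    KE, B0, D = hex8_stiffness(material, h)

    elems = np.argwhere(mask)
    nel = len(elems)
    nodes = _node_ids(elems, mask.shape)  # (nel, 8)

    active, inverse = np.unique(nodes, return_inverse=True)
    local_nodes = inverse.reshape(nel, 8)
    edof = (3 * local_nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(nel, 24)

    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    data = np.tile(KE.ravel(), nel)
    ndof = 3 * len(active)
    K = coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()

    ny1, nz1 = mask.shape[1] + 1, mask.shape[2] + 1
    gi = active // (ny1 * nz1)
    gj = (active // nz1) % ny1
    gk = active % nz1
    node_coords = volume.origin - 0.5 * volume.voxel_size \
        + np.column_stack([gi, gj, gk]) * volume.voxel_size

    logger.info("assembled system: %d elements, %d nodes, %d dofs",
                nel, len(active), ndof)
    return StiffnessSystem(K=K, elems=elems, edof=edof, active_nodes=active,
                           node_coords=node_coords, shape=mask.shape,
                           volume=volume, material=material, B0=B0, D=D)


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------

def _exterior_node_mask(mask: np.ndarray) -> np.ndarray:
    """Boolean over grid nodes: node touches at least one non-material cell."""
    ny1, nz1 = mask.shape[1] + 1, mask.shape[2] + 1
    # count material cells incident to each node
    counts = np.zeros((mask.shape[0] + 1, ny1, nz1), dtype=np.int8)
    for di, dj, dk in _OFFSETS:
        counts[di:di + mask.shape[0], dj:dj + mask.shape[1], dk:dk + mask.shape[2]] += mask
    return counts < 8


def _check_connectivity(mask: np.ndarray, rois: RoiSpec) -> None:
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    load_labels = set(np.unique(labels[rois.load_voxels]))
    fixed_labels = set(np.unique(labels[rois.fixed_voxels]))
    if not (load_labels & fixed_labels):
        raise ConnectivityError("load and fixed regions lie in disconnected material")


_FACE_NEIGHBORS = np.array([
    [-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1],
])
# local corner indices of each element face, keyed like _FACE_NEIGHBORS
_FACE_CORNERS = {
    0: (0, 3, 7, 4), 1: (1, 2, 6, 5),
    2: (0, 1, 5, 4), 3: (3, 2, 6, 7),
    4: (0, 1, 2, 3), 5: (4, 5, 6, 7),
}


def _face_load_weights(mask: np.ndarray, load_elem_idx: np.ndarray,
                       local_nodes: np.ndarray, n_active: int,
                       direction: np.ndarray) -> np.ndarray:
    """Area-weighted traction: node weights from the exposed faces of the
    load elements that oppose the load direction."""
    weights = np.zeros(n_active)
    elems = load_elem_idx
    for fi, dn in enumerate(_FACE_NEIGHBORS):
        if np.dot(dn, direction) >= 0:
            continue  # face must be pushed against (outward normal opposes load)
        nbr = elems + dn
        inside = np.all((nbr >= 0) & (nbr < np.array(mask.shape)), axis=1)
        exposed = np.ones(len(elems), bool)
        exposed[inside] = ~mask[tuple(nbr[inside].T)]
        if not exposed.any():
            continue
        for corner in _FACE_CORNERS[fi]:
            np.add.at(weights, local_nodes[exposed, corner], 0.25)
    return weights


def solve_static(system: StiffnessSystem, rois: RoiSpec, load: LoadCase,
                 tol: float = 1e-8, max_iter: int = 2000,
                 method: str = "auto", load_application: str = "nodes",
                 ) -> FemResult:
    """Solve one constrained static load case.

    All displacement components of the fixed region's nodes are zero.  With
    ``load_application="nodes"`` the total load is distributed equally over
    the exposed surface nodes of the load region; with ``"face"`` it is
    applied as an area-weighted traction over the exposed element faces that
    oppose the load direction.  ``method`` is ``"direct"`` (sparse LU),
    ``"cg"`` (Jacobi-preconditioned conjugate gradients, relative tolerance
    ``tol``, at most ``max_iter`` iterations) or ``"auto"``.
    """
    mask = system.volume.material_mask()
    _check_connectivity(mask, rois)

    # fixed DOFs: every node of every fixed-region element
    fixed_elems = rois.fixed_voxels[tuple(system.elems.T)]
    load_elems = rois.load_voxels[tuple(system.elems.T)]
    if not fixed_elems.any() or not load_elems.any():
        raise ValueError("ROIs select no elements on this grid")

    n_active = len(system.active_nodes)
    local_nodes = system.edof[:, ::3] // 3
    fixed_nodes = np.zeros(n_active, bool)
    fixed_nodes[local_nodes[fixed_elems].ravel()] = True

    if load_application == "face":
        weights = _face_load_weights(mask, system.elems[load_elems],
                                     local_nodes[load_elems], n_active,
                                     load.direction)
        weights[fixed_nodes] = 0.0
        if weights.sum() == 0:
            raise ValueError("load region exposes no faces opposing the load")
        load_nodes = weights > 0
        node_force = load.magnitude * weights / weights.sum()
    elif load_application == "nodes":
        exterior = _exterior_node_mask(mask).ravel()
        load_nodes = np.zeros(n_active, bool)
        load_nodes[local_nodes[load_elems].ravel()] = True
        load_nodes &= exterior[system.active_nodes]
        load_nodes &= ~fixed_nodes
        if not load_nodes.any():
            raise ValueError("load region has no exposed surface nodes")
        node_force = np.zeros(n_active)
        node_force[load_nodes] = load.magnitude / load_nodes.sum()
    else:
        raise ValueError(f"unknown load_application {load_application!r}")

    ndof = 3 * n_active
    f = (node_force[:, None] * load.direction[None, :]).ravel()

    free = np.ones(ndof, bool)
    free[np.repeat(np.where(fixed_nodes)[0] * 3, 3) + np.tile(np.arange(3), fixed_nodes.sum())] = False

    K = system.K
    Kff = K[free][:, free].tocsr()
    ff = f[free]
    u = np.zeros(ndof)
    nf = int(free.sum())
    fnorm = np.linalg.norm(ff)

    if method == "auto":
        method = "direct" if nf <= DIRECT_DOF_LIMIT else "cg"
    iterations = 0
    residual_history: list = []
    if fnorm == 0.0:
        uf = np.zeros(nf)
        method = "trivial"
    elif method == "direct":
        lu = splu(Kff.tocsc())
        uf = lu.solve(ff)
    elif method == "cg":
        dinv = 1.0 / Kff.diagonal()
        M = LinearOperator((nf, nf), matvec=lambda x: dinv * x)
        it_count = [0]

        def cb(xk):
            it_count[0] += 1
            if it_count[0] % 50 == 0:  # sampled residual trace for the run log
                r = np.linalg.norm(Kff @ xk - ff) / fnorm
                residual_history.append((it_count[0], float(r)))
                logger.debug("cg iteration %d: relative residual %.3e", it_count[0], r)

        uf, info = cg(Kff, ff, rtol=tol, maxiter=max_iter, M=M, callback=cb)
        iterations = it_count[0]
        if info > 0:
            logger.warning("CG stopped at %d iterations without reaching rtol=%g", info, tol)
    else:
        raise ValueError(f"unknown solver method {method!r}")
    u[free] = uf

    residual = float(np.linalg.norm(Kff @ uf - ff) / fnorm) if fnorm else 0.0

    # element centroid stress and Von Mises
    ue = u[system.edof]                        # (nel, 24)
    sigma = ue @ (system.D @ system.B0).T      # (nel, 6)
    sxx, syy, szz, sxy, syz, szx = sigma.T
    vm = np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                 + 3.0 * (sxy ** 2 + syz ** 2 + szx ** 2))

    # reaction forces for the global force balance diagnostic
    r = K @ u - f
    fixed_dofs = ~free
    reactions = r[fixed_dofs].reshape(-1, 3).sum(axis=0)

    disp = u.reshape(-1, 3) * 1e6  # metres -> micrometres
    result = FemResult(
        displacements=disp,
        node_ids=system.active_nodes,
        von_mises=vm,
        top_decile_stress=top_decile_stress(vm),
        max_displacement=float(np.linalg.norm(disp, axis=1).max()),
        diagnostics={
            "method": method,
            "iterations": iterations,
            "residual": residual,
            "residual_history": residual_history,
            "n_dofs": nf,
            "n_elements": len(system.elems),
            "reaction_force": reactions,
            "applied_force": load.magnitude * load.direction,
            "load_nodes": int(load_nodes.sum()),
            "load_node_mask": load_nodes,
            "max_von_mises": float(vm.max()),
        },
    )
    logger.info("solved %s load: method=%s residual=%.2e top-decile=%.3g Pa",
                load.mode, method, residual, result.top_decile_stress)
    return result


def top_decile_stress(von_mises: np.ndarray, percentile: float = 10.0) -> float:
    """Mean of the highest ``percentile`` % of element Von Mises values.

    The element count is rounded up and ties at the threshold value are
    included, so the statistic is insensitive to ordering among equal values.
    """
    vm = np.asarray(von_mises, float).ravel()
    if vm.size == 0:
        raise ValueError("empty stress field")
    n = int(np.ceil(vm.size * percentile / 100.0))
    part = np.sort(vm)[::-1]
    threshold = part[n - 1]
    top = vm[vm >= threshold]
    return float(top.mean())


def effective_modulus(result: FemResult, load: LoadCase,
                      envelope_area: float, length: float) -> float:
    """Apparent Young's modulus of the whole structure from an axial solve.

    ``E_eff = (F / envelope_area) / (delta / length)`` with ``delta`` the
    mean displacement of the loaded nodes along the load direction,
    ``envelope_area`` the outer cross-section area at mid-fang (μm²) and
    ``length`` the fang length (μm).
    """
    load_nodes = result.diagnostics.get("load_node_mask")
    if load_nodes is None:
        raise ValueError("result carries no load-node bookkeeping")
    delta = result.displacements[load_nodes] @ load.direction
    delta_axial = abs(float(delta.mean()))
    if delta_axial == 0:
        raise ValueError("zero axial displacement: cannot form a modulus")
    stress = load.magnitude / (envelope_area * 1e-12)      # Pa
    strain = delta_axial / length                          # both micrometres
    return stress / strain


def run_load_pair(volume: VoxelVolume, landmarks: dict, material: MaterialModel,
                  magnitude: float = 5.0, coarsen: int = 1,
                  percentile: float = 10.0, tol: float = 1e-8,
                  max_iter: int = 2000, method: str = "auto",
                  ) -> tuple[FemResult, FemResult, float]:
    """Parallel and lateral (90°) tip-load simulations of one fang.

    The parallel load acts along the tip axis (compressing the tip toward
    the base); the lateral load acts along the curvature-plane normal, i.e.
    rotated 90° out of the fang's curvature plane.  Returns both results and
    the ratio of lateral to parallel top-decile Von Mises stress.
    """
    vol = coarsen_volume(volume, coarsen)
    rois = build_rois(vol, landmarks["tip"], landmarks["orifice"],
                      landmarks["base_point"], landmarks["base_normal"])
    system = assemble_system(vol, material)

    normal = np.asarray(landmarks.get("curvature_normal", [0.0, 0.0, 1.0]), float)
    normal = normal - (normal @ rois.tip_axis) * rois.tip_axis
    normal /= np.linalg.norm(normal)

    par = LoadCase(magnitude=magnitude, direction=-rois.tip_axis, mode="parallel")
    lat = LoadCase(magnitude=magnitude, direction=normal, mode="lateral")
    res_par = solve_static(system, rois, par, tol=tol, max_iter=max_iter, method=method)
    res_lat = solve_static(system, rois, lat, tol=tol, max_iter=max_iter, method=method)
    sp = top_decile_stress(res_par.von_mises, percentile)
    sl = top_decile_stress(res_lat.von_mises, percentile)
    ratio = sl / sp
    res_par.diagnostics["max_ratio"] = res_lat.diagnostics["max_von_mises"] / \
        res_par.diagnostics["max_von_mises"]
    logger.info("load pair: parallel=%.3g Pa lateral=%.3g Pa ratio=%.2f", sp, sl, ratio)
    return res_par, res_lat, ratio
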