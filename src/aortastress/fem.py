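"""Linear-elastic trilinear-hexahedron FEM and the forward penalty stress solve.

The forward penalty method exploits the approximate static determinacy of the
pressurized aortic wall: transmurally averaged stress is fixed by equilibrium
and geometry alone, so solving the image-derived geometry with an artificially
stiff material (default Young's modulus 5e5 kPa) yields the wall stress
without patient-specific material properties, while keeping displacements
negligibly small (order 1e-3 mm).

Element technology: 8-node trilinear hexahedra with selective reduced
integration (mean-dilatation B-bar) so that the near-incompressible default
Poisson ratio 0.49 does not lock.  Pressure is applied as a dead (non-follower)
load on the luminal faces; both end rings are axially constrained and two
in-plane point constraints remove the remaining rigid-body modes.  The sparse
system is solved by direct factorization (deterministic at desk scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hemodynamics import LumenPressureField
from .mesh import SET_FLAP, SET_THROMBUS, HexMesh  # noqa: F401

__all__ = [
    "SolverConfig",
    "DisplacementField",
    "StressField",
    "solve_penalty",
    "corner_jacobian_dets",
]

# natural coordinates of the 8 hex corners
_CORNERS = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)
_GP = _CORNERS / np.sqrt(3.0)  # 2x2x2 Gauss points (weight 1 each)


@dataclass
class SolverConfig:
    """Material and solver controls for the penalty stress computation."""

    e_wall_kpa: float = 5.0e5          # artificially stiff penalty modulus
    e_thrombus_kpa: float | None = None  # None -> ratio-locked at e_wall / 20
    e_flap_kpa: float | None = None    # None -> same as the wall modulus
    poisson: float = 0.49
    tie_stiffness_factor: float = 10.0  # flap tie springs, x (E * element size)
    ratio_locked: bool = True
    #: "tethered" adds a stiff penalty on each ring's centroid in-plane motion,
    #: emulating perivascular/branch-vessel tethering: without it the arch acts
    #: as a pressurized elbow and bends the long descending limb as a beam,
    #: which is an artifact of meshing no branch vessels.  Radial expansion
    #: (zero centroid motion) is unaffected.  "ends-only" keeps just the
    #: end-ring constraints.  "clamped" additionally fixes all three DOFs on
    #: both end rings (with the tether): the compliant-wall coupled iteration
    #: needs this to suppress an end-flare feedback that repeated linear
    #: solves cannot stiffen against; end effects decay within ~sqrt(r t) of
    #: the rings.
    bc_mode: str = "tethered"
    tether_stiffness_factor: float = 100.0

    def __post_init__(self) -> None:
        if self.e_wall_kpa <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 <= self.poisson < 0.5):
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")

    def thrombus_modulus(self) -> float:
        if self.ratio_locked or self.e_thrombus_kpa is None:
            return self.e_wall_kpa / 20.0  # wall:thrombus stiffness ratio 20
        return self.e_thrombus_kpa


@dataclass
class DisplacementField:
    """Per-node displacement vectors in mm."""

    values: np.ndarray  # (n_nodes, 3)

    @property
    def max_magnitude(self) -> float:
        return float(np.linalg.norm(self.values, axis=1).max())


@dataclass
class StressField:
    """Element Cauchy stress and the transmurally averaged principal stress.

    ``tensors`` are element-centroid Cauchy stress tensors (kPa),
    ``max_principal`` the largest principal stress per element, and
    ``transmural_grid`` the wall max-principal stress averaged through the 4
    layers and onto the structured surface node grid (flap and thrombus
    excluded).  ``transmural_quads`` keeps the per-surface-quad averages used
    for field comparisons.
    """

    tensors: np.ndarray            # (n_elems, 3, 3) kPa
    max_principal: np.ndarray      # (n_elems,) kPa
    transmural_grid: np.ndarray    # (n_axial, n_circ) kPa
    transmural_quads: np.ndarray   # (n_axial - 1, n_circ) kPa (NaN off-wall)
    grid_shape: tuple[int, int]


class ConstraintError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# element kinematics
# ---------------------------------------------------------------------------

def _shape_gradients_natural(xi: np.ndarray) -> np.ndarray:
    """dN/d(xi) at one natural point, shape (8, 3)."""
    g = np.empty((8, 3))
    for i, (a, b, c) in enumerate(_CORNERS):
        g[i, 0] = a * (1 + b * xi[1]) * (1 + c * xi[2]) / 8.0
        g[i, 1] = (1 + a * xi[0]) * b * (1 + c * xi[2]) / 8.0
        g[i, 2] = (1 + a * xi[0]) * (1 + b * xi[1]) * c / 8.0
    return g


def _grads_and_det(coords: np.ndarray, xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Physical shape gradients and det J for all elements at one point.

    coords: (nel, 8, 3) -> grads (nel, 8, 3), det (nel,)
    """
    gn = _shape_gradients_natural(xi)              # (8, 3)
    jac = np.einsum("nia,ib->nab", coords, gn)     # dx/dxi, note transpose layout
    det = np.linalg.det(jac)
    inv = np.linalg.inv(jac)
    grads = np.einsum("ib,nba->nia", gn, inv)
    return grads, det


def corner_jacobian_dets(coords: np.ndarray) -> np.ndarray:
    """det J at the 8 natural corners for each element, shape (nel, 8)."""
    out = np.empty((coords.shape[0], 8))
    for k, xi in enumerate(_CORNERS):
        gn = _shape_gradients_natural(xi)
        jac = np.einsum("nia,ib->nab", coords, gn)
        out[:, k] = np.linalg.det(jac)
    return out


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix, Voigt [xx,yy,zz,xy,yz,zx] (engineering shear).

    grads: (nel, 8, 3) -> B: (nel, 6, 24), dof order (n0x, n0y, n0z, n1x, ...).
    """
    nel = grads.shape[0]
    b = np.zeros((nel, 6, 24))
    gx, gy, gz = grads[:, :, 0], grads[:, :, 1], grads[:, :, 2]
    cols = np.arange(8)
    b[:, 0, cols * 3 + 0] = gx
    b[:, 1, cols * 3 + 1] = gy
    b[:, 2, cols * 3 + 2] = gz
    b[:, 3, cols * 3 + 0] = gy
    b[:, 3, cols * 3 + 1] = gx
    b[:, 4, cols * 3 + 1] = gz
    b[:, 4, cols * 3 + 2] = gy
    b[:, 5, cols * 3 + 0] = gz
    b[:, 5, cols * 3 + 2] = gx
    return b


def _material_matrices(e: np.ndarray, nu: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-element shear modulus and bulk modulus arrays."""
    mu = e / (2.0 * (1.0 + nu))
    kappa = e / (3.0 * (1.0 - 2.0 * nu))
    return mu, kappa


_M = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
_I6 = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
_DEV = _I6 - np.outer(_M, _M) / 3.0  # deviatoric projector (Voigt, eng. shear)


def _element_stiffness(coords: np.ndarray, e: np.ndarray, nu: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """B-bar element stiffness matrices.

    Returns (ke (nel, 24, 24), b_vol_bar (nel, 24), volume (nel,)).  The
    deviatoric part uses full 2x2x2 integration, the volumetric part the
    element-mean dilatation operator (selective reduced integration).
    """
    nel = coords.shape[0]
    mu, kappa = _material_matrices(e, nu)
    d_dev = 2.0 * _DEV  # x mu per element below

    ke = np.zeros((nel, 24, 24))
    b_vol = np.zeros((nel, 24))
    vol = np.zeros(nel)
    for gp in _GP:
        grads, det = _grads_and_det(coords, gp)
        b = _b_matrix(grads)
        tmp = np.einsum("nji,jk,nkl->nil", b, d_dev, b)
        ke += tmp * (mu * det)[:, None, None]
        # volumetric operator row: div u = sum_i grad(N_i) . u_i
        bv = np.zeros((nel, 24))
        bv[:, 0::3] = grads[:, :, 0]
        bv[:, 1::3] = grads[:, :, 1]
        bv[:, 2::3] = grads[:, :, 2]
        b_vol += bv * det[:, None]
        vol += det
    b_vol /= vol[:, None]
    ke += (kappa * vol)[:, None, None] * np.einsum("ni,nj->nij", b_vol, b_vol)
    return ke, b_vol, vol


def _geometric_stiffness(coords: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Initial-stress (geometric) element stiffness from a Cauchy stress state.

    K_g[i,j] = int grad(N_i) . sigma . grad(N_j) dV, expanded blockwise over
    the three displacement components.  With tensile membrane stress this is
    the stress-stiffening term that stabilizes thin walls in the coupled
    geometry-update iteration.
    """
    nel = coords.shape[0]
    kg_sc = np.zeros((nel, 8, 8))
    for gp in _GP:
        grads, det = _grads_and_det(coords, gp)
        kg_sc += np.einsum("nia,nab,njb->nij", grads, sigma, grads) * det[:, None, None]
    kg = np.zeros((nel, 24, 24))
    idx = np.arange(8)
    for d in range(3):
        kg[:, (idx * 3 + d)[:, None], (idx * 3 + d)[None, :]] = kg_sc
    return kg


def _assemble(
    mesh: HexMesh,
    config: SolverConfig,
    coords_nodes: np.ndarray,
    sigma_prestress: np.ndarray | None = None,
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Global stiffness with flap tie springs; also returns (b_vol_bar, e_elem)."""
    coords = coords_nodes[mesh.elems]
    e_elem = np.full(mesh.n_elems, config.e_wall_kpa)
    e_elem[mesh.elem_set == SET_THROMBUS] = config.thrombus_modulus()
    if config.e_flap_kpa is not None:
        e_elem[mesh.elem_set == SET_FLAP] = config.e_flap_kpa
    ke, b_vol, _ = _element_stiffness(coords, e_elem, config.poisson)
    if sigma_prestress is not None:
        ke = ke + _geometric_stiffness(coords, sigma_prestress)

    dof = (mesh.elems[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(mesh.n_elems, 24)
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()
    ndof = 3 * mesh.n_nodes
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    if mesh.tie_pairs.shape[0] > 0:
        kappa_tie = config.tie_stiffness_factor * config.e_wall_kpa * mesh.char_length
        i, j = mesh.tie_pairs[:, 0], mesh.tie_pairs[:, 1]
        rows_t, cols_t, vals_t = [], [], []
        for d in range(3):
            di, dj = 3 * i + d, 3 * j + d
            rows_t += [di, dj, di, dj]
            cols_t += [di, dj, dj, di]
            vals_t += [
                np.full(i.size, kappa_tie),
                np.full(i.size, kappa_tie),
                np.full(i.size, -kappa_tie),
                np.full(i.size, -kappa_tie),
            ]
        kt = sp.coo_matrix(
            (np.concatenate(vals_t), (np.concatenate(rows_t), np.concatenate(cols_t))),
            shape=(ndof, ndof),
        ).tocsr()
        k = k + kt

    if config.bc_mode in ("tethered", "clamped"):
        k = k + _tether_penalty(mesh, config)
    elif config.bc_mode != "ends-only":
        raise ValueError(f"unknown bc_mode {config.bc_mode!r}")
    return k, b_vol, e_elem


def _tether_penalty(mesh: HexMesh, config: SolverConfig) -> sp.csr_matrix:
    """Penalty on the in-plane (x, y) centroid displacement of every outer ring.

    Energy (kappa/2) * mean(u_x)^2 + (kappa/2) * mean(u_y)^2 per ring gives a
    rank-2 stiffness block (kappa/n^2) * 1 1^T on the ring's x and y DOFs.
    Scales with the wall modulus so the static-determinacy factor sweep stays
    an exact rescaling.
    """
    na, nc = mesh.grid_shape
    outer = np.arange(na * nc).reshape(na, nc)  # builder orders the outer sheet first
    kappa = config.tether_stiffness_factor * config.e_wall_kpa * mesh.char_length
    rows, cols, vals = [], [], []
    for a in range(na):
        ring = outer[a]
        for d in (0, 1):
            dofs = ring * 3 + d
            r, c = np.meshgrid(dofs, dofs, indexing="ij")
            rows.append(r.ravel())
            cols.append(c.ravel())
            vals.append(np.full(r.size, kappa / nc**2))
    ndof = 3 * mesh.n_nodes
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()


def _face_loads(mesh: HexMesh, pressure: LumenPressureField, coords_nodes: np.ndarray) -> np.ndarray:
    """Consistent nodal forces from luminal pressure (dead load).

    Each loaded face carries a uniform pressure (the mean of its grid-node
    values); with single-point integration every face node receives
    p * A / 4 along the inward (into-the-solid) direction.
    """
    na, nc = mesh.grid_shape
    f = np.zeros((mesh.n_nodes, 3))
    values = pressure.values

    tl_ring = np.array(
        [values[a][~pressure.fl_mask[a]].mean() if (~pressure.fl_mask[a]).any() else values[a].mean()
         for a in range(na)]
    )
    fl_all = values[pressure.fl_mask]
    fl_value = float(fl_all.mean()) if fl_all.size else float(values.mean())

    for name, faces in mesh.faces.items():
        if faces.shape[0] == 0:
            continue
        quad = mesh.face_quad[name]
        a, c = quad[:, 0], quad[:, 1]
        if name in ("tl_lumen", "fl_lumen", "thrombus_lumen"):
            c1 = (c + 1) % nc
            p = 0.25 * (values[a, c] + values[a, c1] + values[a + 1, c] + values[a + 1, c1])
        elif name == "flap_tl":
            p = 0.5 * (tl_ring[a] + tl_ring[np.minimum(a + 1, na - 1)])
        else:  # flap_fl
            p = np.full(faces.shape[0], fl_value)

        pts = coords_nodes[faces]
        # vector area of the (possibly warped) quad; normal points into the fluid
        area_vec = 0.5 * np.cross(pts[:, 2] - pts[:, 0], pts[:, 3] - pts[:, 1])
        force = -(p[:, None] * area_vec) / 4.0  # pressure pushes into the solid
        for corner in range(4):
            np.add.at(f, faces[:, corner], force)
    return f.ravel()


def _boundary_conditions(mesh: HexMesh, bc_mode: str = "tethered") -> np.ndarray:
    """Fixed DOF indices: axial (z) on both end rings + in-plane point constraints.

    The synthetic geometries are built with vertical end tangents, so the
    axial direction on both end rings is the global z axis.  Two extra point
    constraints on the proximal ring remove in-plane translation and the
    rotation about z.  In "clamped" mode both end rings are fixed in all
    three directions.
    """
    if bc_mode == "clamped":
        fixed = [
            mesh.proximal_nodes * 3, mesh.proximal_nodes * 3 + 1, mesh.proximal_nodes * 3 + 2,
            mesh.distal_nodes * 3, mesh.distal_nodes * 3 + 1, mesh.distal_nodes * 3 + 2,
        ]
        return np.unique(np.concatenate(fixed))
    fixed = [mesh.proximal_nodes * 3 + 2, mesh.distal_nodes * 3 + 2]
    n0 = int(mesh.proximal_nodes[0])
    fixed.append(np.array([3 * n0, 3 * n0 + 1]))
    ring = mesh.proximal_nodes
    half = ring[len(ring) // 2]
    fixed.append(np.array([3 * int(half) + 1]))
    return np.unique(np.concatenate(fixed))


def _solve_system(k: sp.csr_matrix, f: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    ndof = f.size
    # orphan DOFs (nodes referenced by no element, e.g. inside fenestration
    # holes) carry no stiffness; pin them so the factorization stays regular
    orphan = np.nonzero(k.diagonal() == 0.0)[0]
    if orphan.size:
        fixed = np.union1d(fixed, orphan)
    free = np.setdiff1d(np.arange(ndof), fixed, assume_unique=False)
    kff = k[free][:, free].tocsc()
    u = np.zeros(ndof)
    try:
        u[free] = spla.spsolve(kff, f[free])
    except RuntimeError as exc:  # singular factorization
        raise ConstraintError(f"singular system (insufficient constraints?): {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise ConstraintError("singular system: non-finite displacement solution")
    return u


def _recover_stress(
    mesh: HexMesh,
    coords_nodes: np.ndarray,
    u: np.ndarray,
    b_vol: np.ndarray,
    e_elem: np.ndarray,
    nu: float,
) -> StressField:
    """Element-centroid Cauchy stress with B-bar volumetric strain."""
    coords = coords_nodes[mesh.elems]
    ue = u.reshape(-1, 3)[mesh.elems].reshape(mesh.n_elems, 24)

    grads, _ = _grads_and_det(coords, np.zeros(3))
    b = _b_matrix(grads)
    eps = np.einsum("nij,nj->ni", b, ue)                      # Voigt, eng. shear
    tr_bar = np.einsum("ni,ni->n", b_vol, ue)                 # mean dilatation
    mu, kappa = _material_matrices(e_elem, nu)

    eps_dev = eps.copy()
    eps_dev[:, :3] -= eps[:, :3].mean(axis=1, keepdims=True)
    sig = np.empty((mesh.n_elems, 6))
    sig[:, :3] = 2.0 * mu[:, None] * eps_dev[:, :3] + (kappa * tr_bar)[:, None]
    sig[:, 3:] = mu[:, None] * eps[:, 3:]                     # tau = mu * gamma

    tensors = np.empty((mesh.n_elems, 3, 3))
    tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2] = sig[:, 0], sig[:, 1], sig[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = sig[:, 3]
    tensors[:, 1, 2] = tensors[:, 2, 1] = sig[:, 4]
    tensors[:, 0, 2] = tensors[:, 2, 0] = sig[:, 5]
    max_principal = np.linalg.eigvalsh(tensors)[:, -1]

    na, nc = mesh.grid_shape
    quads = np.full((na - 1, nc), np.nan)
    wall = mesh.wall_elem_mask()
    aq, cq = mesh.elem_quad[wall, 0], mesh.elem_quad[wall, 1]
    sums = np.zeros((na - 1, nc))
    counts = np.zeros((na - 1, nc))
    np.add.at(sums, (aq, cq), max_principal[wall])
    np.add.at(counts, (aq, cq), 1.0)
    has = counts > 0
    quads[has] = sums[has] / counts[has]

    # node grid: average the incident wall quads
    node_sum = np.zeros((na, nc))
    node_cnt = np.zeros((na, nc))
    qa, qc = np.nonzero(has)
    for da in (0, 1):
        for dc in (0, 1):
            np.add.at(node_sum, (qa + da, (qc + dc) % nc), quads[qa, qc])
            np.add.at(node_cnt, (qa + da, (qc + dc) % nc), 1.0)
    grid = np.where(node_cnt > 0, node_sum / np.maximum(node_cnt, 1), np.nan)

    return StressField(
        tensors=tensors,
        max_principal=max_principal,
        transmural_grid=grid,
        transmural_quads=quads,
        grid_shape=(na, nc),
    )


def solve_elastic(
    mesh: HexMesh,
    pressure: LumenPressureField,
    config: SolverConfig,
    coords_nodes: np.ndarray | None = None,
    sigma_prestress: np.ndarray | None = None,
) -> tuple[DisplacementField, StressField]:
    """One linear-elastic solve on the given (possibly deformed) coordinates.

    ``sigma_prestress`` (per-element Cauchy tensors) adds the initial-stress
    geometric stiffness — used by the coupled iteration.
    """
    if pressure.values.shape != mesh.grid_shape:
        raise ValueError(
            f"pressure grid {pressure.values.shape} does not match mesh grid {mesh.grid_shape}"
        )
    if coords_nodes is None:
        coords_nodes = mesh.nodes
    k, b_vol, e_elem = _assemble(mesh, config, coords_nodes, sigma_prestress)
    f = _face_loads(mesh, pressure, coords_nodes)
    fixed = _boundary_conditions(mesh, config.bc_mode)
    u = _solve_system(k, f, fixed)
    disp = DisplacementField(values=u.reshape(-1, 3))
    stress = _recover_stress(mesh, coords_nodes, u, b_vol, e_elem, config.poisson)
    return disp, stress


def solve_penalty(
    mesh: HexMesh,
    pressure: LumenPressureField,
    config: SolverConfig | None = None,
) -> tuple[DisplacementField, StressField]:
    """Forward penalty stress solve on the image-derived (baseline) geometry.

    Small-strain equilibrium with the artificially stiff wall; displacements
    should come out on the order of 1e-3 mm, making the computed stress the
    statically determinate wall stress of the loaded geometry.
    """
    if config is None:
        config = SolverConfig()
    return solve_elastic(mesh, pressure, config, coords_nodes=None)
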