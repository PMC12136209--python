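"""Layered hexahedral solid meshing of dissected-aorta surfaces.

The solid domain is built by extruding the outer-wall surface quads inward
along nodal normals into 4 layers of 8-node hexahedra: the true-lumen wall
spans 2 mm (0.5 mm/layer, the double-offset convention), the false-lumen wall
and the intimal flap span 1 mm (0.25 mm/layer).  Mural thrombus, when present,
is extruded further inward from the false-lumen luminal surface and shares
nodes with the wall (conforming).  The flap is its own 4-layer hex strip whose
edge node columns are tied to the wall luminal surface at the attachment lines
by stiff penalty springs (a node-to-node tie constraint).

Element and face bookkeeping retains the structured (axial, circumferential)
quad indices so that element stresses can be averaged transmurally back onto
the structured surface grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .surfaces import StructuredSurface
from .synthetic import AnatomyParams, PatientCase, make_dissected_aorta

__all__ = ["HexMesh", "build_solid_mesh", "coarsen_params", "scaled_params", "coarse_case"]

# element set codes
SET_TL_WALL = 0
SET_FL_WALL = 1
SET_FLAP = 2
SET_THROMBUS = 3
SET_NAMES = {SET_TL_WALL: "tl_wall", SET_FL_WALL: "fl_wall", SET_FLAP: "flap", SET_THROMBUS: "thrombus"}


@dataclass
class HexMesh:
    """Solid FE domain with element/face sets and structured-grid bookkeeping."""

    nodes: np.ndarray                       # (n_nodes, 3) mm
    elems: np.ndarray                       # (n_elems, 8) node ids
    elem_set: np.ndarray                    # (n_elems,) int codes, see SET_NAMES
    elem_quad: np.ndarray                   # (n_elems, 2) structured (a, c) of the parent quad; -1 for flap
    elem_layer: np.ndarray                  # (n_elems,) through-thickness layer, 0 = outermost
    faces: dict[str, np.ndarray]            # face-set name -> (n_faces, 4) node ids (outward of solid)
    face_quad: dict[str, np.ndarray]        # face-set name -> (n_faces, 2) structured (a, c)
    proximal_nodes: np.ndarray              # node ids on the proximal end ring
    distal_nodes: np.ndarray                # node ids on the distal end ring
    tie_pairs: np.ndarray                   # (n_ties, 2) node-id pairs coupled by penalty springs
    grid_shape: tuple[int, int]             # (n_axial, n_circ) of the meshed surface
    landmark_layers: tuple[int, int]
    n_layers: int = 4
    char_length: float = 2.0                # mm, nominal element size (tie stiffness scale)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elems]

    def corner_jacobians(self) -> np.ndarray:
        """det J at the 8 corners of every element, shape (n_elems, 8)."""
        from .fem import corner_jacobian_dets

        return corner_jacobian_dets(self.element_coords())

    def wall_elem_mask(self) -> np.ndarray:
        return (self.elem_set == SET_TL_WALL) | (self.elem_set == SET_FL_WALL)


class MeshingError(RuntimeError):
    pass


def coarsen_params(params: AnatomyParams, circ_factor: int = 1, axial_factor: int = 1) -> AnatomyParams:
    """Rescale anatomy parameters onto a coarser structured grid.

    Regenerates the same parametric anatomy at ``n_circ / circ_factor`` by
    ``n_axial / axial_factor`` resolution, rescaling every layer-indexed
    parameter (landmarks, flap span, thrombus span, fenestrations).
    """
    if circ_factor == 1 and axial_factor == 1:
        return params
    nc = max(8, params.n_circ // circ_factor)
    na = max(8, params.n_axial // axial_factor)
    return scaled_params(params, nc, na)


def scaled_params(params: AnatomyParams, n_circ: int, n_axial: int) -> AnatomyParams:
    """Rescale anatomy parameters to an arbitrary target grid resolution."""
    nc, na = n_circ, n_axial
    s = na / params.n_axial

    def scale_layer(layer: int) -> int:
        return int(np.clip(round((layer - 1) * s) + 1, 1, na))

    fen = params.fenestrations
    if fen is not None:
        fen = tuple(
            (scale_layer(a0), max(1, round(ae * s)), c0, ce) for a0, ae, c0, ce in fen
        )
    return dataclasses.replace(
        params,
        n_circ=nc,
        n_axial=na,
        lsa_layer=None if params.lsa_layer is None else scale_layer(params.lsa_layer),
        flap_span=None
        if params.flap_span is None
        else (scale_layer(params.flap_span[0]), scale_layer(params.flap_span[1])),
        thrombus_span=None
        if params.thrombus_span is None
        else (scale_layer(params.thrombus_span[0]), scale_layer(params.thrombus_span[1])),
        fenestrations=fen,
    )


def coarse_case(case: PatientCase, circ_factor: int = 1, axial_factor: int = 1) -> PatientCase:
    """Regenerate a case's baseline anatomy at coarser mesh resolution."""
    params = coarsen_params(case.params, circ_factor, axial_factor)
    coarse = make_dissected_aorta(params)
    return dataclasses.replace(
        coarse,
        patient_id=case.patient_id,
        systolic_bp_kpa=case.systolic_bp_kpa,
        inlet_flow_l_min=case.inlet_flow_l_min,
    )


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _fix_face_orientation(nodes: np.ndarray, faces: np.ndarray, ref_dirs: np.ndarray) -> np.ndarray:
    """Reorder face connectivity so the right-hand normal follows ``ref_dirs``.

    Face normals must point outward of the solid (into the fluid) for the
    pressure loads to act in the right direction.
    """
    if faces.shape[0] == 0:
        return faces
    p = nodes[faces]
    n = np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])
    flip = np.einsum("ij,ij->i", n, ref_dirs) < 0
    out = faces.copy()
    out[flip] = out[flip][:, ::-1]
    return out


def build_solid_mesh(
    case: PatientCase,
    n_layers: int = 4,
    n_thrombus_layers: int = 2,
) -> HexMesh:
    """Extrude the baseline surfaces of a case into the layered hex mesh.

    Raises :class:`MeshingError` when the inward offset self-intersects
    (non-positive corner Jacobian), naming the offending layer.
    """
    surf = case.baseline
    na, nc = surf.grid_shape
    params = case.params
    normals = surf.node_normals()
    thickness = case.wall_thickness_map()

    # ---- wall node sheets: 0 (outer) .. n_layers (luminal) -----------------
    n_sheets = n_layers + 1
    sheet_offsets = np.linspace(0.0, 1.0, n_sheets)
    wall_nodes = (
        surf.nodes[None, :, :, :]
        - sheet_offsets[:, None, None, None] * thickness[None, :, :, None] * normals[None, :, :, :]
    )  # (n_sheets, na, nc, 3)
    wall_ids = np.arange(n_sheets * na * nc).reshape(n_sheets, na, nc)
    nodes_list = [wall_nodes.reshape(-1, 3)]
    next_id = n_sheets * na * nc

    # ---- wall elements -----------------------------------------------------
    fl_circ = _fl_quad_mask(case)                      # (nc,) FL quads by circumferential index
    f0, f1 = (case.flap.span if case.flap is not None else (1, 0))
    a_idx, c_idx = np.meshgrid(np.arange(na - 1), np.arange(nc), indexing="ij")
    c1_idx = (c_idx + 1) % nc

    quad_is_fl = np.zeros((na - 1, nc), dtype=bool)
    if case.flap is not None:
        quad_is_fl[f0 - 1 : f1 - 1, :] = fl_circ[None, :]

    elems = []
    elem_set = []
    elem_quad = []
    elem_layer = []
    for layer in range(n_layers):
        bot, top = wall_ids[layer], wall_ids[layer + 1]
        conn = np.stack(
            [
                bot[a_idx, c_idx], bot[a_idx, c1_idx], bot[a_idx + 1, c1_idx], bot[a_idx + 1, c_idx],
                top[a_idx, c_idx], top[a_idx, c1_idx], top[a_idx + 1, c1_idx], top[a_idx + 1, c_idx],
            ],
            axis=-1,
        ).reshape(-1, 8)
        elems.append(conn)
        elem_set.append(np.where(quad_is_fl.ravel(), SET_FL_WALL, SET_TL_WALL))
        elem_quad.append(np.stack([a_idx.ravel(), c_idx.ravel()], axis=1))
        elem_layer.append(np.full(conn.shape[0], layer))

    # ---- luminal wall faces ------------------------------------------------
    lum = wall_ids[n_layers]
    wall_faces = np.stack(
        [lum[a_idx, c_idx], lum[a_idx, c1_idx], lum[a_idx + 1, c1_idx], lum[a_idx + 1, c_idx]],
        axis=-1,
    ).reshape(-1, 4)
    wall_face_quad = np.stack([a_idx.ravel(), c_idx.ravel()], axis=1)
    quad_thr = case.thrombus_mask.ravel()
    flat_fl = quad_is_fl.ravel()
    faces: dict[str, np.ndarray] = {
        "tl_lumen": wall_faces[~flat_fl],
        "fl_lumen": wall_faces[flat_fl & ~quad_thr],
    }
    face_quad: dict[str, np.ndarray] = {
        "tl_lumen": wall_face_quad[~flat_fl],
        "fl_lumen": wall_face_quad[flat_fl & ~quad_thr],
    }

    # ---- thrombus lining ---------------------------------------------------
    if quad_thr.any():
        (
            thr_nodes,
            thr_elems,
            thr_quad,
            thr_layer,
            thr_faces,
            thr_face_quad,
            next_id,
        ) = _extrude_thrombus(
            case, wall_nodes[n_layers], normals, wall_ids[n_layers], next_id,
            n_thrombus_layers,
        )
        nodes_list.append(thr_nodes)
        elems.append(thr_elems)
        elem_set.append(np.full(thr_elems.shape[0], SET_THROMBUS))
        elem_quad.append(thr_quad)
        elem_layer.append(thr_layer)
        faces["thrombus_lumen"] = thr_faces
        face_quad["thrombus_lumen"] = thr_face_quad
    else:
        faces["thrombus_lumen"] = np.zeros((0, 4), dtype=int)
        face_quad["thrombus_lumen"] = np.zeros((0, 2), dtype=int)

    # ---- flap strip --------------------------------------------------------
    tie_pairs = np.zeros((0, 2), dtype=int)
    if case.flap is not None:
        (
            flap_nodes,
            flap_elems,
            flap_quad,
            flap_layer,
            flap_faces_tl,
            flap_faces_fl,
            flap_face_quad,
            tie_pairs,
            next_id,
        ) = _extrude_flap(case, wall_ids[n_layers], next_id, n_layers)
        nodes_list.append(flap_nodes)
        elems.append(flap_elems)
        elem_set.append(np.full(flap_elems.shape[0], SET_FLAP))
        elem_quad.append(flap_quad)
        elem_layer.append(flap_layer)
        faces["flap_tl"] = flap_faces_tl
        faces["flap_fl"] = flap_faces_fl
        face_quad["flap_tl"] = flap_face_quad
        face_quad["flap_fl"] = flap_face_quad.copy()
    else:
        for name in ("flap_tl", "flap_fl"):
            faces[name] = np.zeros((0, 4), dtype=int)
            face_quad[name] = np.zeros((0, 2), dtype=int)

    nodes = np.concatenate(nodes_list, axis=0)
    elems_arr = np.concatenate(elems, axis=0)

    # orient all loaded faces with their normal pointing into the fluid
    centroids = surf.ring_centroids()
    for name in ("tl_lumen", "fl_lumen", "thrombus_lumen", "flap_tl", "flap_fl"):
        f = faces[name]
        if f.shape[0] == 0:
            continue
        fc = nodes[f].mean(axis=1)
        a = face_quad[name][:, 0]
        if name in ("tl_lumen", "fl_lumen", "thrombus_lumen"):
            ref = 0.5 * (centroids[a] + centroids[a + 1]) - fc
        else:
            fl_wall_pt = 0.5 * (surf.nodes[a, 0] + surf.nodes[np.minimum(a + 1, na - 1), 0])
            ref = fl_wall_pt - fc
            if name == "flap_tl":
                ref = -ref
        faces[name] = _fix_face_orientation(nodes, f, ref)

    mesh = HexMesh(
        nodes=nodes,
        elems=elems_arr,
        elem_set=np.concatenate(elem_set),
        elem_quad=np.concatenate(elem_quad, axis=0),
        elem_layer=np.concatenate(elem_layer),
        faces=faces,
        face_quad=face_quad,
        proximal_nodes=wall_ids[:, 0, :].ravel(),
        distal_nodes=wall_ids[:, -1, :].ravel(),
        tie_pairs=tie_pairs,
        grid_shape=(na, nc),
        landmark_layers=surf.landmark_layers,
        n_layers=n_layers,
        char_length=float(np.median(surf.segment_lengths())),
    )

    _orient_elements(mesh)
    dets = mesh.corner_jacobians()
    if np.any(dets <= 0):
        bad = np.nonzero(np.any(dets <= 0, axis=1))[0]
        layers = np.unique(mesh.elem_layer[bad])
        sets = {SET_NAMES[s] for s in np.unique(mesh.elem_set[bad])}
        raise MeshingError(
            f"self-intersecting offset: {bad.size} elements with non-positive "
            f"corner Jacobian in layer(s) {layers.tolist()} of set(s) {sorted(sets)}"
        )
    return mesh


def _fl_quad_mask(case: PatientCase) -> np.ndarray:
    """Circumferential mask of quads whose both nodes lie in the FL sector."""
    nc = case.baseline.n_circ
    if case.flap is None:
        return np.zeros(nc, dtype=bool)
    k, nk = case.flap.attach_indices
    circ = np.arange(nc)
    fl_nodes = (circ < k) | (circ > nk)  # attachment columns count as TL
    return fl_nodes & np.roll(fl_nodes, -1)


def _extrude_thrombus(case, lum_coords, normals, lum_ids, next_id, n_thrombus_layers):
    """Extrude thrombus hex layers inward from thrombosed FL luminal quads."""
    na, nc = case.baseline.grid_shape
    thr_quads = case.thrombus_mask  # (na-1, nc)
    # nodes incident to a thrombosed quad
    node_mask = np.zeros((na, nc), dtype=bool)
    aq, cq = np.nonzero(thr_quads)
    for da in (0, 1):
        node_mask[aq + da, cq] = True
        node_mask[aq + da, (cq + 1) % nc] = True

    ids_grid = np.full((n_thrombus_layers, na, nc), -1, dtype=int)
    n_new = int(node_mask.sum())
    coords = []
    for t in range(n_thrombus_layers):
        frac = (t + 1) / n_thrombus_layers
        ids_grid[t][node_mask] = np.arange(next_id, next_id + n_new)
        next_id += n_new
        coords.append(
            lum_coords[node_mask]
            - frac * case.params.thrombus_thickness * normals[node_mask]
        )
    thr_nodes = np.concatenate(coords, axis=0)

    sheets = [lum_ids] + [ids_grid[t] for t in range(n_thrombus_layers)]
    elems, quads, layers, faces, face_quads = [], [], [], [], []
    c1 = (cq + 1) % nc
    for t in range(n_thrombus_layers):
        bot, top = sheets[t], sheets[t + 1]
        conn = np.stack(
            [bot[aq, cq], bot[aq, c1], bot[aq + 1, c1], bot[aq + 1, cq],
             top[aq, cq], top[aq, c1], top[aq + 1, c1], top[aq + 1, cq]],
            axis=-1,
        )
        elems.append(conn)
        quads.append(np.stack([aq, cq], axis=1))
        layers.append(np.full(conn.shape[0], t))
    inner = sheets[-1]
    faces = np.stack(
        [inner[aq, cq], inner[aq, c1], inner[aq + 1, c1], inner[aq + 1, cq]], axis=-1
    )
    face_quads = np.stack([aq, cq], axis=1)
    return (
        thr_nodes,
        np.concatenate(elems, axis=0),
        np.concatenate(quads, axis=0),
        np.concatenate(layers),
        faces,
        face_quads,
        next_id,
    )


def _extrude_flap(case, lum_ids, next_id, n_layers):
    """Extrude the flap mid-surface into a 4-layer hex strip with edge ties."""
    flap = case.flap
    params = case.params
    nfl, nac = flap.n_layers, flap.n_across
    f0, _ = flap.span
    k, nk = flap.attach_indices

    # flap mid-surface normals (open grid, no wrap)
    mid = flap.nodes
    dc = np.empty_like(mid)
    dc[:, 1:-1] = mid[:, 2:] - mid[:, :-2]
    dc[:, 0] = mid[:, 1] - mid[:, 0]
    dc[:, -1] = mid[:, -1] - mid[:, -2]
    da = np.empty_like(mid)
    da[1:-1] = mid[2:] - mid[:-2]
    da[0] = mid[1] - mid[0]
    da[-1] = mid[-1] - mid[-2]
    nrm = np.cross(dc, da)
    nrm /= np.linalg.norm(nrm, axis=2, keepdims=True)

    n_sheets = n_layers + 1
    offs = np.linspace(-0.5, 0.5, n_sheets) * params.flap_thickness
    sheets = mid[None] + offs[:, None, None, None] * nrm[None]
    ids = np.arange(next_id, next_id + n_sheets * nfl * nac).reshape(n_sheets, nfl, nac)
    next_id += n_sheets * nfl * nac
    flap_nodes = sheets.reshape(-1, 3)

    open_q = flap.open_quads  # (nfl-1, nac-1)
    ai, ci = np.nonzero(~open_q)
    elems, quads, layers = [], [], []
    for layer in range(n_layers):
        bot, top = ids[layer], ids[layer + 1]
        conn = np.stack(
            [bot[ai, ci], bot[ai, ci + 1], bot[ai + 1, ci + 1], bot[ai + 1, ci],
             top[ai, ci], top[ai, ci + 1], top[ai + 1, ci + 1], top[ai + 1, ci]],
            axis=-1,
        )
        elems.append(conn)
        quads.append(np.stack([ai, ci], axis=1))
        layers.append(np.full(conn.shape[0], layer))

    # which side of the flap faces the false lumen?  The FL sector is centred
    # on circumferential index 0; the sheet whose offset points toward the FL
    # wall is the FL face.
    surf = case.baseline
    fl_dir = surf.nodes[f0 - 1 + np.arange(nfl), 0] - mid[:, nac // 2]
    side = np.sign(np.einsum("ij,ij->i", nrm[:, nac // 2], fl_dir).mean())
    fl_sheet, tl_sheet = (n_sheets - 1, 0) if side > 0 else (0, n_sheets - 1)

    def side_faces(sheet_ids):
        return np.stack(
            [sheet_ids[ai, ci], sheet_ids[ai, ci + 1], sheet_ids[ai + 1, ci + 1], sheet_ids[ai + 1, ci]],
            axis=-1,
        )

    faces_fl = side_faces(ids[fl_sheet])
    faces_tl = side_faces(ids[tl_sheet])
    face_quad = np.stack([ai + f0 - 1, ci], axis=1)  # absolute axial layer, chord index

    # edge ties: every flap edge node couples to the wall luminal node at its
    # attachment line (stiff spring tie, node-to-node)
    a_abs = f0 - 1 + np.arange(nfl)
    ties = []
    for sheet in range(n_sheets):
        ties.append(np.stack([ids[sheet, :, 0], lum_ids[a_abs, k]], axis=1))
        ties.append(np.stack([ids[sheet, :, -1], lum_ids[a_abs, nk]], axis=1))
    tie_pairs = np.concatenate(ties, axis=0)

    return (
        flap_nodes,
        np.concatenate(elems, axis=0),
        np.concatenate(quads, axis=0),
        np.concatenate(layers),
        faces_tl,
        faces_fl,
        face_quad,
        tie_pairs,
        next_id,
    )


def _orient_elements(mesh: HexMesh) -> None:
    """Flip element connectivity where the median corner Jacobian is negative."""
    dets = mesh.corner_jacobians()
    flip = np.median(dets, axis=1) < 0
    if flip.any():
        e = mesh.elems[flip]
        mesh.elems[flip] = e[:, [4, 5, 6, 7, 0, 1, 2, 3]]
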