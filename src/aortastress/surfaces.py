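"""Structured cylinder-topology vessel surfaces.

The common coordinate frame of the whole pipeline is a structured quadrilateral
surface grid that is topologically the lateral surface of a cylinder: ``n_circ``
nodes around each circumference and ``n_axial`` circumferential layers (rings)
from the proximal to the distal end.  Growth heatmaps, sampled stress fields and
the axial region partition all live on this grid.

Conventions (used everywhere in the package):

* lengths in mm, pressures/stresses in kPa, wall shear stress in Pa, time in years;
* the axial layer index is 1-based, proximal to distal;
* the circumferential index wraps, node ``n_circ`` is adjacent to node 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["StructuredSurface"]


@dataclass
class StructuredSurface:
    """A vessel surface on an (n_axial x n_circ) structured node grid.

    Parameters
    ----------
    nodes
        Array of shape ``(n_axial, n_circ, 3)`` with node coordinates in mm.
        ``nodes[a, c]`` is the node on ring ``a`` (0-based internally) at
        circumferential position ``c``.
    landmark_layers
        1-based axial layer indices ``(left_subclavian, bifurcation)``.  The
        descending aorta spans the layers between them (inclusive).
    """

    nodes: np.ndarray
    landmark_layers: tuple[int, int] = field(default=(1, 2))

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 3 or self.nodes.shape[2] != 3:
            raise ValueError("nodes must have shape (n_axial, n_circ, 3)")
        lsa, bif = self.landmark_layers
        if not (1 <= lsa < bif <= self.n_axial):
            raise ValueError(
                f"landmark layers {self.landmark_layers} invalid for n_axial={self.n_axial}"
            )

    # -- basic shape ---------------------------------------------------------
    @property
    def n_axial(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_circ(self) -> int:
        return self.nodes.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.n_axial, self.n_circ)

    def points(self) -> np.ndarray:
        """All nodes as an ``(n_axial * n_circ, 3)`` array (ring-major order)."""
        return self.nodes.reshape(-1, 3)

    # -- ring geometry -------------------------------------------------------
    def ring_centroids(self) -> np.ndarray:
        """Mean node position of every ring, shape (n_axial, 3)."""
        return self.nodes.mean(axis=1)

    def segment_lengths(self) -> np.ndarray:
        """Circumferential segment lengths, shape (n_axial, n_circ).

        Entry ``[a, c]`` is the length of the segment from node c to node c+1
        (wrapping) on ring a.
        """
        d = np.roll(self.nodes, -1, axis=1) - self.nodes
        return np.linalg.norm(d, axis=2)

    def ring_perimeters(self) -> np.ndarray:
        return self.segment_lengths().sum(axis=1)

    def effective_diameters(self) -> np.ndarray:
        """Per-ring effective diameter, perimeter / pi.

        Dissected cross sections are not circular, so "diameter" is defined
        through the perimeter of the outer wall ring.
        """
        return self.ring_perimeters() / np.pi

    def ring_areas(self) -> np.ndarray:
        """Enclosed (projected) area of each ring polygon.

        Computed in the ring's own best-fit plane via the cross-product shoelace
        formula about the centroid; positive for non-self-intersecting rings.
        """
        c = self.ring_centroids()[:, None, :]
        r = self.nodes - c
        cross = np.cross(r, np.roll(r, -1, axis=1))
        # magnitude of the summed vector area of the triangle fan
        return 0.5 * np.linalg.norm(cross.sum(axis=1), axis=1)

    # -- connectivity --------------------------------------------------------
    def quad_connectivity(self) -> np.ndarray:
        """Quad faces implied by the grid as flat node indices, shape (n_quad, 4).

        Flat index of node (a, c) is ``a * n_circ + c``.  Quads wrap in the
        circumferential direction.
        """
        na, nc = self.grid_shape
        a = np.arange(na - 1)[:, None]
        c = np.arange(nc)[None, :]
        c1 = (c + 1) % nc
        i00 = a * nc + c
        i01 = a * nc + c1
        i10 = (a + 1) * nc + c
        i11 = (a + 1) * nc + c1
        quads = np.stack([i00, i01, i11, i10], axis=-1)
        return quads.reshape(-1, 4)

    def node_normals(self) -> np.ndarray:
        """Outward unit normals per node, shape (n_axial, n_circ, 3).

        Normals point away from the ring centroid (outward for a convex tube),
        computed as the cross product of the circumferential and axial tangents
        and orientation-fixed against the centroid direction.
        """
        dc = np.roll(self.nodes, -1, axis=1) - np.roll(self.nodes, 1, axis=1)
        da = np.empty_like(self.nodes)
        da[1:-1] = self.nodes[2:] - self.nodes[:-2]
        da[0] = self.nodes[1] - self.nodes[0]
        da[-1] = self.nodes[-1] - self.nodes[-2]
        n = np.cross(dc, da)
        norm = np.linalg.norm(n, axis=2, keepdims=True)
        norm[norm == 0] = 1.0
        n /= norm
        outward = self.nodes - self.ring_centroids()[:, None, :]
        flip = np.sum(n * outward, axis=2) < 0
        n[flip] *= -1.0
        return n

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        """Check the structural-surface invariants; raise ValueError on failure."""
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("non-finite node coordinates")
        if np.any(self.segment_lengths() <= 0):
            raise ValueError("degenerate (repeated) nodes within a ring")
        if np.any(self.ring_areas() <= 0):
            raise ValueError("ring with non-positive enclosed area")

    # -- transforms ----------------------------------------------------------
    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructuredSurface":
        """Return a rigidly transformed copy (x -> R x + t)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new = self.nodes @ rotation.T + translation
        return replace(self, nodes=new)

    def copy(self) -> "StructuredSurface":
        return replace(self, nodes=self.nodes.copy())

    def descending_layer_mask(self) -> np.ndarray:
        """Boolean mask over axial layers that lie in the descending aorta."""
        lsa, bif = self.landmark_layers
        layers = np.arange(1, self.n_axial + 1)
        return (layers >= lsa) & (layers <= bif)
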