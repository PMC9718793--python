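"""Macrowear quantification: crown volumes, wear rates, facet geometry.

Crown volume comes from the divergence theorem on a closed triangulated
surface; crowns scanned without a base are closed with a planar fan cap
first.  Percent volume lost compares size-matched intact and worn crowns;
per-quadrant abraded volume multiplies the per-tooth loss by the tooth
count of the jaw quadrant.  Facet geometry (area coverage and angle to the
apicobasal axis) distinguishes steep shearing wear from low-angle grinding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import LevelingError, WatertightError
from .surfaces import CrownMesh


@dataclass
class WearPair:
    complete: CrownMesh | None
    worn: CrownMesh | None
    v_complete: float  # mm³
    v_worn: float  # mm³

    @property
    def percent_lost(self) -> float:
        return percent_volume_lost(self.v_complete, self.v_worn)


@dataclass
class FacetMeasurement:
    facet_area: float  # mm²
    occlusal_crown_area: float  # mm²
    coverage_percent: float
    facet_angle: float  # degrees from the apicobasal axis


@dataclass
class QuadrantWear:
    tooth_count: int
    per_tooth_loss: float  # mm³
    total_abraded: float  # mm³
    provenance: str = ""


# ---------------------------------------------------------------------------
# boundary handling
# ---------------------------------------------------------------------------


def boundary_loops(mesh: CrownMesh) -> list[list[int]]:
    """Directed boundary loops (vertex index lists) of an open mesh.

    A boundary edge appears in exactly one face; the loop direction follows
    the face winding, so a fan cap built on the loop closes the surface with
    consistent orientation.
    """
    edges: dict[tuple[int, int], int] = {}
    for a, b, c in mesh.faces:
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            edges[key] = edges.get(key, 0) + 1
    directed = {}
    for a, b, c in mesh.faces:
        for u, v in ((a, b), (b, c), (c, a)):
            if edges[(min(u, v), max(u, v))] == 1:
                directed[int(u)] = int(v)
    loops = []
    seen: set[int] = set()
    for start in sorted(directed):
        if start in seen:
            continue
        loop, node = [start], directed[start]
        seen.add(start)
        while node != start and node not in seen:
            loop.append(node)
            seen.add(node)
            node = directed.get(node, start)
        loops.append(loop)
    return loops


def cap_loop(mesh: CrownMesh, loop: list[int]) -> CrownMesh:
    """Close one boundary loop with a fan to its centroid.

    Boundary loops inherit the face winding, so fan triangles
    ``(centroid, v_next, v)`` keep the outward orientation consistent.
    """
    centroid = mesh.vertices[loop].mean(axis=0)
    verts = np.vstack([mesh.vertices, centroid])
    ci = len(verts) - 1
    fan = [[ci, loop[(k + 1) % len(loop)], loop[k]] for k in range(len(loop))]
    faces = np.vstack([mesh.faces, np.asarray(fan, dtype=np.int64)])
    return CrownMesh(verts, faces, mesh.apicobasal_axis, mesh.label)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def crown_volume(mesh: CrownMesh, cap_base: bool = False) -> float:
    """Enclosed crown volume (mm³) via the divergence theorem.

    Watertight meshes are integrated directly.  A mesh open only at the
    crown base is closed with a planar fan cap when ``cap_base`` is set;
    any other hole pattern raises a watertightness error listing the
    boundary loops.
    """
    loops = boundary_loops(mesh)
    if loops:
        if not cap_base:
            raise WatertightError(
                f"mesh has {len(loops)} boundary loop(s); pass cap_base=True "
                "if the only opening is the crown base",
                loops=loops,
            )
        if len(loops) != 1:
            raise WatertightError(
                f"cap_base expects a single base opening, found {len(loops)} loops",
                loops=loops,
            )
        mesh = cap_loop(mesh, loops[0])
    vol = mesh.signed_volume()
    return abs(vol)


def percent_volume_lost(v_complete: float, v_worn: float) -> float:
    """Percent of the complete crown volume removed by wear."""
    if v_complete <= 0:
        raise ValueError("complete crown volume must be positive")
    if v_worn > v_complete:
        warnings.warn(
            "worn volume exceeds complete volume; the size-matching assumption "
            "is violated"
        )
    return 100.0 * (v_complete - v_worn) / v_complete


def quadrant_abraded_volume(
    tooth_count: int, per_tooth_loss: float, provenance: str = ""
) -> QuadrantWear:
    """Total abraded volume over a jaw quadrant: tooth count x per-tooth loss."""
    if tooth_count < 1:
        raise ValueError("tooth_count must be >= 1")
    return QuadrantWear(
        tooth_count=tooth_count,
        per_tooth_loss=per_tooth_loss,
        total_abraded=tooth_count * per_tooth_loss,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# facets
# ---------------------------------------------------------------------------


def _masked_face_area(mesh: CrownMesh, vertex_mask: np.ndarray) -> float:
    """Summed area of faces whose three vertices are all in the mask."""
    inside = vertex_mask[mesh.faces].all(axis=1)
    t = mesh.vertices[mesh.faces[inside]]
    if len(t) == 0:
        return 0.0
    return float(0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum())


def facet_plane_angle(mesh: CrownMesh, vertex_mask: np.ndarray) -> float:
    """Angle (degrees) between the facet's least-squares plane and the
    apicobasal axis: 0° for a facet parallel to the axis, 90° perpendicular."""
    pts = mesh.vertices[vertex_mask]
    if len(pts) < 3:
        raise LevelingError("facet needs at least 3 vertices for a plane fit")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise LevelingError("facet vertices are collinear; plane is degenerate")
    normal = vt[2]
    cosang = abs(float(np.dot(normal, mesh.apicobasal_axis)))
    return 90.0 - np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))


def facet_metrics(
    mesh: CrownMesh, facet_mask: np.ndarray, occlusal_mask: np.ndarray
) -> FacetMeasurement:
    """Facet area, occlusal crown-face area, coverage %, and facet angle.

    Masks are boolean per-vertex; a face contributes only when all three of
    its vertices are inside the mask.
    """
    facet_mask = np.asarray(facet_mask, dtype=bool)
    occlusal_mask = np.asarray(occlusal_mask, dtype=bool)
    if not facet_mask.any() or not occlusal_mask.any():
        raise ValueError("facet and occlusal masks must be non-empty")
    fa = _masked_face_area(mesh, facet_mask)
    oa = _masked_face_area(mesh, occlusal_mask)
    if oa <= 0:
        raise ValueError("occlusal mask selects no complete face")
    return FacetMeasurement(
        facet_area=fa,
        occlusal_crown_area=oa,
        coverage_percent=100.0 * fa / oa,
        facet_angle=facet_plane_angle(mesh, facet_mask),
    )


def coverage_percent(facet_area: float, occlusal_area: float) -> float:
    """Wear-facet coverage of the occlusal crown face, in percent."""
    if occlusal_area <= 0:
        raise ValueError("occlusal area must be positive")
    return 100.0 * facet_area / occlusal_area
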