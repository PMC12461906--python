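"""Surface discretization: triangulated mesh -> point folder.

Each mesh vertex becomes one surface element per leaflet: the outer point
sits at ``r + (t/2) n``, the inner point at ``r - (t/2) n`` with the normal
flipped.  Lipid packing density is therefore controlled by mesh resolution
(one lipid anchor per point); the optional ``rescale`` factor stretches the
whole mesh first.

Moving a curved surface parallel to itself changes its curvature and area.
For an offset ``s`` along the normal the parallel-surface transforms are

    c_i' = c_i / (1 + s c_i),    area' = area (1 + s c1)(1 + s c2)

(concentric spheres: a sphere of radius R offset outward by s becomes one
of radius R + s with curvature 1/(R+s) and area 4 pi (R+s)^2).  Inner-leaflet
curvatures are negated after the transform because they are seen from the
flipped normal.  An offset at or beyond the curvature radius
(``1 + s c_i <= 0``) cannot form a leaflet and is an error.
"""

from __future__ import annotations


import numpy as np

from .geometry import VertexFrame, vertex_frames
from .mesh_io import TriMesh, detect_open_edges
from .point_model import Exclusion, Inclusion, PointFolder, SurfacePoint

__all__ = ["discretize", "leaflet_point", "DEFAULT_THICKNESS"]

#: default bilayer thickness, nm (typical coarse-grained phospholipid bilayer)
DEFAULT_THICKNESS = 3.8


def leaflet_point(pid: int, position: np.ndarray, frame: VertexFrame,
                  offset: float, leaflet: str, edge: bool = False,
                  domain: int = 0, source_vertex: int | None = None
                  ) -> SurfacePoint:
    """Offset one mid-surface element into a leaflet point.

    ``offset`` is signed along the mid-surface normal (+t/2 outer, -t/2
    inner).  Applies the parallel-surface curvature/area transforms; for the
    inner leaflet the normal and the transformed curvatures are flipped.
    """
    f1 = 1.0 + offset * frame.c1
    f2 = 1.0 + offset * frame.c2
    if f1 <= 0 or f2 <= 0:
        raise ValueError(
            f"point {pid}: leaflet offset {offset:+.3g} nm reaches beyond the "
            f"curvature radius (c1={frame.c1:.3g}, c2={frame.c2:.3g} 1/nm); "
            "use a finer mesh or a thinner bilayer"
        )
    c1p = frame.c1 / f1
    c2p = frame.c2 / f2
    area = frame.area * f1 * f2
    if leaflet == "inner":
        normal = -frame.normal
        # curvature seen from the flipped normal changes sign; swap to keep c1 >= c2
        c1p, c2p = -c2p, -c1p
        t1, t2 = frame.t2.copy(), frame.t1.copy()
    else:
        normal = frame.normal.copy()
        t1, t2 = frame.t1.copy(), frame.t2.copy()
    new_frame = VertexFrame(normal=normal, t1=t1, t2=t2,
                            c1=c1p, c2=c2p, area=area,
                            degenerate=frame.degenerate)
    return SurfacePoint(
        id=pid, position=position + offset * frame.normal, frame=new_frame,
        leaflet=leaflet, domain=domain, edge=edge,
        source_vertex=pid if source_vertex is None else source_vertex)


def discretize(mesh: TriMesh, bilayer_thickness: float = DEFAULT_THICKNESS,
               rescale: float = 1.0) -> PointFolder:
    """Convert an oriented mesh into a two-leaflet :class:`PointFolder`.

    Point count is exactly twice the vertex count; point ids equal source
    vertex ids on both leaflets.  Boundary vertices are flagged ``edge`` on
    both leaflets; inclusion/exclusion marks are carried through onto the
    corresponding points.  Deterministic: no randomness involved.
    """
    if bilayer_thickness <= 0:
        raise ValueError(f"bilayer thickness must be > 0, got {bilayer_thickness}")
    if rescale <= 0:
        raise ValueError(f"rescale must be > 0, got {rescale}")

    if rescale != 1.0:
        mesh = TriMesh(mesh.vertices * rescale, mesh.triangles,
                       mesh.box * rescale,
                       vertex_domain=mesh.vertex_domain,
                       inclusion_marks=list(mesh.inclusion_marks),
                       exclusion_marks=list(mesh.exclusion_marks))

    frames = vertex_frames(mesh)
    boundary = detect_open_edges(mesh)
    half = bilayer_thickness / 2.0
    dom = mesh.vertex_domain

    outer, inner = [], []
    edges = [(int(a), int(b)) for a, b in _mesh_edge_list(mesh)]
    for i in range(mesh.n_vertices):
        d = int(dom[i]) if dom is not None else 0
        e = i in boundary
        outer.append(leaflet_point(i, mesh.vertices[i], frames[i], +half,
                                   "outer", edge=e, domain=d))
        inner.append(leaflet_point(i, mesh.vertices[i], frames[i], -half,
                                   "inner", edge=e, domain=d))

    inclusions = [Inclusion(type_id=tid, point_id=vid,
                            orientation=np.asarray(direction)[:2])
                  for tid, vid, direction in mesh.inclusion_marks]
    exclusions = [Exclusion(point_id=vid, radius=r)
                  for vid, r in mesh.exclusion_marks]

    folder = PointFolder(outer=outer, inner=inner, box=mesh.box.copy(),
                         inclusions=inclusions, exclusions=exclusions,
                         mesh_edges={"outer": edges, "inner": list(edges)})
    if exclusions:
        from .placement import _pore_members
        for exc in exclusions:
            for name in ("outer", "inner"):
                folder.excluded_ids[name] |= _pore_members(
                    folder, name, exc.point_id, exc.radius)
    return folder


def _mesh_edge_list(mesh: TriMesh):
    seen = set()
    for a, b, c in mesh.triangles:
        for u, v in ((a, b), (b, c), (c, a)):
            e = (min(u, v), max(u, v))
            if e not in seen:
                seen.add(e)
                yield e
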