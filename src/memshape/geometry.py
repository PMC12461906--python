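"""Per-vertex discrete differential geometry on triangle meshes.

Normals are angle-weighted averages of incident triangle normals; areas use
the barycentric one-third rule (exact global area conservation, robust to
obtuse triangles).  Principal curvatures come from a local quadric fit: the
1-ring (escalated to the 2-ring when fewer than 5 neighbours) is expressed
in the vertex tangent frame, a quadratic height field
``h(u, v) = 1/2 (a u^2 + 2 b u v + c v^2)`` is least-squares fitted, and the
shape operator ``-[[a, b], [b, c]]`` is eigen-decomposed into principal
curvatures and directions.

Sign convention: with outward normals, a sphere of radius R has
``c1 = c2 = +1/R``; mean curvature ``H = (c1 + c2) / 2``.  Curvatures are
in 1/nm, areas in nm^2.  The estimator degrades gracefully at open edges
(one-sided fans) and is isolated here so alternatives can be swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh_io import TriMesh, MeshError

__all__ = ["VertexFrame", "vertex_normals", "vertex_areas",
           "principal_curvatures", "vertex_frames"]

#: below this many 1-ring neighbours, escalate the fit to the 2-ring
RING_ESCALATION_THRESHOLD = 5


@dataclass
class VertexFrame:
    """Local orthonormal frame + curvature of one surface element.

    ``{t1, t2, normal}`` is right-handed; ``c1 >= c2`` (principal
    curvatures, 1/nm along t1/t2); ``area`` in nm^2.
    """

    normal: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    c1: float
    c2: float
    area: float
    degenerate: bool = False

    @property
    def mean_curvature(self) -> float:
        return 0.5 * (self.c1 + self.c2)


def _triangle_normals_areas(mesh: TriMesh):
    v = mesh.vertices[mesh.triangles]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norm = np.linalg.norm(cross, axis=1)
    areas = 0.5 * norm
    zero = norm < 1e-14
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-area triangles contribute nothing")
        norm = np.where(zero, 1.0, norm)
    return cross / norm[:, None], areas


def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Angle-weighted per-vertex unit normals (N, 3).

    Boundary vertices use their one-sided fan.  An isolated vertex (no
    incident triangle) is an error.
    """
    tn, _ = _triangle_normals_areas(mesh)
    normals = np.zeros((mesh.n_vertices, 3))
    incident = np.zeros(mesh.n_vertices, dtype=int)
    V, T = mesh.vertices, mesh.triangles
    for k in range(3):
        i = T[:, k]
        e1 = V[T[:, (k + 1) % 3]] - V[i]
        e2 = V[T[:, (k + 2) % 3]] - V[i]
        n1 = np.linalg.norm(e1, axis=1)
        n2 = np.linalg.norm(e2, axis=1)
        cosang = np.clip(np.einsum("ij,ij->i", e1, e2) / np.maximum(n1 * n2, 1e-30),
                         -1.0, 1.0)
        ang = np.arccos(cosang)
        np.add.at(normals, i, tn * ang[:, None])
        np.add.at(incident, i, 1)
    if (incident == 0).any():
        raise MeshError(
            f"isolated vertices (no incident triangle): "
            f"{np.flatnonzero(incident == 0).tolist()}"
        )
    norm = np.linalg.norm(normals, axis=1)
    norm = np.where(norm < 1e-30, 1.0, norm)
    return normals / norm[:, None]


def vertex_areas(mesh: TriMesh) -> np.ndarray:
    """Barycentric vertex areas: each triangle gives a third to each corner."""
    _, ta = _triangle_normals_areas(mesh)
    areas = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(areas, mesh.triangles[:, k], ta / 3.0)
    return areas


def _vertex_adjacency(mesh: TriMesh) -> list:
    adj = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.triangles:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return adj


def principal_curvatures(mesh: TriMesh, normals: np.ndarray | None = None):
    """Quadric-fit shape operator at every vertex.

    Returns ``(c1, c2, t1, t2, degenerate)`` arrays with ``c1 >= c2`` and
    right-handed ``{t1, t2, normal}``.  A rank-deficient fit (e.g. collinear
    neighbours) falls back to zero curvature with the ``degenerate`` flag
    set instead of raising.
    """
    if normals is None:
        normals = vertex_normals(mesh)
    adj = _vertex_adjacency(mesh)
    N = mesh.n_vertices
    V = mesh.vertices
    c1 = np.zeros(N)
    c2 = np.zeros(N)
    t1 = np.zeros((N, 3))
    t2 = np.zeros((N, 3))
    degenerate = np.zeros(N, dtype=bool)

    for i in range(N):
        n = normals[i]
        ring = set(adj[i])
        if len(ring) < RING_ESCALATION_THRESHOLD:
            for j in list(ring):
                ring |= adj[j]
            ring.discard(i)
        nbrs = np.array(sorted(ring), dtype=int)

        # tangent basis seed: any direction orthogonal to n
        seed = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - n * (seed @ n)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)

        d = V[nbrs] - V[i]
        u = d @ e1
        v = d @ e2
        h = d @ n
        A = np.column_stack([0.5 * u * u, u * v, 0.5 * v * v])
        sol, _, rank, _ = np.linalg.lstsq(A, h, rcond=None)
        if rank < 3 or len(nbrs) < 3:
            degenerate[i] = True
            t1[i], t2[i] = e1, e2
            continue
        a, b, c = sol
        # outward-normal sphere bends below its tangent plane (h < 0):
        # negate the Hessian so that sphere gives +1/R
        shape = -np.array([[a, b], [b, c]])
        w, vecs = np.linalg.eigh(shape)  # ascending
        c1[i], c2[i] = w[1], w[0]
        d1 = vecs[:, 1]
        t1[i] = d1[0] * e1 + d1[1] * e2
        t1[i] /= np.linalg.norm(t1[i])
        t2[i] = np.cross(n, t1[i])
    return c1, c2, t1, t2, degenerate


def vertex_frames(mesh: TriMesh) -> list[VertexFrame]:
    """Full per-vertex frames: normals, areas and principal curvatures."""
    normals = vertex_normals(mesh)
    areas = vertex_areas(mesh)
    c1, c2, t1, t2, degenerate = principal_curvatures(mesh, normals)
    return [
        VertexFrame(normal=normals[i], t1=t1[i], t2=t2[i],
                    c1=float(c1[i]), c2=float(c2[i]),
                    area=float(areas[i]), degenerate=bool(degenerate[i]))
        for i in range(mesh.n_vertices)
    ]
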