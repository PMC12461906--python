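"""Deterministic synthetic geometry and structure generators.

Every mesh and toy structure the package needs — icospheres, capped
cylinders, tori, Möbius strips, sine sheets, flat grids, toy lipids, a
rigid toy protein and a water template — is generated here from closed-form
parametrizations, so the full pipeline is exercisable without any external
input files.  Analytic curvature is known for the sphere/cylinder/sine
shapes, which is what makes them usable as geometry oracles; the Möbius
strip is the canonical nonorientable input for the orientation/cut
machinery.

These doubles as tutorial inputs: ``memshape FIX --shape icosphere -o d/``
writes ready-to-use files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .builder import MembraneModel, Residue, write_gro
from .lipid_lib import MINI_LIB_TEXT
from .mesh_io import TriMesh, signed_volume

__all__ = ["make_mesh", "make_toy_structures", "write_toy_structures",
           "toy_protein_beads", "water_template_model"]

SHAPES = ("icosphere", "cylinder", "torus", "moebius", "sine_sheet",
          "flat_grid")


def make_mesh(shape: str, **params) -> TriMesh:
    """Build one of the named parametric test meshes.

    shape / params (all lengths nm):

    * ``icosphere`` — ``radius`` (10), ``subdivisions`` (3); closed,
      orientable, 10*4^s + 2 vertices.
    * ``cylinder`` — ``radius`` (5), ``length`` (20), ``n_theta`` (24),
      ``n_z`` (16); closed (capped).
    * ``torus`` — ``R`` (8), ``r`` (3), ``n_u`` (32), ``n_v`` (16); closed.
    * ``moebius`` — ``scale`` (8), ``width`` (0.35 of scale), ``n_u`` (60),
      ``n_v`` (5); nonorientable, one continuous rim.
    * ``sine_sheet`` — ``Lx, Ly`` (20), ``A`` (2), ``m`` (1), ``nx, ny``
      (24); open sheet z = A sin(2 pi m x / Lx).
    * ``flat_grid`` — ``n`` (10), ``spacing`` (1.0); open flat sheet.
    """
    builders = {
        "icosphere": _icosphere, "cylinder": _capped_cylinder,
        "torus": _torus, "moebius": _moebius,
        "sine_sheet": _sine_sheet, "flat_grid": _flat_grid,
    }
    if shape not in builders:
        raise ValueError(f"unknown shape {shape!r}; expected one of {SHAPES}")
    return builders[shape](**params)


# ---------------------------------------------------------------------------
# closed shapes
# ---------------------------------------------------------------------------

def _icosphere(radius: float = 10.0, subdivisions: int = 3) -> TriMesh:
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ], dtype=float)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [v / np.linalg.norm(v) for v in verts]
    for _ in range(subdivisions):
        cache: dict = {}
        new_faces = []

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = verts[a] + verts[b]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    v = np.array(verts) * radius
    L = 2.0 * radius + 6.0
    v = v + L / 2.0
    mesh = TriMesh(v, np.array(faces, dtype=int), np.array([L, L, L]))
    return _outward(mesh)


def _capped_cylinder(radius: float = 5.0, length: float = 20.0,
                     n_theta: int = 24, n_z: int = 16) -> TriMesh:
    if n_theta < 3 or n_z < 1:
        raise ValueError("cylinder needs n_theta >= 3 and n_z >= 1")
    Lxy = 2.0 * radius + 6.0
    cx = cy = Lxy / 2.0
    verts = []
    for j in range(n_z + 1):
        z = length * j / n_z
        for i in range(n_theta):
            th = 2.0 * np.pi * i / n_theta
            verts.append((cx + radius * np.cos(th),
                          cy + radius * np.sin(th), z))
    faces = []
    for j in range(n_z):
        for i in range(n_theta):
            a = j * n_theta + i
            b = j * n_theta + (i + 1) % n_theta
            c = a + n_theta
            d = b + n_theta
            faces += [(a, b, c), (b, d, c)]
    bottom = len(verts)
    verts.append((cx, cy, 0.0))
    top = len(verts)
    verts.append((cx, cy, length))
    for i in range(n_theta):
        b = (i + 1) % n_theta
        faces.append((bottom, b, i))
        base = n_z * n_theta
        faces.append((top, base + i, base + b))
    mesh = TriMesh(np.array(verts), np.array(faces, dtype=int),
                   np.array([Lxy, Lxy, length]))
    return _outward(mesh)


def _torus(R: float = 8.0, r: float = 3.0, n_u: int = 32,
           n_v: int = 16) -> TriMesh:
    if n_u < 3 or n_v < 3:
        raise ValueError("torus needs n_u, n_v >= 3")
    L = 2.0 * (R + r) + 6.0
    c = L / 2.0
    verts = []
    for i in range(n_u):
        u = 2.0 * np.pi * i / n_u
        for j in range(n_v):
            v = 2.0 * np.pi * j / n_v
            verts.append((c + (R + r * np.cos(v)) * np.cos(u),
                          c + (R + r * np.cos(v)) * np.sin(u),
                          c + r * np.sin(v)))
    faces = []
    for i in range(n_u):
        for j in range(n_v):
            a = i * n_v + j
            b = ((i + 1) % n_u) * n_v + j
            a2 = i * n_v + (j + 1) % n_v
            b2 = ((i + 1) % n_u) * n_v + (j + 1) % n_v
            faces += [(a, b, a2), (b, b2, a2)]
    mesh = TriMesh(np.array(verts), np.array(faces, dtype=int),
                   np.array([L, L, L]))
    return _outward(mesh)


def _outward(mesh: TriMesh) -> TriMesh:
    if signed_volume(mesh) < 0:
        mesh.triangles = mesh.triangles[:, ::-1]
    return mesh


# ---------------------------------------------------------------------------
# open / nonorientable shapes
# ---------------------------------------------------------------------------

def _moebius(scale: float = 8.0, width: float | None = None,
             n_u: int = 60, n_v: int = 5) -> TriMesh:
    """(u, v) -> ((1 + v cos(u/2)) cos u, (1 + v cos(u/2)) sin u,
    v sin(u/2)), scaled; the u-wrap glues with v reversed, which is what
    makes the strip one-sided."""
    if n_u < 8 or n_v < 2:
        raise ValueError("moebius needs n_u >= 8 and n_v >= 2")
    w = (0.35 if width is None else width / scale)
    L = 2.0 * scale * (1.0 + w) + 6.0
    c = L / 2.0
    verts = []
    for i in range(n_u):
        u = 2.0 * np.pi * i / n_u
        for j in range(n_v):
            v = -w + 2.0 * w * j / (n_v - 1)
            rad = 1.0 + v * np.cos(u / 2.0)
            verts.append((c + scale * rad * np.cos(u),
                          c + scale * rad * np.sin(u),
                          c + scale * v * np.sin(u / 2.0)))

    def idx(i, j):
        if i < n_u:
            return i * n_v + j
        return n_v - 1 - j          # glue to i = 0 with v reversed

    faces = []
    for i in range(n_u):
        for j in range(n_v - 1):
            a, b = idx(i, j), idx(i + 1, j)
            a2, b2 = idx(i, j + 1), idx(i + 1, j + 1)
            faces += [(a, b, a2), (b, b2, a2)]
    return TriMesh(np.array(verts), np.array(faces, dtype=int),
                   np.array([L, L, L]))


def _sine_sheet(Lx: float = 20.0, Ly: float = 20.0, A: float = 2.0,
                m: int = 1, nx: int = 24, ny: int = 24) -> TriMesh:
    if nx < 2 or ny < 2:
        raise ValueError("sine sheet needs nx, ny >= 2")
    Lz = 2.0 * abs(A) + 10.0
    verts = []
    for i in range(nx):
        x = Lx * i / (nx - 1)
        z = Lz / 2.0 + A * np.sin(2.0 * np.pi * m * x / Lx)
        for j in range(ny):
            verts.append((x, Ly * j / (ny - 1), z))
    faces = _sheet_faces(nx, ny)
    return TriMesh(np.array(verts), np.array(faces, dtype=int),
                   np.array([Lx, Ly, Lz]))


def _flat_grid(n: int = 10, spacing: float = 1.0) -> TriMesh:
    if n < 2:
        raise ValueError("flat grid needs n >= 2")
    L = (n - 1) * spacing
    verts = [(i * spacing, j * spacing, 5.0)
             for i in range(n) for j in range(n)]
    faces = _sheet_faces(n, n)
    return TriMesh(np.array(verts), np.array(faces, dtype=int),
                   np.array([max(L, spacing), max(L, spacing), 10.0]))


def _sheet_faces(nx, ny):
    """CCW-from-above winding: normals point +z."""
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces += [(a, b, a + 1), (b, b + 1, a + 1)]
    return faces


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def toy_protein_beads(seed: int = 0, n_beads: int = 50) -> list:
    """A rigid helical 'protein' of ``n_beads`` backbone beads, centroid at
    the origin, principal axis +z.  Fully deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    t = np.linspace(-2.0, 2.0, n_beads)
    theta = np.linspace(0.0, 6.0 * np.pi, n_beads)
    pos = np.column_stack([0.5 * np.cos(theta), 0.5 * np.sin(theta), t])
    pos = pos + rng.normal(0.0, 0.02, size=pos.shape)
    pos = pos - pos.mean(axis=0)
    return [("BB", p) for p in pos]


def water_template_model(seed: int = 0, edge: float = 3.0,
                         n_side: int = 6) -> MembraneModel:
    """A jittered-grid coarse-grained water cube: ``n_side^3`` single-bead
    W molecules in an ``edge``-nm box (~8 beads/nm^3, the usual 4:1
    coarse-grained water density)."""
    rng = np.random.default_rng(seed)
    spacing = edge / n_side
    residues = []
    for i in range(n_side):
        for j in range(n_side):
            for k in range(n_side):
                p = (np.array([i, j, k]) + 0.5) * spacing
                p = p + rng.uniform(-0.2, 0.2, 3) * spacing
                p = np.clip(p, 0.01, edge - 0.01)
                residues.append(Residue(name="W", beads=[("W", p)]))
    return MembraneModel(residues=residues, box=np.array([edge] * 3),
                         title=f"toy water template (seed {seed})")


def make_toy_structures(seed: int = 0):
    """(mini LIB text, toy protein beads, water template model)."""
    return MINI_LIB_TEXT, toy_protein_beads(seed), water_template_model(seed)


def write_toy_structures(directory, seed: int = 0) -> dict:
    """Write ToyLipids.LIB, toy_protein.gro and water.gro; byte-identical
    for identical seeds.  Returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lib_text, protein, water = make_toy_structures(seed)
    paths = {
        "lib": directory / "ToyLipids.LIB",
        "protein": directory / "toy_protein.gro",
        "water": directory / "water.gro",
    }
    paths["lib"].write_text(lib_text)
    pmodel = MembraneModel(
        residues=[Residue(name="PROT", beads=protein)],
        box=np.array([6.0, 6.0, 8.0]),
        title=f"toy protein (seed {seed})")
    # recenter into the box for a standalone viewable file
    shift = pmodel.box / 2.0
    pmodel.residues[0].beads = [(n, p + shift) for n, p in protein]
    write_gro(pmodel, paths["protein"])
    write_gro(water, paths["water"])
    return paths
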