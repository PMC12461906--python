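"""The point-folder data model: the central currency between surface
discretization and membrane building.

A :class:`PointFolder` holds two leaflets of :class:`SurfacePoint` surface
elements (position, area, normal, principal curvatures/directions, lipid
domain, open-edge flag), plus protein :class:`Inclusion` marks, pore
:class:`Exclusion` marks, and optionally the mesh edge list so geodesic
operations work on reloaded folders.

On disk a point folder is a directory of plain-text files (normative
dialect of this package):

* ``OuterBM.dat`` / ``InnerBM.dat`` — header ``< Point NoPoints N >`` and a
  box line, then one row per point:
  ``id domain area x y z nx ny nz p1x p1y p1z p2x p2y p2z c1 c2 edge``
* ``IncPoint.dat`` — rows ``id type_id point_id ux uy uz`` (in-plane 3D
  orientation, reconstructed to a local 2-vector on load)
* ``ExcPoint.dat`` — rows ``id point_id radius``
* ``Edges.dat`` — ``[ outer ]`` / ``[ inner ]`` sections of
  ``point_id_a point_id_b`` rows

Selection and mutation primitives (:func:`select`, :func:`set_domain`)
never change point count, geometry or leaflet membership; later domain
writes overwrite earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import VertexFrame

__all__ = ["SurfacePoint", "Inclusion", "Exclusion", "PointFolder",
           "PointFolderError", "load", "save", "select", "set_domain",
           "LEAFLETS"]

LEAFLETS = ("outer", "inner")


class PointFolderError(ValueError):
    """Malformed point folder or invalid reference."""


@dataclass
class SurfacePoint:
    """One surface element of a membrane leaflet."""

    id: int
    position: np.ndarray          # nm
    frame: VertexFrame
    leaflet: str                  # outer | inner | mid
    domain: int = 0
    edge: bool = False
    source_vertex: int = -1

    @property
    def mean_curvature(self) -> float:
        return self.frame.mean_curvature

    @property
    def area(self) -> float:
        return self.frame.area


@dataclass
class Inclusion:
    """Abstract protein location: a typed mark on a membrane point with an
    in-plane orientation (unit 2-vector in the point's (t1, t2) basis)."""

    type_id: int
    point_id: int
    orientation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self):
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(2)
        n = np.linalg.norm(self.orientation)
        if n < 1e-12:
            raise PointFolderError("inclusion orientation must be non-zero")
        self.orientation = self.orientation / n


@dataclass
class Exclusion:
    """Abstract membrane hole: a pore of given radius around a point."""

    point_id: int
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise PointFolderError(f"exclusion radius must be > 0, got {self.radius}")


@dataclass
class PointFolder:
    """Outer/inner leaflet point sets + inclusions/exclusions + box."""

    outer: list
    inner: list
    box: np.ndarray
    inclusions: list = field(default_factory=list)
    exclusions: list = field(default_factory=list)
    mesh_edges: dict | None = None   # leaflet -> list[(id, id)]
    excluded_ids: dict = field(default_factory=lambda: {"outer": set(), "inner": set()})

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.validate()

    def leaflet(self, name: str) -> list:
        if name not in LEAFLETS:
            raise PointFolderError(f"unknown leaflet {name!r}; expected {LEAFLETS}")
        return getattr(self, name)

    def points(self, leaflet: str = "both") -> list:
        if leaflet == "both":
            return list(self.outer) + list(self.inner)
        return self.leaflet(leaflet)

    def by_id(self, leaflet: str, pid: int) -> SurfacePoint:
        pts = self.leaflet(leaflet)
        for p in pts:
            if p.id == pid:
                return p
        raise PointFolderError(f"no point id {pid} in {leaflet} leaflet")

    def validate(self) -> None:
        for name in LEAFLETS:
            ids = [p.id for p in self.leaflet(name)]
            if len(ids) != len(set(ids)):
                raise PointFolderError(f"duplicate point ids in {name} leaflet")
        outer_ids = {p.id for p in self.outer}
        for inc in self.inclusions:
            if inc.point_id not in outer_ids:
                raise PointFolderError(
                    f"inclusion references unknown point id {inc.point_id}")
        for exc in self.exclusions:
            if exc.point_id not in outer_ids:
                raise PointFolderError(
                    f"exclusion references unknown point id {exc.point_id}")

    # convenience arrays -------------------------------------------------
    def positions(self, leaflet: str) -> np.ndarray:
        return np.array([p.position for p in self.leaflet(leaflet)]).reshape(-1, 3)

    def mid_position(self, pid: int) -> np.ndarray:
        """Mid-surface position of a point id (mean of the two leaflets)."""
        return 0.5 * (self.by_id("outer", pid).position
                      + self.by_id("inner", pid).position)

    def mid_normal(self, pid: int) -> np.ndarray:
        return self.by_id("outer", pid).frame.normal


# ---------------------------------------------------------------------------
# disk dialect
# ---------------------------------------------------------------------------

def _write_leaflet(points: list, box, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"< Point NoPoints {len(points)} >\n")
        fh.write("< box %.10g %.10g %.10g >\n" % tuple(box))
        fh.write("< id domain area x y z nx ny nz p1x p1y p1z "
                 "p2x p2y p2z c1 c2 edge >\n")
        for p in points:
            f = p.frame
            row = [p.id, p.domain, f.area, *p.position, *f.normal,
                   *f.t1, *f.t2, f.c1, f.c2, int(p.edge)]
            fh.write(" ".join(
                f"{x:.10f}" if isinstance(x, float) else str(int(x))
                for x in row) + "\n")


def _read_leaflet(path: Path, leaflet: str) -> tuple[list, np.ndarray]:
    points = []
    box = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("<"):
                tok = line.strip("<> ").split()
                if tok and tok[0] == "box":
                    box = np.array([float(x) for x in tok[1:4]])
                continue
            t = line.split()
            if len(t) != 18:
                raise PointFolderError(
                    f"{path}: point row needs 18 fields, got {len(t)}")
            vals = [float(x) for x in t]
            frame = VertexFrame(
                normal=np.array(vals[6:9]), t1=np.array(vals[9:12]),
                t2=np.array(vals[12:15]), c1=vals[15], c2=vals[16],
                area=vals[2])
            points.append(SurfacePoint(
                id=int(vals[0]), position=np.array(vals[3:6]), frame=frame,
                leaflet=leaflet, domain=int(vals[1]), edge=bool(int(vals[17])),
                source_vertex=int(vals[0])))
    if box is None:
        raise PointFolderError(f"{path}: missing box header line")
    return points, box


def save(folder: PointFolder, directory) -> None:
    """Write a point folder directory (lossless round-trip to 1e-5 nm)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_leaflet(folder.outer, folder.box, directory / "OuterBM.dat")
    _write_leaflet(folder.inner, folder.box, directory / "InnerBM.dat")
    if folder.inclusions:
        by_id = {p.id: p for p in folder.outer}
        with open(directory / "IncPoint.dat", "w") as fh:
            fh.write(f"< Inclusion NoInc {len(folder.inclusions)} >\n")
            for i, inc in enumerate(folder.inclusions):
                f = by_id[inc.point_id].frame
                u = inc.orientation[0] * f.t1 + inc.orientation[1] * f.t2
                fh.write(f"{i} {inc.type_id} {inc.point_id} "
                         f"{u[0]:.10f} {u[1]:.10f} {u[2]:.10f}\n")
    if folder.exclusions:
        with open(directory / "ExcPoint.dat", "w") as fh:
            fh.write(f"< Exclusion NoExc {len(folder.exclusions)} >\n")
            for i, exc in enumerate(folder.exclusions):
                fh.write(f"{i} {exc.point_id} {exc.radius:.10f}\n")
    if folder.mesh_edges:
        with open(directory / "Edges.dat", "w") as fh:
            for name in LEAFLETS:
                pairs = folder.mesh_edges.get(name, [])
                fh.write(f"[ {name} ]\n")
                for a, b in pairs:
                    fh.write(f"{a} {b}\n")


def load(directory) -> PointFolder:
    """Read a point folder directory.  Missing IncPoint/ExcPoint/Edges files
    yield empty lists; dangling point references are a validation error."""
    directory = Path(directory)
    outer_path = directory / "OuterBM.dat"
    if not outer_path.exists():
        raise PointFolderError(f"{directory}: no OuterBM.dat — not a point folder")
    outer, box = _read_leaflet(outer_path, "outer")
    inner_path = directory / "InnerBM.dat"
    inner, _ = _read_leaflet(inner_path, "inner") if inner_path.exists() else ([], box)

    inclusions = []
    inc_path = directory / "IncPoint.dat"
    if inc_path.exists():
        by_id = {p.id: p for p in outer}
        with open(inc_path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("<"):
                    continue
                t = line.split()
                type_id, pid = int(t[1]), int(t[2])
                u = np.array([float(t[3]), float(t[4]), float(t[5])])
                if pid not in by_id:
                    raise PointFolderError(
                        f"{inc_path}: inclusion references unknown point id {pid}")
                f = by_id[pid].frame
                ori = np.array([u @ f.t1, u @ f.t2])
                if np.linalg.norm(ori) < 1e-9:
                    ori = np.array([1.0, 0.0])
                inclusions.append(Inclusion(type_id, pid, ori))

    exclusions = []
    exc_path = directory / "ExcPoint.dat"
    if exc_path.exists():
        with open(exc_path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("<"):
                    continue
                t = line.split()
                exclusions.append(Exclusion(int(t[1]), float(t[2])))

    mesh_edges = None
    edges_path = directory / "Edges.dat"
    if edges_path.exists():
        mesh_edges = {}
        current = None
        with open(edges_path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("["):
                    current = line.strip("[] ").strip()
                    mesh_edges[current] = []
                elif current is not None:
                    a, b = line.split()[:2]
                    mesh_edges[current].append((int(a), int(b)))

    folder = PointFolder(outer=outer, inner=inner, box=box,
                         inclusions=inclusions, exclusions=exclusions,
                         mesh_edges=mesh_edges)
    if exclusions:
        # pore membership is recomputed from the recorded exclusions rather
        # than persisted, so reload agrees with the original make_pore call
        from .placement import _pore_members
        for exc in exclusions:
            for name in LEAFLETS:
                folder.excluded_ids[name] |= _pore_members(
                    folder, name, exc.point_id, exc.radius)
    return folder


# ---------------------------------------------------------------------------
# selection / mutation
# ---------------------------------------------------------------------------

def select(folder: PointFolder, predicate, leaflet: str = "outer") -> list:
    """Ids (ascending) of points for which ``predicate(point)`` is true.

    The predicate receives a :class:`SurfacePoint` and may inspect position,
    curvature, domain, edge flag or leaflet; selection never mutates.
    """
    return sorted(p.id for p in folder.points(leaflet) if predicate(p))


def set_domain(folder: PointFolder, ids, domain_id: int,
               leaflet: str = "outer") -> PointFolder:
    """Assign ``domain_id`` to exactly the given point ids (in place).

    Later calls overwrite earlier assignments (last write wins), matching
    the behaviour of repeated domain tools on overlapping regions.
    """
    if domain_id < 0:
        raise PointFolderError(f"domain_id must be >= 0, got {domain_id}")
    ids = set(ids)
    if not ids:
        return folder
    names = LEAFLETS if leaflet == "both" else (leaflet,)
    found: set = set()
    for name in names:
        for p in folder.leaflet(name):
            if p.id in ids:
                p.domain = domain_id
                found.add(p.id)
    missing = ids - found
    if missing:
        raise PointFolderError(f"unknown point ids {sorted(missing)[:5]}...")
    return folder
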