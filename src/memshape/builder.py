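"""Membrane building: point folders -> placed beads -> GRO/TOP files.

Supports direct analytical shapes (flat sheet, vesicle, cylinder, sine
sheet) with exact closed-form frames, lipid placement from a template
library (one lipid per surface element, template rotated into the local
frame with a seeded random azimuth spin), protein placement at inclusion
marks with a user z-offset along the local normal, wall beads (virtual
restrained scaffold beads), and fixed-width GRO plus GROMACS topology
serialization.

The produced structure is an overlap-free *initial* configuration: no
relaxation is performed, energy minimization and equilibration are up to
the simulation engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import VertexFrame
from .lipid_lib import LibEntry
from .placement import LipidSpec
from .point_model import PointFolder
from .pointillism import DEFAULT_THICKNESS, leaflet_point

__all__ = ["Residue", "MembraneModel", "ProteinSpec", "analytical_folder",
           "place_lipids", "place_proteins", "wall_beads",
           "write_wall_restraints", "write_gro", "read_gro", "write_top",
           "protein_from_gro", "parse_builder_config"]


@dataclass
class Residue:
    """One molecule instance: named beads at world coordinates (nm)."""

    name: str
    beads: list                      # [(bead_name, np.ndarray(3))]
    anchor: tuple | None = None      # (leaflet, point_id) for lipids

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class MembraneModel:
    """Ordered residues + box, ready for GRO/TOP serialization."""

    residues: list = field(default_factory=list)
    box: np.ndarray = field(default_factory=lambda: np.ones(3))
    title: str = "membrane built by memshape"

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_beads(self) -> int:
        return sum(r.n_beads for r in self.residues)

    @property
    def molecule_counts(self) -> list:
        """(name, count) runs in residue order — the GROMACS [ molecules ]
        contract (consecutive identical molecules merge into one line)."""
        out: list = []
        for r in self.residues:
            if out and out[-1][0] == r.name:
                out[-1][1] += 1
            else:
                out.append([r.name, 1])
        return [(n, c) for n, c in out]

    def positions(self) -> np.ndarray:
        if not self.residues:
            return np.zeros((0, 3))
        return np.concatenate([[p for _, p in r.beads] for r in self.residues])


@dataclass
class ProteinSpec:
    """Placement recipe for one protein type."""

    name: str
    structure: list                  # [(bead_name, np.ndarray(3))] local frame
    z_offset: float = 0.0            # nm along the local membrane normal
    count: int = 1
    collision_radius: float = 0.0    # nm; lipids cleared laterally within it
    type_id: int = 1                 # matches Inclusion.type_id

    def __post_init__(self):
        if not self.structure:
            raise ValueError(f"{self.name}: protein structure has no beads")
        self.structure = [(str(n), np.asarray(p, dtype=float).reshape(3))
                          for n, p in self.structure]


# ---------------------------------------------------------------------------
# analytical shapes
# ---------------------------------------------------------------------------

def _grid_edges(nx: int, ny: int, wrap_x: bool = False):
    """Right/up/diagonal adjacency of an nx*ny grid (ids = i*ny + j)."""
    edges = []
    for i in range(nx):
        for j in range(ny):
            a = i * ny + j
            ip = i + 1
            if ip < nx or wrap_x:
                edges.append((a, (ip % nx) * ny + j))
            if j + 1 < ny:
                edges.append((a, a + 1))
            if (ip < nx or wrap_x) and j + 1 < ny:
                edges.append((a, (ip % nx) * ny + j + 1))
                edges.append((a + 1, (ip % nx) * ny + j))
    return edges


def analytical_folder(kind: str, params: dict, apl_hint: float = 0.64,
                      thickness: float = DEFAULT_THICKNESS) -> PointFolder:
    """Generate a point folder for an analytical shape with exact frames.

    kind/params:

    * ``flat`` — ``Lx, Ly`` (optional ``Lz``); square grid of spacing
      ~sqrt(apl_hint), H = 0 everywhere.
    * ``vesicle`` — ``R``; Fibonacci sphere with N = round(4 pi R^2 / apl),
      per-point area exactly 4 pi R^2 / N, c1 = c2 = 1/R.
    * ``cylinder`` — ``R, L``; wrapped grid, (c1, c2) = (1/R, 0), open ends.
    * ``sine`` — ``Lx, Ly, A, m`` (amplitude nm, periods); height
      z = A sin(2 pi m x / Lx) with exact parametric curvature and
      metric-corrected per-point areas.

    Grid spacings are rounded to fit the box; when the realized area per
    point differs from ``apl_hint`` it is reported in a warning.
    """
    if apl_hint <= 0:
        raise ValueError("apl_hint must be > 0")
    half = thickness / 2.0
    s = np.sqrt(apl_hint)

    if kind == "flat":
        return _sheet_folder(params["Lx"], params["Ly"],
                             params.get("Lz", 10.0 + 2 * thickness),
                             0.0, 1, s, half)
    if kind == "sine":
        return _sheet_folder(params["Lx"], params["Ly"],
                             params.get("Lz", 10.0 + 2 * thickness
                                        + 2 * abs(params.get("A", 0.0))),
                             params.get("A", 0.0), params.get("m", 1), s, half)
    if kind == "vesicle":
        return _vesicle_folder(params["R"], apl_hint, half, thickness)
    if kind == "cylinder":
        return _cylinder_folder(params["R"], params["L"], s, half, thickness)
    raise ValueError(f"unknown analytical shape {kind!r}; "
                     "expected flat|vesicle|cylinder|sine")


def _sheet_folder(Lx, Ly, Lz, A, m, s, half) -> PointFolder:
    nx = max(1, round(Lx / s))
    ny = max(1, round(Ly / s))
    sx, sy = Lx / nx, Ly / ny
    realized = sx * sy
    if abs(realized - s * s) / (s * s) > 1e-9:
        warnings.warn(f"grid rounded to {nx}x{ny}: realized area per point "
                      f"{realized:.4f} nm^2 (requested {s * s:.4f})")
    z0 = Lz / 2.0
    omega = 2.0 * np.pi * m / Lx
    outer, inner = [], []
    pid = 0
    for i in range(nx):
        x = (i + 0.5) * sx
        fp = A * omega * np.cos(omega * x)       # dz/dx
        fpp = -A * omega * omega * np.sin(omega * x)
        met = np.sqrt(1.0 + fp * fp)
        cx = -fpp / met ** 3                      # crest (+H), valley (-H)
        n = np.array([-fp, 0.0, 1.0]) / met
        tx = np.array([1.0, 0.0, fp]) / met
        ty = np.array([0.0, 1.0, 0.0])
        if cx >= 0:
            c1, c2, t1, t2 = cx, 0.0, tx, ty
        else:
            c1, c2, t1, t2 = 0.0, cx, ty, -tx    # keep right-handed frame
        for j in range(ny):
            y = (j + 0.5) * sy
            mid = np.array([x, y, z0 + A * np.sin(omega * x)])
            frame = VertexFrame(normal=n.copy(), t1=t1.copy(), t2=t2.copy(),
                                c1=c1, c2=c2, area=realized * met)
            edge = i in (0, nx - 1) or j in (0, ny - 1)
            outer.append(leaflet_point(pid, mid, frame, +half, "outer", edge=edge))
            inner.append(leaflet_point(pid, mid, frame, -half, "inner", edge=edge))
            pid += 1
    return PointFolder(outer=outer, inner=inner, box=np.array([Lx, Ly, Lz]),
                       mesh_edges={"outer": _grid_edges(nx, ny),
                                   "inner": _grid_edges(nx, ny)})


def _vesicle_folder(R, apl, half, thickness) -> PointFolder:
    n = max(12, round(4.0 * np.pi * R * R / apl))
    area = 4.0 * np.pi * R * R / n
    L = 2.0 * (R + thickness) + 4.0
    center = np.full(3, L / 2.0)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    outer, inner = [], []
    for i in range(n):
        z = 1.0 - 2.0 * (i + 0.5) / n
        r = np.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * i
        normal = np.array([r * np.cos(phi), r * np.sin(phi), z])
        t1 = _orthogonal(normal)
        t2 = np.cross(normal, t1)
        frame = VertexFrame(normal=normal, t1=t1, t2=t2,
                            c1=1.0 / R, c2=1.0 / R, area=area)
        mid = center + R * normal
        outer.append(leaflet_point(i, mid, frame, +half, "outer"))
        inner.append(leaflet_point(i, mid, frame, -half, "inner"))
    return PointFolder(outer=outer, inner=inner, box=np.array([L, L, L]))


def _cylinder_folder(R, L, s, half, thickness) -> PointFolder:
    nc = max(3, round(2.0 * np.pi * R / s))
    nz = max(1, round(L / s))
    area = (2.0 * np.pi * R / nc) * (L / nz)
    box = np.array([2.0 * (R + thickness) + 4.0,
                    2.0 * (R + thickness) + 4.0, L])
    cxy = box[:2] / 2.0
    outer, inner = [], []
    pid = 0
    for i in range(nc):
        th = 2.0 * np.pi * (i + 0.5) / nc
        normal = np.array([np.cos(th), np.sin(th), 0.0])
        t1 = np.array([-np.sin(th), np.cos(th), 0.0])   # circumferential, c = 1/R
        t2 = np.cross(normal, t1)                        # axial, c = 0
        for j in range(nz):
            z = (j + 0.5) * L / nz
            mid = np.array([cxy[0] + R * normal[0], cxy[1] + R * normal[1], z])
            frame = VertexFrame(normal=normal.copy(), t1=t1.copy(),
                                t2=t2.copy(), c1=1.0 / R, c2=0.0, area=area)
            edge = j in (0, nz - 1)
            outer.append(leaflet_point(pid, mid, frame, +half, "outer", edge=edge))
            inner.append(leaflet_point(pid, mid, frame, -half, "inner", edge=edge))
            pid += 1
    return PointFolder(outer=outer, inner=inner, box=box,
                       mesh_edges={"outer": _grid_edges(nc, nz, wrap_x=True),
                                   "inner": _grid_edges(nc, nz, wrap_x=True)})


def _orthogonal(n: np.ndarray) -> np.ndarray:
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t = seed - n * (seed @ n)
    return t / np.linalg.norm(t)


# ---------------------------------------------------------------------------
# placement into 3D
# ---------------------------------------------------------------------------

def place_lipids(folder: PointFolder, lib: dict, domain_map: dict,
                 seed: int | None = None) -> MembraneModel:
    """One lipid per non-excluded point, rotated into the point frame.

    ``domain_map`` maps domain id -> :class:`~memshape.placement.LipidSpec`
    (or plain lipid name).  Template beads (head toward local +z) are spun
    by a seeded random azimuth, rotated (z -> normal, x -> t1) and
    translated onto the point.  Residues are emitted grouped by lipid type
    in ``domain_map`` order so the topology stays compact.
    """
    rng = np.random.default_rng(seed)
    specs: dict = {}
    for d, v in domain_map.items():
        specs[d] = v if isinstance(v, LipidSpec) else LipidSpec(
            name=str(v), fraction=1.0, apl=1.0)

    present = set()
    for name in ("outer", "inner"):
        for p in folder.leaflet(name):
            if p.id not in folder.excluded_ids.get(name, set()):
                present.add(p.domain)
    unmapped = present - set(specs)
    if unmapped:
        raise ValueError(f"domains {sorted(unmapped)} present in the folder "
                         "but missing from the domain map")
    for d, spec in specs.items():
        if spec.name not in lib:
            raise KeyError(f"lipid {spec.name!r} (domain {d}) not in library")

    model = MembraneModel(box=folder.box.copy())
    apl_warn = 0
    for d in specs:                      # domain_map insertion order
        spec = specs[d]
        entry: LibEntry = lib[spec.name]
        for leaflet in ("outer", "inner"):
            excl = folder.excluded_ids.get(leaflet, set())
            for p in sorted(folder.leaflet(leaflet), key=lambda q: q.id):
                if p.domain != d or p.id in excl:
                    continue
                if spec.apl > 0 and abs(p.area - spec.apl) / spec.apl > 0.20:
                    apl_warn += 1
                psi = rng.uniform(0.0, 2.0 * np.pi)
                f = p.frame
                ex = np.cos(psi) * f.t1 + np.sin(psi) * f.t2
                ey = -np.sin(psi) * f.t1 + np.cos(psi) * f.t2
                R = np.column_stack([ex, ey, f.normal])
                beads = [(bn, p.position + R @ bp) for bn, bp in entry.beads]
                model.residues.append(Residue(name=spec.name, beads=beads,
                                              anchor=(leaflet, p.id)))
    if apl_warn:
        warnings.warn(f"{apl_warn} points deviate >20% from their lipid's "
                      "area per lipid; consider adjusting mesh density")
    return model


def place_proteins(model: MembraneModel, folder: PointFolder,
                   specs: list, seed: int | None = None) -> MembraneModel:
    """Place protein copies at inclusion marks and clear overlapping lipids.

    Each copy is translated so its geometric center sits at the inclusion's
    mid-surface position plus ``z_offset`` along the local normal
    (``z_offset = 0`` puts the center in the middle of the membrane), and
    rotated so the structure's +z aligns with the normal and its +x with
    the inclusion's in-plane orientation.  Lipids anchored laterally within
    ``collision_radius`` of the inclusion are removed.  No relaxation is
    performed; structures wider than the cleared patch only warn.
    """
    rng = np.random.default_rng(seed)
    for spec in specs:
        incs = [i for i in folder.inclusions if i.type_id == spec.type_id]
        if len(incs) < spec.count:
            # random fallback for unmarked copies
            from .placement import inu_place
            missing = spec.count - len(incs)
            inu_place(folder, spec.type_id, missing, c0=0.0, k=0.0,
                      collision_radius=spec.collision_radius,
                      seed=int(rng.integers(2 ** 31)))
            incs = [i for i in folder.inclusions if i.type_id == spec.type_id]
        local = np.array([p for _, p in spec.structure])
        local = local - local.mean(axis=0)
        extent = np.linalg.norm(local[:, :2], axis=1).max() if len(local) else 0.0
        if spec.collision_radius and extent > spec.collision_radius:
            warnings.warn(f"{spec.name}: lateral extent {extent:.2f} nm exceeds "
                          f"collision radius {spec.collision_radius:.2f} nm; "
                          "placed as-is (no relaxation)")
        for inc in incs[: spec.count]:
            p = folder.by_id("outer", inc.point_id)
            mid = folder.mid_position(inc.point_id)
            f = p.frame
            x = inc.orientation[0] * f.t1 + inc.orientation[1] * f.t2
            y = np.cross(f.normal, x)
            R = np.column_stack([x, y, f.normal])
            center = mid + spec.z_offset * f.normal
            beads = [(spec.structure[b][0], center + R @ local[b])
                     for b in range(len(local))]
            if spec.collision_radius > 0:
                model.residues = [
                    r for r in model.residues
                    if not _anchor_within(r, folder, mid, f.normal,
                                          spec.collision_radius)]
            model.residues.append(Residue(name=spec.name, beads=beads))
    return model


def _anchor_within(res: Residue, folder: PointFolder, mid, normal,
                   radius: float) -> bool:
    if res.anchor is None:
        return False
    leaflet, pid = res.anchor
    delta = folder.by_id(leaflet, pid).position - mid
    along = delta @ normal
    lateral = np.linalg.norm(delta - along * normal)
    # lateral clearance only; the normal window keeps antipodal membrane
    # regions (far side of a vesicle) out of reach
    return lateral <= radius and abs(along) <= 2.0 * DEFAULT_THICKNESS


def wall_beads(folder: PointFolder, spacing_stride: int = 1):
    """Virtual scaffold beads on every ``spacing_stride``-th mid-surface
    point, for use with position restraints that freeze the geometry.

    Returns ``(beads, indices)``: bead list ``[(name, position)]`` and the
    1-based indices (into that list) to restrain — all of them.
    """
    ids = sorted(p.id for p in folder.leaflet("outer"))
    if spacing_stride >= len(ids):
        warnings.warn("stride covers the whole folder; emitting a single wall bead")
        ids = ids[:1]
    else:
        ids = ids[::spacing_stride]
    beads = [("WL", folder.mid_position(pid)) for pid in ids]
    indices = list(range(1, len(beads) + 1))
    return beads, indices


def write_wall_restraints(indices, ndx_path, itp_path,
                          force_constant: float = 1000.0) -> None:
    """Index group + position-restraint stanza template for wall beads."""
    with open(ndx_path, "w") as fh:
        fh.write("[ WALL ]\n")
        for i in range(0, len(indices), 15):
            fh.write(" ".join(str(j) for j in indices[i:i + 15]) + "\n")
    with open(itp_path, "w") as fh:
        fh.write("[ position_restraints ]\n")
        fh.write("; ai  funct  fcx  fcy  fcz\n")
        for j in indices:
            fh.write(f"{j:6d}  1  {force_constant:g}  {force_constant:g}  "
                     f"{force_constant:g}\n")


# ---------------------------------------------------------------------------
# GRO / TOP
# ---------------------------------------------------------------------------

def _clip_name(name: str, what: str) -> str:
    if len(name) > 5:
        warnings.warn(f"{what} name {name!r} longer than 5 chars; truncated")
        return name[:5]
    return name


def write_gro(model: MembraneModel, path) -> None:
    """Fixed-width GRO: ``%5d%-5s%5s%5d%8.3f%8.3f%8.3f`` per atom, residue
    and atom numbers wrapping modulo 100000, free-format box line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(model.title + "\n")
        fh.write(f"{model.n_beads:5d}\n")
        atom = 0
        for resnum, res in enumerate(model.residues, start=1):
            rname = _clip_name(res.name, "residue")
            for bead_name, pos in res.beads:
                atom += 1
                bname = _clip_name(bead_name, "atom")
                fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n" % (
                    resnum % 100000, rname, bname, atom % 100000,
                    pos[0], pos[1], pos[2]))
        fh.write("%10.5f%10.5f%10.5f\n" % tuple(model.box))


def read_gro(path) -> MembraneModel:
    """Inverse of :func:`write_gro` within 0.001 nm; consecutive atoms with
    the same (residue number, residue name) form one residue."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: not a GRO file (fewer than 3 lines)")
    title = lines[0]
    n = int(lines[1].strip())
    residues: list = []
    key = None
    for line in lines[2:2 + n]:
        resnum = int(line[0:5])
        resname = line[5:10].strip()
        atomname = line[10:15].strip()
        pos = np.array([float(line[20:28]), float(line[28:36]),
                        float(line[36:44])])
        if (resnum, resname) != key:
            residues.append(Residue(name=resname, beads=[]))
            key = (resnum, resname)
        residues[-1].beads.append((atomname, pos))
    box_tokens = lines[2 + n].split()
    box = np.array([float(x) for x in box_tokens[:3]])
    return MembraneModel(residues=residues, box=box, title=title)


def write_top(model: MembraneModel, path, includes=(),
              system_name: str = "memshape membrane") -> None:
    """GROMACS topology: ``[ molecules ]`` in first-appearance order with
    exact counts.  Refuses an empty model or count/bead inconsistency."""
    if not model.residues:
        raise ValueError("refusing to write topology for an empty model")
    counts = model.molecule_counts
    total = sum(c for _, c in counts)
    if total != len(model.residues):
        raise ValueError("molecule counts inconsistent with residues")
    with open(path, "w") as fh:
        for inc in includes:
            fh.write(f'#include "{inc}"\n')
        if includes:
            fh.write("\n")
        fh.write("[ system ]\n")
        fh.write(f"{system_name}\n\n")
        fh.write("[ molecules ]\n")
        for name, count in counts:
            fh.write(f"{name:<10s} {count}\n")


def protein_from_gro(path) -> list:
    """Bead list of a (single-molecule) protein structure file, centered at
    its geometric center, frame taken as-is (+z = placement direction)."""
    model = read_gro(path)
    beads = [(n, p) for r in model.residues for n, p in r.beads]
    center = np.mean([p for _, p in beads], axis=0)
    return [(n, p - center) for n, p in beads]


# ---------------------------------------------------------------------------
# builder configuration ("input.str" analog)
# ---------------------------------------------------------------------------

def parse_builder_config(path):
    """INI-like builder config.

    ``[Lipids List]`` rows: ``name fraction apl c0 k``;
    ``[Protein List]`` rows: ``name count z_offset collision_radius``.
    Returns (list of LipidSpec, list of protein dicts).
    """
    lipids: list = []
    proteins: list = []
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] ").strip().lower()
                continue
            tok = line.split()
            if section == "lipids list":
                if len(tok) != 5:
                    raise ValueError(f"{path}:{lineno}: lipid row needs "
                                     "'name fraction apl c0 k'")
                lipids.append(LipidSpec(
                    name=tok[0], fraction=float(tok[1]), apl=float(tok[2]),
                    c0=float(tok[3]), k=float(tok[4]),
                    domain_id=len(lipids)))
            elif section == "protein list":
                if len(tok) != 4:
                    raise ValueError(f"{path}:{lineno}: protein row needs "
                                     "'name count z_offset collision_radius'")
                proteins.append({"name": tok[0], "count": int(tok[1]),
                                 "z_offset": float(tok[2]),
                                 "collision_radius": float(tok[3])})
            else:
                raise ValueError(f"{path}:{lineno}: row outside a known section")
    return lipids, proteins
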