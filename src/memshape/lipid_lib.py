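"""Lipid template library: bead templates in a local frame.

A library entry stores one lipid's beads in a local coordinate system with
the head group toward +z and the origin at the template centroid; the
builder rotates this template into each surface element's frame.  The LIB
text dialect is::

    [ NAME ]
    bead <bead_name> <x> <y> <z>
    <blank line terminates the entry>

Head identification follows the coarse-grained convention that the first
bead in file order is the head group.  ``libmaker`` generates an entry from
a single-lipid structure file by centering the bead cloud and aligning its
principal axis with +z (sign chosen so the head bead ends up on top).

A bundled Martini-3-style mini library (POPC/DLPC/CDL/CHOL-like toy
templates — geometric stand-ins with plausible bead counts, not validated
chemistry) backs tests and tutorials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["LibEntry", "parse_lib", "parse_lib_text", "write_lib",
           "libmaker", "default_library", "MINI_LIB_TEXT"]


@dataclass
class LibEntry:
    """One lipid template: ordered beads with local coordinates (nm)."""

    name: str
    beads: list            # [(bead_name, np.ndarray(3))]
    head_index: int = 0
    charge_note: str = ""

    def __post_init__(self):
        if not self.beads:
            raise ValueError(f"{self.name}: template needs at least one bead")
        self.beads = [(str(n), np.asarray(p, dtype=float).reshape(3))
                      for n, p in self.beads]

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def positions(self) -> np.ndarray:
        return np.array([p for _, p in self.beads]).reshape(-1, 3)


def parse_lib_text(text: str, source: str = "<string>") -> dict:
    """Parse LIB text into a name -> :class:`LibEntry` map."""
    entries: dict = {}
    name = None
    beads: list = []

    def flush():
        nonlocal name, beads
        if name is not None:
            if name in entries:
                warnings.warn(f"{source}: duplicate entry {name!r}; last wins")
            if beads:
                entries[name] = LibEntry(name=name, beads=beads)
            else:
                warnings.warn(f"{source}: entry {name!r} has no beads; skipped")
        name, beads = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            flush()
            continue
        if line.startswith("["):
            flush()
            name = line.strip("[] ").strip()
            continue
        tok = line.split()
        if tok[0] != "bead" or len(tok) != 5:
            raise ValueError(
                f"{source}:{lineno}: expected 'bead <name> <x> <y> <z>', "
                f"got {raw.strip()!r}")
        if name is None:
            raise ValueError(f"{source}:{lineno}: bead line outside any [ NAME ] entry")
        beads.append((tok[1], np.array([float(tok[2]), float(tok[3]),
                                        float(tok[4])])))
    flush()
    if not entries:
        warnings.warn(f"{source}: empty lipid library")
    return entries


def parse_lib(path) -> dict:
    """Read a LIB file into a name -> :class:`LibEntry` map."""
    path = Path(path)
    return parse_lib_text(path.read_text(), source=str(path))


def write_lib(entries: dict, path) -> None:
    with open(path, "w") as fh:
        for name, entry in entries.items():
            fh.write(f"[ {name} ]\n")
            for bead_name, p in entry.beads:
                fh.write(f"bead {bead_name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write("\n")


def libmaker(gro_path) -> LibEntry:
    """Build a library entry from a single-lipid structure file.

    The bead cloud is translated to its centroid and rotated so its
    principal axis lies along +z, with the sign chosen so the first bead
    (the head, by convention) sits at z >= 0.  Multi-residue files are an
    error: extract one lipid first.
    """
    from .builder import read_gro
    model = read_gro(gro_path)
    residues = {r.name for r in model.residues}
    if len(model.residues) != 1:
        raise ValueError(
            f"{gro_path}: expected exactly one residue, found "
            f"{len(model.residues)} ({sorted(residues)}) — extract one lipid")
    res = model.residues[0]
    names = [b[0] for b in res.beads]
    pos = np.array([b[1] for b in res.beads]).reshape(-1, 3)
    pos = pos - pos.mean(axis=0)
    if len(pos) > 1:
        cov = np.cov(pos.T)
        w, vecs = np.linalg.eigh(cov)
        axis = vecs[:, np.argmax(w)]          # principal axis
        second = vecs[:, np.argsort(w)[-2]]
        z = axis / np.linalg.norm(axis)
        if pos[0] @ z < 0:                    # head on top
            z = -z
        x = second - z * (second @ z)
        nx = np.linalg.norm(x)
        x = x / nx if nx > 1e-12 else _any_orthogonal(z)
        y = np.cross(z, x)
        R = np.column_stack([x, y, z])        # world -> local: p @ R
        pos = pos @ R
    return LibEntry(name=res.name, beads=list(zip(names, pos)))


def _any_orthogonal(z: np.ndarray) -> np.ndarray:
    seed = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = seed - z * (seed @ z)
    return x / np.linalg.norm(x)


# ---------------------------------------------------------------------------
# bundled mini library (toy geometry, head bead first, head toward +z)
# ---------------------------------------------------------------------------

MINI_LIB_TEXT = """\
; Martini-3-style toy templates: head bead first, +z = head direction,
; coordinates in nm around the template centroid.  Geometry only.
[ POPC ]
bead NC3 0.00 0.00 1.05
bead PO4 0.00 0.00 0.75
bead GL1 0.00 0.12 0.45
bead GL2 0.00 -0.12 0.45
bead C1A 0.00 0.12 0.15
bead C2A 0.00 0.12 -0.15
bead C3A 0.00 0.12 -0.45
bead C4A 0.00 0.12 -0.75
bead C1B 0.00 -0.12 0.15
bead C2B 0.00 -0.12 -0.15
bead C3B 0.00 -0.12 -0.45
bead C4B 0.00 -0.12 -0.75

[ DLPC ]
bead NC3 0.00 0.00 0.75
bead PO4 0.00 0.00 0.45
bead GL1 0.00 0.12 0.15
bead GL2 0.00 -0.12 0.15
bead C1A 0.00 0.12 -0.15
bead C2A 0.00 0.12 -0.45
bead C1B 0.00 -0.12 -0.15
bead C2B 0.00 -0.12 -0.45

[ CDL2 ]
bead GL0 0.00 0.00 0.90
bead PO41 0.15 0.00 0.65
bead PO42 -0.15 0.00 0.65
bead GL11 0.15 0.10 0.35
bead GL21 0.15 -0.10 0.35
bead GL12 -0.15 0.10 0.35
bead GL22 -0.15 -0.10 0.35
bead C1A1 0.15 0.10 0.05
bead C2A1 0.15 0.10 -0.25
bead C1B1 0.15 -0.10 0.05
bead C2B1 0.15 -0.10 -0.25
bead C1A2 -0.15 0.10 0.05
bead C2A2 -0.15 0.10 -0.25
bead C1B2 -0.15 -0.10 0.05
bead C2B2 -0.15 -0.10 -0.25

[ CHOL ]
bead ROH 0.00 0.00 0.55
bead R1 0.00 0.05 0.25
bead R2 0.00 -0.05 0.25
bead R3 0.00 0.05 -0.05
bead R4 0.00 -0.05 -0.05
bead C1 0.00 0.00 -0.35
bead C2 0.00 0.00 -0.60
"""


def default_library() -> dict:
    """The bundled mini library, parsed fresh on each call."""
    return parse_lib_text(MINI_LIB_TEXT, source="bundled mini library")
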