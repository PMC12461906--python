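"""Solvent propagation and ion placement.

Tiles a small equilibrated water box across the system box (clipping at the
boundary), deletes solvent residues that come within a user cutoff of any
existing bead under the periodic minimum-image metric, and replaces seeded
random surviving solvent residues one-for-one with ions.  The neighbor
search uses a KD-tree with periodic wrapping; the quadratic brute-force
audit lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .builder import MembraneModel, Residue, read_gro

__all__ = ["SolventTemplate", "solvent_template_from_gro", "solvate_box"]


@dataclass
class SolventTemplate:
    """An equilibrated small water box: residues of beads inside ``box``."""

    residues: list               # [(res_name, [(bead_name, pos nm)])]
    box: np.ndarray

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError(f"template box must be positive, got {self.box}")
        for name, beads in self.residues:
            for _, p in beads:
                if np.any(p < -1e-9) or np.any(p > self.box + 1e-9):
                    raise ValueError(
                        f"template bead of {name} at {p} outside box {self.box}")

    @property
    def n_beads(self) -> int:
        return sum(len(b) for _, b in self.residues)


def solvent_template_from_gro(path) -> SolventTemplate:
    model = read_gro(path)
    residues = [(r.name, list(r.beads)) for r in model.residues]
    return SolventTemplate(residues=residues, box=model.box)


def solvate_box(model: MembraneModel, template: SolventTemplate,
                cutoff: float, ions=(), seed: int | None = None
                ) -> MembraneModel:
    """Fill ``model.box`` with solvent from ``template``; place ions.

    The template is tiled ceil(L/l) times per axis and clipped to the box;
    a solvent residue is dropped when any of its beads lies within
    ``cutoff`` of an existing bead (periodic metric).  Each requested ion
    replaces one randomly chosen surviving solvent residue at its first
    bead's position.  Solvent molecules are appended to the model first,
    then ions, so the topology order is solvent, then ions.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    box = model.box
    reps = np.ceil(box / template.box).astype(int)

    candidates: list = []        # (res_name, [(bead_name, pos)])
    for ix in range(reps[0]):
        for iy in range(reps[1]):
            for iz in range(reps[2]):
                shift = np.array([ix, iy, iz]) * template.box
                for name, beads in template.residues:
                    moved = [(bn, p + shift) for bn, p in beads]
                    if all(np.all(p < box) for _, p in moved):
                        candidates.append((name, moved))

    solute = model.positions()
    if len(solute) and candidates:
        tree = cKDTree(np.mod(solute, box), boxsize=box)
        kept = []
        for name, beads in candidates:
            pos = np.mod(np.array([p for _, p in beads]), box)
            d, _ = tree.query(pos, k=1, distance_upper_bound=cutoff)
            if np.all(np.isinf(d)):
                kept.append((name, beads))
        candidates = kept

    rng = np.random.default_rng(seed)
    n_ions = sum(int(c) for _, c in ions)
    if n_ions > len(candidates):
        raise ValueError(
            f"requested {n_ions} ions but only {len(candidates)} solvent "
            "molecules survive the cutoff")
    ion_slots = sorted(rng.choice(len(candidates), size=n_ions,
                                  replace=False).tolist()) if n_ions else []
    taken = set(ion_slots)

    for i, (name, beads) in enumerate(candidates):
        if i in taken:
            continue
        model.residues.append(Residue(name=name, beads=beads))
    slot_idx = 0
    for ion_name, count in ions:
        for _ in range(int(count)):
            slot = ion_slots[slot_idx]
            slot_idx += 1
            _, beads = candidates[slot]
            model.residues.append(
                Residue(name=str(ion_name), beads=[(str(ion_name)[:5],
                                                    beads[0][1])]))
    return model
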