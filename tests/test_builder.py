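import numpy as np
import pytest
from scipy.spatial import cKDTree

import memshape as ms
from memshape.builder import Residue, parse_builder_config, \
    write_wall_restraints
from memshape.fixtures import toy_protein_beads
from memshape.placement import LipidSpec


# ---------------------------------------------------------------------------
# analytical shapes
# ---------------------------------------------------------------------------

def test_flat_grid_dimensions(flat_folder):
    # 16 / sqrt(0.64) = 20 per side
    assert len(flat_folder.outer) == 400
    areas = {round(p.area, 9) for p in flat_folder.outer}
    assert areas == {0.64}


def test_vesicle_area_exact():
    R = 10.0
    folder = ms.analytical_folder("vesicle", {"R": R}, apl_hint=0.64)
    n = round(4 * np.pi * R * R / 0.64)
    assert len(folder.outer) == n
    mid_area = n * (4 * np.pi * R * R / n)
    assert mid_area == pytest.approx(4 * np.pi * R * R)
    for p in folder.outer[::97]:
        assert p.frame.c1 == pytest.approx(1 / (R + 1.9))


def test_cylinder_folder_curvature():
    folder = ms.analytical_folder("cylinder", {"R": 5.0, "L": 20.0},
                                  apl_hint=0.64)
    half = 1.9
    for p in folder.outer[::53]:
        assert p.frame.c1 == pytest.approx(1 / (5.0 + half))
        assert p.frame.c2 == pytest.approx(0.0)


def test_sine_zero_amplitude_is_flat():
    sine = ms.analytical_folder("sine", {"Lx": 16.0, "Ly": 16.0,
                                         "A": 0.0, "m": 3}, apl_hint=0.64)
    flat = ms.analytical_folder("flat", {"Lx": 16.0, "Ly": 16.0},
                                apl_hint=0.64)
    assert len(sine.outer) == len(flat.outer)
    for p in sine.outer:
        assert p.mean_curvature == 0.0
    np.testing.assert_allclose(sine.positions("outer")[:, 2],
                               flat.positions("outer")[:, 2], atol=1e-12)


def test_noncommensurate_apl_warns():
    with pytest.warns(UserWarning, match="realized area per point"):
        ms.analytical_folder("flat", {"Lx": 10.0, "Ly": 10.0}, apl_hint=0.9)


# ---------------------------------------------------------------------------
# lipid placement
# ---------------------------------------------------------------------------

def test_single_point_single_lipid(mini_lib):
    folder = ms.analytical_folder("flat", {"Lx": 1.0, "Ly": 1.0},
                                  apl_hint=1.0)
    folder.inner.clear()
    model = ms.place_lipids(folder, mini_lib,
                            {0: LipidSpec("CHOL", 1.0, 0.4)}, seed=0)
    assert len(model.residues) == 1
    assert model.n_beads == mini_lib["CHOL"].n_beads


def test_flat_bilayer_head_tail_order(flat_folder, mini_lib):
    model = ms.place_lipids(flat_folder, mini_lib,
                            {0: LipidSpec("POPC", 1.0, 0.64)}, seed=2)
    mid_z = flat_folder.box[2] / 2.0
    for res in model.residues:
        leaflet, _ = res.anchor
        head_z = res.beads[0][1][2]
        tail_z = res.beads[-1][1][2]
        if leaflet == "outer":
            assert head_z > tail_z > mid_z - 0.01
        else:
            assert head_z < tail_z < mid_z + 0.01


def test_unmapped_domain_error(flat_folder, mini_lib):
    ms.set_domain(flat_folder, [5, 6], 3)
    with pytest.raises(ValueError, match=r"\[3\]"):
        ms.place_lipids(flat_folder, mini_lib,
                        {0: LipidSpec("POPC", 1.0, 0.64)}, seed=0)


def test_apl_mismatch_warns(flat_folder, mini_lib):
    with pytest.warns(UserWarning, match="deviate >20%"):
        ms.place_lipids(flat_folder, mini_lib,
                        {0: LipidSpec("CDL2", 1.0, 1.2)}, seed=0)


# ---------------------------------------------------------------------------
# protein placement
# ---------------------------------------------------------------------------

def _protein_spec(z_offset, radius=1.5):
    return ms.ProteinSpec(name="PROT", structure=toy_protein_beads(),
                          z_offset=z_offset, count=1,
                          collision_radius=radius, type_id=1)


@pytest.mark.parametrize("z_offset", [0.0, 5.0])
def test_protein_z_offset(flat_folder, mini_lib, z_offset):
    ms.inu_place(flat_folder, 1, 1, seed=9)
    model = ms.place_lipids(flat_folder, mini_lib,
                            {0: LipidSpec("POPC", 1.0, 0.64)}, seed=1)
    model = ms.place_proteins(model, flat_folder, [_protein_spec(z_offset)])
    prot = [r for r in model.residues if r.name == "PROT"][0]
    center = np.mean([p for _, p in prot.beads], axis=0)
    mid = flat_folder.mid_position(flat_folder.inclusions[0].point_id)
    assert center[2] == pytest.approx(mid[2] + z_offset, abs=1e-3)


def test_protein_clears_lipids(flat_folder, mini_lib):
    ms.inu_place(flat_folder, 1, 1, seed=9)
    model = ms.place_lipids(flat_folder, mini_lib,
                            {0: LipidSpec("POPC", 1.0, 0.64)}, seed=1)
    n_before = len(model.residues)
    radius = 2.0
    model = ms.place_proteins(model, flat_folder, [_protein_spec(0.0, radius)])
    mid = flat_folder.mid_position(flat_folder.inclusions[0].point_id)
    lipids = [r for r in model.residues if r.name == "POPC"]
    assert len(lipids) < n_before
    for r in lipids:
        leaflet, pid = r.anchor
        delta = flat_folder.by_id(leaflet, pid).position - mid
        assert np.linalg.norm(delta[:2]) > radius


def test_protein_random_fallback(flat_folder, mini_lib):
    # no inclusions marked: placement falls back to seeded random points
    model = ms.place_lipids(flat_folder, mini_lib,
                            {0: LipidSpec("POPC", 1.0, 0.64)}, seed=1)
    spec = ms.ProteinSpec(name="PROT", structure=toy_protein_beads(),
                          count=2, collision_radius=3.0, type_id=1)
    model = ms.place_proteins(model, flat_folder, [spec], seed=5)
    assert sum(1 for r in model.residues if r.name == "PROT") == 2
    assert len(flat_folder.inclusions) == 2


# ---------------------------------------------------------------------------
# wall beads
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("stride,expected", [(1, 400), (4, 100), (7, 58)])
def test_wall_bead_stride(flat_folder, stride, expected):
    beads, indices = ms.wall_beads(flat_folder, stride)
    assert len(beads) == expected == len(indices)


def test_wall_bead_oversized_stride(flat_folder):
    with pytest.warns(UserWarning, match="single wall bead"):
        beads, indices = ms.wall_beads(flat_folder, 10 ** 6)
    assert len(beads) == 1


def test_wall_restraint_files(tmp_path, flat_folder):
    _, indices = ms.wall_beads(flat_folder, 16)
    write_wall_restraints(indices, tmp_path / "wall.ndx",
                          tmp_path / "posre.itp")
    ndx = (tmp_path / "wall.ndx").read_text().split()
    assert [int(x) for x in ndx[3:]] == indices
    itp = (tmp_path / "posre.itp").read_text().splitlines()
    listed = [int(line.split()[0]) for line in itp[2:]]
    assert listed == indices


# ---------------------------------------------------------------------------
# GRO / TOP
# ---------------------------------------------------------------------------

def test_gro_fixed_width_fields(tmp_path):
    model = ms.MembraneModel(
        residues=[Residue("LIP", [("HD", np.array([1.2345, 0.0, 0.0]))])],
        box=np.array([5.0, 5.0, 5.0]))
    ms.write_gro(model, tmp_path / "one.gro")
    line = (tmp_path / "one.gro").read_text().splitlines()[2]
    assert line == "    1LIP     HD    1   1.234   0.000   0.000"


def test_gro_round_trip(tmp_path, flat_folder, mini_lib):
    model = ms.place_lipids(flat_folder, mini_lib,
                            {0: LipidSpec("POPC", 1.0, 0.64)}, seed=3)
    ms.write_gro(model, tmp_path / "m.gro")
    back = ms.read_gro(tmp_path / "m.gro")
    assert back.n_beads == model.n_beads
    assert back.molecule_counts == model.molecule_counts
    np.testing.assert_allclose(back.positions(), model.positions(), atol=1e-3)
    np.testing.assert_allclose(back.box, model.box, atol=1e-5)


def test_gro_atom_number_wraps_modulo(tmp_path):
    residues = [Residue("W", [("W", np.zeros(3))]) for _ in range(100001)]
    model = ms.MembraneModel(residues=residues, box=np.ones(3))
    ms.write_gro(model, tmp_path / "big.gro")
    lines = (tmp_path / "big.gro").read_text().splitlines()
    assert int(lines[2 + 100000][15:20]) == 1        # 100001st atom
    assert int(lines[2 + 100000][0:5]) == 1          # and residue


def test_gro_long_name_truncated(tmp_path):
    model = ms.MembraneModel(
        residues=[Residue("TOOLONGNAME", [("B", np.zeros(3))])],
        box=np.ones(3))
    with pytest.warns(UserWarning, match="truncated"):
        ms.write_gro(model, tmp_path / "t.gro")
    assert ms.read_gro(tmp_path / "t.gro").residues[0].name == "TOOLO"


def test_gro_readable_by_mdanalysis(tmp_path, flat_folder, mini_lib):
    """Independent reader cross-check of the writer."""
    mda = pytest.importorskip("MDAnalysis")
    model = ms.place_lipids(flat_folder, mini_lib,
                            {0: LipidSpec("POPC", 1.0, 0.64)}, seed=3)
    ms.write_gro(model, tmp_path / "m.gro")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(tmp_path / "m.gro"))
    assert len(u.atoms) == model.n_beads
    np.testing.assert_allclose(u.atoms.positions / 10.0,  # Angstrom -> nm
                               model.positions(), atol=1e-3)
    np.testing.assert_allclose(u.dimensions[:3] / 10.0, model.box, atol=1e-4)


def test_top_molecule_order(tmp_path):
    residues = ([Residue("A", [("X", np.zeros(3))])] * 3
                + [Residue("PROT", [("X", np.zeros(3))])]
                + [Residue("B", [("X", np.zeros(3))])] * 2)
    model = ms.MembraneModel(residues=residues, box=np.ones(3))
    ms.write_top(model, tmp_path / "t.top")
    lines = [l.split() for l in
             (tmp_path / "t.top").read_text().splitlines()
             if l and not l.startswith(("[", "#", "memshape"))]
    assert lines == [["A", "3"], ["PROT", "1"], ["B", "2"]]


def test_top_flat_case_counts(tmp_path, flat_folder, mini_lib):
    specs = [LipidSpec("POPC", 0.9, 0.64, domain_id=0),
             LipidSpec("DLPC", 0.1, 0.77, domain_id=1)]
    for leaflet in ("outer", "inner"):
        ms.dop_assign(flat_folder, leaflet, specs, seed=0)
    model = ms.place_lipids(flat_folder, mini_lib,
                            {s.domain_id: s for s in specs}, seed=0)
    assert model.molecule_counts == [("POPC", 720), ("DLPC", 80)]


def test_top_empty_model_refused(tmp_path):
    with pytest.raises(ValueError, match="empty"):
        ms.write_top(ms.MembraneModel(box=np.ones(3)), tmp_path / "t.top")


# ---------------------------------------------------------------------------
# global build invariants
# ---------------------------------------------------------------------------

def _min_cross_molecule_distance(model):
    pos = model.positions()
    owner = np.concatenate([[i] * r.n_beads
                            for i, r in enumerate(model.residues)])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=0.35, output_type="ndarray")
    cross = pairs[owner[pairs[:, 0]] != owner[pairs[:, 1]]]
    if len(cross) == 0:
        return np.inf
    return np.linalg.norm(pos[cross[:, 0]] - pos[cross[:, 1]], axis=1).min()


@pytest.mark.parametrize("kind,params", [
    ("flat", {"Lx": 16.0, "Ly": 16.0}),
    ("sine", {"Lx": 20.0, "Ly": 20.0, "A": 1.5, "m": 1}),
    ("vesicle", {"R": 8.0}),
])
def test_build_overlap_free(kind, params, mini_lib):
    """Membranes built at the physical area per lipid have no cross-molecule
    bead contacts below 0.1 nm."""
    folder = ms.analytical_folder(kind, params, apl_hint=0.64)
    specs = [LipidSpec("POPC", 0.8, 0.64, domain_id=0),
             LipidSpec("CDL2", 0.2, 1.2, c0=-0.3, k=10.0, domain_id=1)]
    for leaflet in ("outer", "inner"):
        ms.dop_assign(folder, leaflet, specs, seed=11)
    model = ms.place_lipids(folder, mini_lib,
                            {s.domain_id: s for s in specs}, seed=11)
    assert _min_cross_molecule_distance(model) >= 0.1


def test_build_bit_reproducible(tmp_path, mini_lib):
    for run in ("a", "b"):
        folder = ms.analytical_folder("flat", {"Lx": 12.0, "Ly": 12.0}, 0.64)
        specs = [LipidSpec("POPC", 0.7, 0.64, domain_id=0),
                 LipidSpec("CHOL", 0.3, 0.4, domain_id=1)]
        for leaflet in ("outer", "inner"):
            ms.dop_assign(folder, leaflet, specs, seed=42)
        model = ms.place_lipids(folder, mini_lib,
                                {s.domain_id: s for s in specs}, seed=42)
        ms.write_gro(model, tmp_path / f"{run}.gro")
    assert (tmp_path / "a.gro").read_bytes() == (tmp_path / "b.gro").read_bytes()


def test_total_bead_count_identity(flat_folder, mini_lib):
    specs = [LipidSpec("POPC", 0.9, 0.64, domain_id=0),
             LipidSpec("CHOL", 0.1, 0.4, domain_id=1)]
    for leaflet in ("outer", "inner"):
        ms.dop_assign(flat_folder, leaflet, specs, seed=1)
    model = ms.place_lipids(flat_folder, mini_lib,
                            {s.domain_id: s for s in specs}, seed=1)
    per = {"POPC": mini_lib["POPC"].n_beads, "CHOL": mini_lib["CHOL"].n_beads}
    assert model.n_beads == sum(per[n] * c for n, c in model.molecule_counts)


def test_builder_config_parse(tmp_path):
    cfg = tmp_path / "input.str"
    cfg.write_text("""\
[Lipids List]
POPC 0.9 0.64 0 0
DLPC 0.1 0.77 0 0
[Protein List]
PROT 1 5.0 1.5
""")
    lipids, proteins = parse_builder_config(cfg)
    assert [l.name for l in lipids] == ["POPC", "DLPC"]
    assert lipids[0].fraction == 0.9
    assert proteins == [{"name": "PROT", "count": 1, "z_offset": 5.0,
                         "collision_radius": 1.5}]
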