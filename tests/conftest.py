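import numpy as np
import pytest

import memshape as ms
from memshape.placement import LipidSpec


@pytest.fixture(scope="session")
def icosphere_mesh():
    mesh, report = ms.orient_mesh(ms.make_mesh("icosphere", radius=10.0,
                                               subdivisions=3))
    assert report.orientable
    return mesh


@pytest.fixture()
def icosphere_folder(icosphere_mesh):
    return ms.discretize(icosphere_mesh, bilayer_thickness=4.0)


@pytest.fixture(scope="session")
def moebius_cut_mesh():
    mesh, report = ms.orient_mesh(ms.make_mesh("moebius"))
    assert not report.orientable
    return mesh


@pytest.fixture()
def moebius_folder(moebius_cut_mesh):
    return ms.discretize(moebius_cut_mesh, bilayer_thickness=2.0)


@pytest.fixture()
def sine_folder():
    """40x40 points per leaflet, amplitude 3 nm, one period."""
    return ms.analytical_folder("sine", {"Lx": 20.0, "Ly": 20.0,
                                         "A": 3.0, "m": 1}, apl_hint=0.25)


@pytest.fixture()
def small_sine_folder():
    """20x20 points: cheap enough for many-seed statistics."""
    return ms.analytical_folder("sine", {"Lx": 20.0, "Ly": 20.0,
                                         "A": 3.0, "m": 1}, apl_hint=1.0)


@pytest.fixture()
def flat_folder():
    """20x20 flat grid at 0.64 nm^2 per point."""
    return ms.analytical_folder("flat", {"Lx": 16.0, "Ly": 16.0},
                                apl_hint=0.64)


def two_sheet_mesh(gap=3.0, n=12, spacing=1.0):
    """Two stacked flat square sheets ``gap`` nm apart in one mesh."""
    base = ms.make_mesh("flat_grid", n=n, spacing=spacing)
    nv = base.n_vertices
    upper = base.vertices.copy()
    upper[:, 2] += gap
    verts = np.vstack([base.vertices, upper])
    faces = np.vstack([base.triangles, base.triangles + nv])
    box = base.box.copy()
    box[2] = max(box[2], upper[:, 2].max() + 5.0)
    return ms.TriMesh(verts, faces, box)


@pytest.fixture()
def two_sheet_folder():
    mesh, _ = ms.orient_mesh(two_sheet_mesh())
    return ms.discretize(mesh, bilayer_thickness=1.0)


@pytest.fixture(scope="session")
def mini_lib():
    return ms.default_library()


def cdl_popc_specs(cdl_fraction=0.2, k_cdl=10.0, c0_cdl=-0.3):
    """The curvature-preference study pair: CDL biased, POPC unbiased."""
    return [
        LipidSpec("POPC", 1.0 - cdl_fraction, 0.64, c0=0.0, k=1.0,
                  domain_id=0),
        LipidSpec("CDL2", cdl_fraction, 1.2, c0=c0_cdl, k=k_cdl,
                  domain_id=1),
    ]
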