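"""Lateral organization of membrane components on a point folder.

Implements curvature-biased lipid sorting, circular lipid domains
(straight-line or geodesic), curvature-biased collision-free protein
placement, pores, edge-specific lipid selection, and a curvature-enrichment
summary table.

Curvature-biased sorting assigns each surface element a lipid type with
probability proportional to a Boltzmann weight

    P(l) = exp(-k (2H - C0)^2)

where ``H`` is the local mean curvature, ``C0`` the lipid's spontaneous
(preferred) curvature, and ``k`` a dimensionless sharpness factor.  When
``k`` is additionally scaled by the element area the exponent mimics the
Helfrich bending energy (k then carries nm^2).  The overall composition is
conserved exactly: per-type quotas are fixed up front by largest-remainder
rounding, points are visited in seeded random order to avoid systematic
bias, and at each point the draw is restricted to types with remaining
quota.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .point_model import Inclusion, Exclusion, PointFolder, PointFolderError

__all__ = ["LipidSpec", "boltzmann_weight", "largest_remainder_quotas",
           "dop_assign", "dai_euclidean", "dai_geodesic", "inu_place",
           "make_pore", "edge_domain", "curvature_enrichment"]


@dataclass
class LipidSpec:
    """Placement parameters of one lipid type.

    fraction : target share of the composition, [0, 1]
    apl : area per lipid, nm^2
    c0 : spontaneous curvature preference (preferred value of 2H), 1/nm
    k : bias sharpness, dimensionless (nm^2 when area-scaled)
    domain_id : lipid domain tag written onto assigned points
    """

    name: str
    fraction: float
    apl: float
    c0: float = 0.0
    k: float = 0.0
    domain_id: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"{self.name}: fraction must be in [0,1]")
        if self.apl <= 0:
            raise ValueError(f"{self.name}: apl must be > 0")
        if self.k < 0:
            raise ValueError(f"{self.name}: k must be >= 0")


def _check_fractions(specs) -> None:
    total = sum(s.fraction for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"lipid fractions must sum to 1, got {total}")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate lipid names in {names}")
    doms = [s.domain_id for s in specs]
    if len(set(doms)) != len(doms):
        raise ValueError(f"lipid specs must have distinct domain_ids, got {doms}")


def boltzmann_weight(H: float, spec: LipidSpec, area: float = 1.0,
                     area_scaled: bool = False) -> float:
    """``exp(-k (2H - c0)^2)``; k is multiplied by the element area when
    ``area_scaled``.  Equals 1 iff ``2H == c0`` or ``k == 0``."""
    k = spec.k * area if area_scaled else spec.k
    return float(np.exp(-k * (2.0 * H - spec.c0) ** 2))


def largest_remainder_quotas(fractions, n: int) -> np.ndarray:
    """Integer quotas summing to ``n`` by largest-remainder rounding.

    Ties in the remainders are broken by position (earlier spec wins), so
    the realized composition is deterministic.
    """
    fractions = np.asarray(fractions, dtype=float)
    exact = fractions * n
    quotas = np.floor(exact).astype(int)
    remainder = exact - quotas
    short = n - quotas.sum()
    order = sorted(range(len(fractions)), key=lambda i: (-remainder[i], i))
    for i in order[:short]:
        quotas[i] += 1
    return quotas


def _eligible(folder: PointFolder, leaflet: str):
    pts = []
    for p in folder.points(leaflet):
        ex = folder.excluded_ids.get(p.leaflet, set())
        if p.id not in ex:
            pts.append(p)
    return pts


def dop_assign(folder: PointFolder, leaflet: str, specs: list,
               area_scaled: bool = False, seed: int | None = None
               ) -> PointFolder:
    """Curvature-biased, composition-conserving lipid-domain assignment.

    Visits the leaflet's non-excluded points in seeded random order; at each
    point the normalized Boltzmann weights of the lipid types that still
    have quota left define a categorical draw.  Final per-type counts equal
    the largest-remainder quotas exactly, for every seed.
    """
    _check_fractions(specs)
    rng = np.random.default_rng(seed)
    pts = _eligible(folder, leaflet)
    n = len(pts)
    if n == 0:
        warnings.warn("dop_assign: no eligible points")
        return folder
    quotas = largest_remainder_quotas([s.fraction for s in specs], n)
    remaining = quotas.copy()
    order = rng.permutation(n)
    for idx in order:
        p = pts[idx]
        open_types = np.flatnonzero(remaining > 0)
        assert open_types.size, "quota bookkeeping exhausted before points"
        w = np.array([boltzmann_weight(p.mean_curvature, specs[j],
                                       p.area, area_scaled)
                      for j in open_types])
        total = w.sum()
        probs = w / total if total > 0 else np.full(len(w), 1.0 / len(w))
        j = int(open_types[rng.choice(len(open_types), p=probs)])
        p.domain = specs[j].domain_id
        remaining[j] -= 1
    assert remaining.sum() == 0
    return folder


# ---------------------------------------------------------------------------
# circular domains
# ---------------------------------------------------------------------------

def _center_positions(folder: PointFolder, leaflet: str, centers) -> np.ndarray:
    """Centers may be point ids (ints) or raw coordinates (3-vectors)."""
    out = []
    for c in centers:
        if np.isscalar(c) or isinstance(c, (int, np.integer)):
            out.append(folder.by_id(leaflet, int(c)).position)
        else:
            out.append(np.asarray(c, dtype=float).reshape(3))
    return np.array(out).reshape(-1, 3)


def dai_euclidean(folder: PointFolder, centers, radius: float, domain_id: int,
                  leaflet: str = "outer") -> PointFolder:
    """Straight-line circular domains: every point within ``radius`` of any
    center gets ``domain_id``.

    Fast, but straight-line distance ignores the surface: where two
    membrane regions approach each other closer than the radius, points on
    the far region are captured too (use :func:`dai_geodesic` to avoid
    that).
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    centers = list(centers)
    if not centers:
        warnings.warn("dai_euclidean: empty centers, nothing assigned")
        return folder
    cpos = _center_positions(folder, leaflet, centers)
    pts = folder.leaflet(leaflet)
    pos = folder.positions(leaflet)
    tree = cKDTree(cpos)
    dist, _ = tree.query(pos, k=1)
    for p, d in zip(pts, dist):
        if d <= radius:
            p.domain = domain_id
    return folder


def _leaflet_graph(folder: PointFolder, leaflet: str):
    if not folder.mesh_edges or leaflet not in folder.mesh_edges \
            or not folder.mesh_edges[leaflet]:
        raise PointFolderError(
            "point folder carries no mesh edges for leaflet "
            f"{leaflet!r}; regenerate it with the surface discretizer "
            "(PLM) so geodesic operations are available")
    pts = folder.leaflet(leaflet)
    index = {p.id: i for i, p in enumerate(pts)}
    pos = folder.positions(leaflet)
    rows, cols, w = [], [], []
    for a, b in folder.mesh_edges[leaflet]:
        if a in index and b in index:
            i, j = index[a], index[b]
            d = float(np.linalg.norm(pos[i] - pos[j]))
            rows.append(i); cols.append(j); w.append(d)
    n = len(pts)
    g = coo_matrix((w + w, (rows + cols, cols + rows)), shape=(n, n))
    return g.tocsr(), index, pts


def dai_geodesic(folder: PointFolder, centers, radius: float, domain_id: int,
                 leaflet: str = "outer") -> PointFolder:
    """Geodesic circular domains via multi-source Dijkstra on the mesh graph.

    Edge weights are the Euclidean edge lengths, so the graph distance upper
    bounds the true straight-line distance: the assigned set is always a
    subset of the Euclidean one at equal radius, and disconnected membrane
    surfaces can never bleed into each other.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    graph, index, pts = _leaflet_graph(folder, leaflet)
    sources = []
    for c in centers:
        if np.isscalar(c) or isinstance(c, (int, np.integer)):
            sources.append(index[int(c)])
        else:
            # nearest leaflet point to a raw coordinate
            pos = folder.positions(leaflet)
            sources.append(int(np.argmin(
                np.linalg.norm(pos - np.asarray(c, dtype=float), axis=1))))
    if not sources:
        warnings.warn("dai_geodesic: empty centers, nothing assigned")
        return folder
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    for p, d in zip(pts, dist):
        if d <= radius:
            p.domain = domain_id
    return folder


# ---------------------------------------------------------------------------
# proteins, pores, edges
# ---------------------------------------------------------------------------

def inu_place(folder: PointFolder, protein_type: int, n_copies: int,
              c0: float = 0.0, k: float = 0.0, collision_radius: float = 0.0,
              seed: int | None = None, leaflet: str = "outer",
              orientations=None) -> PointFolder:
    """Curvature-biased, collision-free protein placement.

    Candidate points are weighted with the same Boltzmann function as lipid
    sorting; placements are drawn without replacement and rejected when
    within ``collision_radius`` (straight-line) of an already placed
    inclusion.  Each accepted inclusion gets a seeded random in-plane
    orientation unless one is supplied.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if collision_radius < 0:
        raise ValueError("collision_radius must be >= 0")
    rng = np.random.default_rng(seed)
    spec = LipidSpec("protein", fraction=1.0, apl=1.0, c0=c0, k=k)
    pts = _eligible(folder, leaflet)
    weights = np.array([boltzmann_weight(p.mean_curvature, spec) for p in pts])
    if weights.sum() <= 0:
        weights = np.ones(len(pts))
    placed_pos = [folder.by_id(leaflet, inc.point_id).position
                  for inc in folder.inclusions]
    available = np.ones(len(pts), dtype=bool)
    placed = 0
    while placed < n_copies and available.any():
        w = np.where(available, weights, 0.0)
        if w.sum() <= 0:
            break
        i = int(rng.choice(len(pts), p=w / w.sum()))
        available[i] = False
        p = pts[i]
        if any(np.linalg.norm(p.position - q) < collision_radius
               for q in placed_pos):
            continue
        if orientations is not None and placed < len(orientations):
            ori = np.asarray(orientations[placed], dtype=float)
        else:
            phi = rng.uniform(0, 2 * np.pi)
            ori = np.array([np.cos(phi), np.sin(phi)])
        folder.inclusions.append(Inclusion(protein_type, p.id, ori))
        placed_pos.append(p.position)
        placed += 1
    if placed < n_copies:
        raise RuntimeError(
            f"could only place {placed}/{n_copies} proteins collision-free "
            f"at radius {collision_radius} nm")
    return folder


def _pore_members(folder: PointFolder, leaflet: str, center_id: int,
                  radius: float) -> set:
    """Point ids within ``radius`` of the pore center, geodesic when mesh
    edges are available, straight-line otherwise."""
    try:
        graph, index, pts = _leaflet_graph(folder, leaflet)
    except PointFolderError:
        center = folder.by_id("outer", center_id).position
        pts = folder.leaflet(leaflet)
        return {p.id for p in pts
                if np.linalg.norm(p.position - center) <= radius}
    if center_id not in index:
        return set()
    dist = dijkstra(graph, directed=False, indices=[index[center_id]],
                    min_only=True)
    return {p.id for p, d in zip(pts, dist) if d <= radius}


def make_pore(folder: PointFolder, center, radius: float) -> PointFolder:
    """Record a membrane pore: an exclusion whose member points the builder
    will skip on both leaflets.

    ``center`` is an outer-leaflet point id or a coordinate (snapped to the
    nearest outer point).  A center farther than ``radius`` from the
    membrane yields a warning and an empty pore.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if np.isscalar(center) or isinstance(center, (int, np.integer)):
        center_id = int(center)
        folder.by_id("outer", center_id)  # validates
    else:
        c = np.asarray(center, dtype=float).reshape(3)
        pos = folder.positions("outer")
        d = np.linalg.norm(pos - c, axis=1)
        i = int(np.argmin(d))
        if d[i] > radius:
            warnings.warn(
                f"pore center {c} is {d[i]:.2f} nm from the membrane "
                f"(> radius {radius}); empty pore, nothing recorded")
            return folder
        center_id = folder.leaflet("outer")[i].id
    folder.exclusions.append(Exclusion(point_id=center_id, radius=radius))
    for name in ("outer", "inner"):
        folder.excluded_ids[name] |= _pore_members(folder, name,
                                                   center_id, radius)
    return folder


def edge_domain(folder: PointFolder, domain_id: int,
                leaflet: str = "both") -> PointFolder:
    """Assign ``domain_id`` to exactly the edge-flagged points (e.g. to line
    an open rim with edge-stabilizing lipids).  Closed surfaces have no
    edges: warning, no-op."""
    flagged = [p for p in folder.points(leaflet) if p.edge]
    if not flagged:
        warnings.warn("edge_domain: surface has no open edges; nothing to do")
        return folder
    for p in flagged:
        p.domain = domain_id
    return folder


def curvature_enrichment(folder: PointFolder, names: dict | None = None,
                         leaflet: str = "outer", bins: int = 20
                         ) -> pd.DataFrame:
    """Relative lipid distribution per mean-curvature bin.

    ``H`` is binned into ``bins`` equal-width bins over the observed range;
    each row holds, per lipid (domain), count_in_bin / bin_total, so rows
    sum to 1.  Empty bins are dropped.  ``names`` optionally maps domain id
    to a lipid label for the columns.
    """
    pts = folder.points(leaflet)
    H = np.array([p.mean_curvature for p in pts])
    dom = np.array([p.domain for p in pts])
    lo, hi = H.min(), H.max()
    if hi - lo < 1e-12:
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        edges = np.linspace(lo, hi, bins + 1)
    which = np.clip(np.digitize(H, edges) - 1, 0, len(edges) - 2)
    doms = sorted(set(dom.tolist()))
    cols = {d: (names[d] if names and d in names else f"domain{d}")
            for d in doms}
    rows = []
    idx = []
    for b in range(len(edges) - 1):
        mask = which == b
        total = int(mask.sum())
        if total == 0:
            continue
        idx.append(0.5 * (edges[b] + edges[b + 1]))
        rows.append([float((dom[mask] == d).sum()) / total for d in doms])
    table = pd.DataFrame(rows, index=pd.Index(idx, name="H"),
                         columns=[cols[d] for d in doms])
    return table
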