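# Methods

This note documents the models and algorithms behind `memshape`, the
defaults and why they were chosen, what the synthetic fixtures do and do
not emulate, and the package's known limitations.

## Geometry estimation

**Normals** are angle-weighted averages of incident triangle normals;
boundary vertices use their one-sided fan. On a radius-10 icosphere at
three subdivision levels this leaves a discretization floor of ~0.3°
against the analytic radial normal — an inherent property of any
one-ring estimator at that resolution, not a numerical defect.

**Areas** follow the barycentric one-third rule (each triangle contributes
A/3 to each corner). This conserves total surface area exactly and is
robust to obtuse triangles, unlike mixed-Voronoi weights; the trade-off is
slightly less local accuracy, which does not matter here because areas are
only consumed as per-lipid packing budgets.

**Principal curvatures** come from a local quadric fit: the 1-ring
neighbourhood (escalated to the 2-ring when fewer than 5 neighbours, the
usual case at open edges and mesh corners) is expressed in the tangent
frame, a quadratic height field `h(u,v) = ½(a u² + 2b uv + c v²)` is fit
by least squares, and the shape operator `−[[a,b],[b,c]]` is
eigen-decomposed. The quadric fit was chosen over cotangent-Laplacian mean
curvature because the builder needs full principal *directions* (to orient
anisotropic placements) and one-sided behaviour at open edges; it degrades
gracefully on boundary fans, falling back to zero curvature with a flag
only when the fit is rank-deficient (collinear neighbours). The estimator
lives behind a single function so it can be swapped.

**Sign convention**: with outward normals a sphere of radius R has
c₁ = c₂ = +1/R; mean curvature H = (c₁+c₂)/2; crests of a sheet with
up-pointing normals have H > 0, valleys H < 0. Units: nm, nm⁻¹, nm².

Verified accuracy on analytic fixtures (median error): sphere and
cylinder principal curvatures < 5%; rigid-motion invariance to 1e-6;
curvatures scale as 1/s and areas as s² under uniform scaling s.

## Orientation repair and nonorientable surfaces

Winding consistency is propagated by BFS over triangle adjacency (an edge
shared by more than two triangles aborts: non-manifold). When a conflict
cycle survives, the surface is nonorientable; the conflicting edges form a
cut seam whose vertices are duplicated on the later-discovered side,
turning e.g. a Möbius strip into an orientable open ribbon — the only
form in which a two-leaflet bilayer is definable. Seam edges are processed
in sorted order so the cut is reproducible. Closed meshes are globally
flipped if needed so signed volume ≥ 0 (normals outward).

## Leaflet construction

Each mesh vertex yields one surface element per leaflet at r ± (t/2)·n̂,
default bilayer thickness t = 3.8 nm (typical for coarse-grained
phospholipid bilayers; flag-overridable). Curvature and area transform as
for parallel surfaces at signed offset s:

    cᵢ' = cᵢ / (1 + s·cᵢ),    A' = A·(1 + s·c₁)(1 + s·c₂)

— exact for concentric spheres/cylinders, which is the test oracle. Inner
leaflet normals are flipped and the transformed curvatures negated (the
same wall seen from the other side curves the other way). Offsets at or
beyond the curvature radius (1 + s·cᵢ ≤ 0) are a hard error suggesting a
finer mesh or thinner bilayer. Applying the transforms (rather than
copying mid-surface values) is what lets both leaflets honor their area
per lipid on curved membranes; it is a deliberate design choice isolated
in one function.

Lipid packing density is set by mesh resolution: one lipid anchor per
vertex per leaflet. Users control it via the mesh or the rescale factor;
the builder warns when an element's area deviates more than 20% from the
assigned lipid's APL.

## Curvature-biased lipid sorting

Each surface element draws a lipid type with probability proportional to

    P(l) = exp(−k·(2H − C₀(l))²)

normalized over the types still available. `C₀` is the lipid's preferred
value of 2H (nm⁻¹; e.g. cardiolipin favors negative curvature), `k` ≥ 0 is
dimensionless sharpness; with area scaling the exponent becomes
`k·A·(2H−C₀)²`, structurally the Helfrich bending energy, and `k` carries
nm⁻²·nm² ≡ nm² per unit area. Composition is conserved *exactly*:

* per-type quotas = largest-remainder rounding of fraction·N (ties broken
  by spec order — deterministic);
* elements are visited in seeded random order (avoids sweep-direction
  bias);
* the categorical draw at each element is restricted to types with
  remaining quota. The alternative — resampling on exhaustion — was
  rejected as order-biased.

Consequences verified by the suite: realized counts equal quotas for
every seed; k = 0 is indistinguishable from uniform assignment (pooled χ²
across curvature quintiles over 50 seeds, α = 0.01); enrichment at
preferred-curvature elements is monotone in k; a 20% cardiolipin target on
a curved membrane is realized at exactly 20.0% for any (k, C₀).

## Domains, proteins, pores, edges

* **Circular domains**: Euclidean assignment is fast but bleeds across
  membrane regions that approach each other closer than the radius (two
  stacked sheets 3 nm apart are the canonical failure, reproduced in the
  tests). Geodesic assignment runs multi-source Dijkstra on the mesh-edge
  graph (scipy csgraph) with Euclidean edge weights; since graph distance
  bounds straight-line distance from above, the geodesic set is always a
  subset of the Euclidean one and never leaves a connected surface.
  Repeated runs overwrite overlaps — last write wins.
* **Proteins**: candidate elements weighted with the same Boltzmann
  function; draws without replacement; rejected within a user collision
  radius (straight-line; a geodesic collision metric is future work).
  Placement copies the pre-oriented structure, +z along the local normal,
  +x along the inclusion's in-plane azimuth, center at mid-surface +
  z-offset (offset 0 = membrane center). Lipids anchored laterally within
  the collision radius (and within 2t along the normal — keeps the far
  side of a vesicle untouched) are removed. No relaxation is performed.
* **Pores**: an exclusion mark plus its member elements (geodesic when
  mesh edges are available, else Euclidean); the builder skips them on
  both leaflets. Membership is recomputed on folder reload rather than
  persisted.
* **Edges**: boundary vertices (edges on exactly one triangle) are
  flagged through to both leaflets; `edge_domain` retargets exactly those
  elements, e.g. to line a nanodisc rim or a Möbius edge with short
  lipids.

## Building, formats, solvation

Lipid templates (LIB dialect: head bead first, +z toward the head, origin
at the centroid) are spun by a seeded random azimuth — avoids crystalline
packing artifacts — and rotated into each element frame. Output residues
are grouped by lipid type so the GROMACS `[ molecules ]` section stays
compact; counts are derived from residue order (consecutive runs merge),
never stated independently. GRO is fixed-width (`%5d%-5s%5s%5d%8.3f×3`),
numbers wrap modulo 100000, velocities are never written; the writer is
cross-checked against an independent reader in the tests. Wall beads (one
per stride-th mid-surface element) emit an index group and a
position-restraint stanza so analytical shapes can be frozen during
simulation.

Solvation tiles a small equilibrated water box ⌈L/l⌉ times per axis,
clips at the box, deletes solvent residues within the cutoff of any
existing bead under the periodic minimum-image metric (KD-tree; a
quadratic audit backs it in the tests), then swaps seeded random waters
for the requested ions one-for-one. Charge neutralization arithmetic is
the user's job.

## Synthetic fixtures: what they do and do not show

All test inputs are generated: icospheres, capped cylinders and tori
(closed, analytic curvature), sine sheets and flat grids (open), the
parametric Möbius strip (nonorientable), toy Martini-3-style lipid
templates with plausible bead counts but **no validated chemistry**, a
rigid helical 50-bead toy protein, and a jittered-grid water cube at the
usual coarse-grained density (~8 beads/nm³). They exercise every code
path with known closed-form answers. They do not emulate: real Martini
bead chemistry or force-field validity, experimentally derived meshes
(noise, holes, non-uniform triangle quality), or thermal disorder —
passing tests demonstrate geometric and statistical correctness of the
construction, not simulation stability of any particular force field.

Problem sizes in the suite (chosen as representative desk-scale cases):
sheets of 400–1600 elements per leaflet, 50-seed statistics on the
400-element sheet, solvation boxes of a few thousand beads.

## Numerical choices and degenerate inputs

* Vesicles sample the sphere by a Fibonacci lattice (uniform area,
  deterministic; N = round(4πR²/APL), per-point area exactly 4πR²/N).
* Grid spacings round to fit the box; the realized area per point is
  reported when it differs from the request.
* Largest-remainder ties and Dijkstra ties are broken deterministically;
  a single RNG seed threads through every stochastic operation and is
  recorded in run logs and output titles — rebuilding with the same seed
  is bit-identical.
* Zero-area triangles contribute nothing (warning); isolated vertices are
  an error; a rank-deficient curvature fit yields zero curvature plus a
  flag; an empty curvature range in the enrichment table yields one row;
  empty domain-center lists warn and no-op.

## Known limitations

* One lipid per mesh vertex: packing fidelity is only as good as the mesh
  is uniform; no blue-noise resampling is performed.
* Strongly curved membranes (|c| approaching 1/(t/2 + lipid length))
  geometrically converge inner-leaflet tail beads; the overlap-free
  guarantee holds for |c| ≲ 0.15 nm⁻¹ at the default thickness and APL,
  and energy minimization is expected to resolve residual close contacts
  beyond that.
* No energy minimization, equilibration, or force-field parameter
  generation: the output is an initial structure.
* The geodesic metric is the mesh-edge graph metric, an upper bound on
  the true surface geodesic (exact geodesics would require e.g. the heat
  method).
* Protein placement performs no auto-orientation; supply pre-oriented
  structures (one file per orientation if several are needed).
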