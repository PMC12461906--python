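# memshape

**Curvature-aware coarse-grained membrane building** — from a triangulated
surface (or an analytical shape) to a simulation-ready bilayer structure with
topology and solvent.

Setting up coarse-grained molecular dynamics simulations of curved membranes
(organelle shapes, vesicles, nanodiscs, cubic phases) requires an initial
structure in which thousands of lipids tile an arbitrary surface without
overlaps, with the right composition, and — ideally — already laterally
organized the way curvature would sort them, so equilibration is cheap.
`memshape` builds such structures for Martini-style (and format-compatible)
force fields. It is a library first and a command-line tool second; the
audience is membrane simulators who have a target geometry as a mesh (e.g.
from a dynamically-triangulated-surface simulation, Blender, or segmented
microscopy data) or as a simple parametric shape.

## The pipeline

1. **Surface discretization** (`PLM`): a triangulated mesh (`.tsi` or OBJ)
   is validated, oriented (winding repaired by breadth-first propagation;
   nonorientable surfaces such as a Möbius strip are cut along the conflict
   seam into orientable open surfaces), and converted to a *point folder*:
   one surface element per vertex and leaflet, carrying position, area,
   normal, and principal curvatures/directions from a local quadric fit.
   Leaflets are offset ±t/2 along the normal with the parallel-surface
   transforms `c' = c/(1 + s·c)`, `A' = A·(1 + s·c₁)(1 + s·c₂)`.

2. **Lateral organization** (`DOP`/`DAI`/`INU`, or the Python point API):
   lipid types are assigned to surface elements with Boltzmann weights

   P(l) = exp(−k·(2H − C₀)²)

   where `H` is the local mean curvature, `C₀(l)` the lipid's spontaneous
   curvature and `k` the bias sharpness (optionally scaled by element area,
   mimicking the Helfrich bending energy). The overall composition is
   conserved *exactly* via largest-remainder quotas and a quota-restricted
   draw in seeded random visiting order. Circular lipid domains can be
   painted by straight-line or geodesic (mesh Dijkstra) distance; proteins
   are placed collision-free with the same curvature weighting; pores and
   edge-specific lipids are supported.

3. **Membrane building** (`PCG`): one lipid template per surface element,
   rotated into the local frame; proteins at their marked positions with a
   user z-offset along the normal (offset 0 = protein center at the
   membrane center); optional restrained wall beads; fixed-width GRO +
   GROMACS topology output; fast solvation (`SOL`) by tiling an
   equilibrated water box with a periodic overlap cutoff and ion placement.

## Worked example

A flat 16×16 nm two-lipid membrane, 90% POPC (APL 0.64 nm²) and 10% DLPC
(APL 0.77 nm²):

```sh
memshape PCG --flat 16 16 \
    --lipid POPC 0.9 0.64 0 0 --lipid DLPC 0.1 0.77 0 0 \
    -o out/ --seed 7
# wrote out/membrane.gro (9280 beads) and out/topol.top
```

The box is commensurate with the requested area per lipid, so each leaflet
gets exactly 16·16/0.64 = 400 lipids, split 360/40 by the largest-remainder
quotas — 720 POPC and 80 DLPC in the topology:

```
[ molecules ]
POPC       720
DLPC       80
```

Curvature-biased sorting on a sine-shaped membrane (amplitude 3 nm, one
period, 40×40 surface elements), placing 20% cardiolipin with a negative
curvature preference (C₀ = −0.3 nm⁻¹, k = 10) against unbiased POPC:

```python
import memshape as ms
from memshape.placement import LipidSpec

folder = ms.analytical_folder("sine", {"Lx": 20, "Ly": 20, "A": 3, "m": 1},
                              apl_hint=0.25)
specs = [LipidSpec("POPC", 0.8, 0.64, c0=0.0, k=1.0, domain_id=0),
         LipidSpec("CDL2", 0.2, 1.2, c0=-0.3, k=10.0, domain_id=1)]
ms.dop_assign(folder, "outer", specs, seed=7)
print(ms.curvature_enrichment(folder, names={0: "POPC", 1: "CDL2"}, bins=6))
```

```
            POPC   CDL2
H
-0.294564  0.775  0.225
-0.223905  0.612  0.388
-0.153245  0.600  0.400
-0.082586  0.712  0.288
-0.011927  0.784  0.216
 0.058732  0.904  0.096
```

Cardiolipin is enriched in the negatively curved valleys (up to 40% of
elements near 2H ≈ C₀) and depleted on the crests (10%), while the global
composition stays exactly 20% — the per-row numbers are the relative lipid
distribution per mean-curvature bin.

## Layout

| module | role |
|---|---|
| `memshape.mesh_io` | `.tsi`/OBJ read/write, open-edge detection, orientation repair and seam cutting |
| `memshape.geometry` | per-vertex normals, areas, principal curvatures (quadric fit) |
| `memshape.pointillism` | mesh → two-leaflet point folder (parallel-surface transforms) |
| `memshape.point_model` | point-folder data model, disk dialect, select/set-domain primitives |
| `memshape.placement` | curvature-biased sorting, Euclidean/geodesic domains, protein placement, pores, enrichment tables |
| `memshape.builder` | analytical shapes, lipid/protein placement into 3D, wall beads, GRO/TOP |
| `memshape.lipid_lib` | lipid template library (LIB dialect) + `libmaker` |
| `memshape.solvate` | water-box tiling, overlap cutoff, ions |
| `memshape.fixtures` | deterministic test/tutorial geometry and toy structures |
| `memshape.cli` | `memshape PLM/PCG/DOP/DAI/INU/SOL/VIS/LIB/FIX` |

See `docs/methods.md` for the model details, numerical choices and known
limitations.
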