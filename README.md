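# hyphamorph

Quantitative 3D micromorphometry of filamentous fungi from confocal
laser-scanning microscopy (CLSM) z-stacks.

Filamentous fungi such as *Trichoderma reesei* — the workhorse producer of
cellulolytic enzymes — grow as septate hyphae whose single-cell dimensions
(intercalary cell length, cell width, degree of branching) shift with strain
background, carbon source and process conditions, and correlate with enzyme
productivity. On insoluble lignocellulosic substrates like wheat straw,
wide-field microscopy fails; CLSM of Calcofluor-White-stained biomass yields
a z-stack in which cell walls appear as bright shells and septa as bright
transverse disks, and in which *actual* 3D distances can be measured rather
than 2D projections.

`hyphamorph` is the scriptable analysis half of that workflow. It consumes

* grayscale multi-page TIFF z-stacks with voxel-spacing metadata
  (reference geometry: 183 × 183 µm = 1024 × 1024 px laterally, 0.46 µm
  z-spacing, 60–100 slices),
* skeleton annotations in a small JSON schema — septum centres as 3D points,
  cells as septum pairs (optionally with waypoints tracing curvature),
  branch marks,

and computes per cell

* **length** — the anisotropic 3D Euclidean distance between the bounding
  septum centres, `L = √((Δx·dx)² + (Δy·dy)² + (Δz·dz)²)`, or the polyline
  length through waypoints;
* **width** — from the cell-wall fluorescence: intensity profiles are
  sampled perpendicular to the cell axis, and the width is the distance
  between the innermost opposing pair of wall peaks (FWHM of the
  background-subtracted profile as fallback), aggregated as the median over
  axial positions and radial directions;
* **branching** — the fraction of cells bearing a branch mark.

A synthetic-scene generator produces stacks of bent, branching, septate
tubes blurred by an anisotropic confocal PSF with exact exported ground
truth, so the whole measurement chain is testable without microscope data.
The statistics layer provides the study-level analyses: per-condition
summaries (mean ± n−1 sd), Welch's unequal-variance group test with
significance stars, and ordinary least squares linking morphology to
cellulase activity (FPU/mL) and protein titre (g/L). A packaged 20-condition
table (two strains × wheat-straw/lactose setups) drives a reproduction
report of the published aggregates and regression coefficients.

## Worked example

Generate a synthetic scene at reference voxel spacing and measure it:

```python
from hyphamorph import (SceneParams, VoxelGrid, generate_scene,
                        measure_all, summarize_cells)
from hyphamorph.core import PAPER_DX_UM

params = SceneParams(
    grid=VoxelGrid(nx=512, ny=512, nz=40,
                   dx=PAPER_DX_UM, dy=PAPER_DX_UM, dz=0.46),
    n_hyphae=12, tube_diameter_um=3.5, seed=13)
stack, truth = generate_scene(params)

table = measure_all(truth.skeleton, stack=stack)
print(table.head(5).to_string(index=False))
s = summarize_cells(table)
print(f"length (um)       {s.length_mean:.2f} +/- {s.length_sd:.2f}")
print(f"width (um)        {s.width_mean:.2f} +/- {s.width_sd:.2f}")
print(f"branches per cell {s.branches_per_cell:.2f}")
```

prints

```
cell_id  length_um  width_um  is_branching
  c0000  13.040566  3.389718         False
  c0001   7.978769  3.388286         False
  c0002  14.386945  3.388578          True
  c0003   9.543507  3.556594         False
  c0004   9.753178  3.467797         False
length (um)       10.93 +/- 3.72
width (um)        3.49 +/- 0.13
branches per cell 0.09
```

Lengths are exact (they derive from the annotated septum coordinates; here
the generator's own ground truth). The 23 simulated cells of true diameter
3.50 µm are estimated at 3.49 ± 0.13 µm from the rendered fluorescence —
the wall-peak-pair estimator recovers tube diameters within 0.25 µm on
noiseless phantoms over the 2.5–4 µm range.

The same workflow from the shell:

```sh
hyphamorph simulate --seed 13 --out-dir scene/
hyphamorph measure scene/scene_s13_d3.00.json \
    --stack scene/scene_s13_d3.00.tif -o cells.csv
hyphamorph summarize cells.csv
hyphamorph reproduce-table1        # recompute the published statistics
```

`reproduce-table1` recomputes, from the packaged condition table, the
strain/substrate/inoculation-level mean cell lengths, the branching
fractions, and the three published regressions — cellulase activity vs
length (−0.30 FPU/(mL µm), R² 0.53 over the 12 wheat-straw conditions),
protein vs length (−0.04 g/(L µm) over all 20), width vs length
(−0.11 µm/µm) — comparing each at printed precision and flagging the
printed values that are not recoverable from the printed table itself
(see `docs/methods.md`).

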