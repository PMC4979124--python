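# Methods

## Coordinate model

A confocal z-stack is a 3D array indexed `(z, y, x)` bound to a `VoxelGrid`
that records voxel counts and physical spacing (µm/voxel). All annotation
coordinates are continuous, 0-based voxel units `(x, y, z)`; physical
positions are obtained only by per-axis scaling through the grid, which
keeps the voxel↔µm contract in one place. Sub-voxel septum centres are
first-class: a mouse click on a zoomed slice is naturally fractional.
The reference acquisition is 1024 × 1024 px = 183 × 183 µm laterally
(0.178711 µm/px) with 0.46 µm z-steps over 60–100 slices, so axial voxels
are ~2.6× coarser than lateral ones; every distance computation scales each
axis before taking the Euclidean norm.

## Cell length

An intercalary cell is the stretch of hypha between two septa. The default
length is the straight 3D chord between the two annotated septum centres —
the one measurement the annotation protocol guarantees. An annotation may
trace waypoints between the septa, in which case the polyline length is
used; by the triangle inequality this never undercuts the chord. Hyphal
tips (apical compartments bounded by a single septum) are representable in
the schema but excluded from length statistics: their distal end is a
growing front, not a septum, so their "length" is not comparable.

## Cell width

Calcofluor White stains the cell wall, so a line through a hypha
perpendicular to its axis sees two bright wall peaks separated by the cell
diameter. The estimator:

1. samples intensity profiles by trilinear interpolation at 5 axial
   positions along the cell (excluding 15 % of the length at each end, which
   keeps clear of the bright septa), in 8 radial directions per position
   spread over 180° perpendicular to the local axis;
2. excludes directions within 30° of the optical axis — the confocal PSF is
   axially elongated (σ_z ≈ 3 σ_xy here), which inflates apparent widths in
   near-axial directions;
3. per profile: background = 0.2-quantile; wall peaks = local maxima with
   prominence ≥ 0.2 × (max − background) after Gaussian smoothing with
   σ = 0.2 µm (matched to the lateral PSF width — it suppresses noise maxima
   that would otherwise register as spurious inner walls, while no optical
   structure is narrower than the PSF), refined to sub-step precision by a
   3-point parabolic fit; width = distance between the innermost opposing
   peak pair; if no opposing pair resolves, the FWHM of the raw
   background-subtracted profile (raw, so the smoothing kernel cannot widen
   it); if that fails too, the profile contributes nothing;
4. the cell width is the median over all successful profiles, and the
   estimate fails if fewer than one third succeed. A relative guard treats
   essentially constant profiles (dynamic range below 10⁻⁹ of the signal) as
   structureless, so interpolation round-off on empty stacks cannot
   manufacture peaks.

Peak-pair distance is preferred over FWHM because it is insensitive to
staining brightness and, like the whole pipeline, invariant under uniform
intensity scaling. On noiseless synthetic tubes at reference voxel spacing
the estimator recovers diameters across 2.5–4.0 µm within 0.16 µm
(monotonically in the true diameter); at a signal-to-noise ratio around 5
the error stays within ~0.1 µm on 20-seed averages. The original
acquisition software's width algorithm is not documented beyond its use of
wall fluorescence, so equivalence with it is not claimed — only parameter
recovery on synthetic ground truth.

## Synthetic scenes

The generator emulates the reference imaging conditions for end-to-end
testing. Hyphae grow as persistent random walks (1 µm steps, per-step
direction perturbed by a normal angle of sd 10°, near-lateral initial
course because the imaged volume is thin) segmented into cells of lognormal
length (default mean 10 µm, CV 0.3 — inside the measured 7.9–16.7 µm range;
lognormal because lengths are positive, and at this CV it is practically
indistinguishable from the near-normal distributions observed). Branches
spawn at septa with probability 0.2 per cell at 30–90° off the parent axis;
a successfully spawned branch marks its parent cell as branching (a cell
with several branches still counts once — branching cells, not branch tips,
are counted). Cells truncated by the volume boundary are discarded rather
than annotated short.

Rendering is sub-voxel exact: the distance of every voxel centre to the
densely resampled centreline (0.1 µm steps) is computed in µm space, and
the wall is a Gaussian shell of FWHM 0.3 µm centred at radius = diameter/2
(default 3 µm diameter, inside the measured 2.4–4.0 µm range). Septa are
filled disks perpendicular to the local axis with the same Gaussian
thickness. The field is convolved with a separable anisotropic Gaussian PSF
(σ_xy = 0.2 µm, σ_z = 0.6 µm — axial elongation as in confocal optics), and
Gaussian or Poisson noise is applied last. Intensities are arbitrary units
(wall 200, septum 220, background 10 by default).

All randomness flows through a single generator seeded once per scene, with
draws in a fixed documented order, so scenes are bit-reproducible per seed.
Ground-truth lengths are computed in µm space during growth and therefore
agree with geometric re-measurement of the exported annotations to within
floating-point round-off (≪ 1e−6 µm).

What the generator does *not* emulate: wheat-straw autofluorescence and
fibre clutter, hyphal crossing density of dense pellets, apical (tip)
compartments, depth-dependent attenuation, and detector artefacts. Passing
the synthetic recovery tests therefore demonstrates the estimator's
geometric correctness and noise robustness, not performance on cluttered
real samples.

## Statistics

Arithmetic means and sample (n−1) standard deviations throughout.
Condition-level averages are unweighted means of per-condition means.
Group comparisons use Welch's unequal-variance two-sided t-test (the
original study never names its test; per-condition spreads differ visibly,
which argues against the pooled-variance variant), mapped to the
conventional star code: 1/2/3 stars for p < 0.05/0.01/0.001. Ordinary least
squares with R² = Sxy²/(Sxx·Syy); paper-comparison columns are rounded half
away from zero to the printed decimals, with full precision retained
alongside.

### Comparing against printed values

The packaged condition table stores values exactly as printed, i.e. rounded
to 2 dp, while the original aggregates were evidently computed from
unrounded data. Statistics derived from 2-dp inputs can therefore differ
from the printed ones by up to one unit in the last printed digit, and that
(±0.01 at 2 dp) is the tolerance the reproduction report and the acceptance
tests apply. Missing values are real: the filter-paper assay has a lower
detection limit that all lactose cultivations fell below, so their FPU
entries are missing, never zero, and the FPU regression uses only the 12
wheat-straw conditions while protein and width regressions use all 20.

### Known non-reproducible printed values

The reproduction report recomputes every printed aggregate and flags, with
full-precision values, the ones that arithmetic on the printed table cannot
yield:

* the QM9414 branching aggregates (printed 0.16 for wheat straw and 0.22
  strain-wide against constituent means of 0.20 and 0.25);
* the substrate shortening percentages, where the printed per-strain
  assignment (10 %/21 %) is swapped relative to table arithmetic
  (21 %/8 %);
* the protein-vs-length R² (printed 0.33, recomputed 0.283 with a matching
  slope);
* the width-vs-length pair: the all-points fit gives −0.104/R² 0.275,
  whereas the printed −0.11/0.42 corresponds exactly (at 2 dp) to the fit
  excluding the single most outlying condition (largest studentized
  residual: the 2.35 µm width). The report shows both the all-points and
  the influence-trimmed fit.

## Problem sizes in the test suite

Synthetic validation uses paper-spacing crops (96–256 px laterally, 32–64
slices) rather than full 1024² stacks: the estimators operate on local
neighbourhoods, so crops exercise the identical code paths, and the full
suite plus the reproduction script stay fast enough to run routinely. Width
recovery is assessed on 5 tube orientations per diameter at 2.5, 3.0, 3.5
and 4.0 µm; the Welch power simulation uses 100 replicates of 40 cells per
group drawn from generator skeletons.

## Known limitations

* Annotations are inputs; there is no automatic septum detection or hypha
  tracing.
* No deconvolution or PSF estimation from data; the z-direction exclusion
  is a workaround, not a correction, so widths of near-axial cells rely on
  fewer profiles.
* Chord-based default lengths undercut strongly curved cells unless
  waypoints are annotated.
* TIFF voxel spacing is deliberately not read from tags (dialects vary);
  an explicit grid, a YAML sidecar, or the documented reference default is
  required.
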