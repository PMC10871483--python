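# Methods

`lungmorph` re-implements, as a tested pipeline, a μCT morphometry
workflow for the developing marsupial lung: seeded region-growing
segmentation of the air spaces, derivation of terminal air-space
volume and surface by ROI subtraction, fractionator line-intercept
stereology for air-space diameter and septum thickness, and
allometric analysis of the resulting volumes and surfaces against
body mass. Because no image data of the original specimens is
publicly available, the 3D stages are validated on a synthetic
"developing-lung phantom" with known ground truth, while the
statistical stages are validated against the packaged per-specimen
data table (35 gray short-tailed opossum specimens, 13 dpc to adult).

## Data model and units

All imaging operations run on a `VoxelGrid` — a 3D 16-bit gray-value
lattice with per-axis voxel spacing carried in micrometres — and on
boolean `Mask` / integer `LabelMap` lattices aligned to it. Axis 0 is
the slice (z) axis; the "length of the lung" used for section
sampling is measured along it. Spacing stays in μm throughout;
volumes and surfaces are converted to mm³/mm² only in the metrics
layer, matching the data table's columns. TIFF carries no reliable
voxel size, so reading TIFF without an explicit spacing is refused
rather than defaulted; NRRD/MetaImage spacings follow the ITK
millimetre convention and are converted (×1000) on read.

## Segmentation

The region grower marks all voxels connected to a seed (placed on the
tracheal centerline) whose gray value lies within a fixed tolerance
band centred on the seed's own gray value. The band is fixed, not an
adaptive running mean: this is deterministic and matches the manual
workflow the package automates, in which a single tolerance (default
1100, within the tool's customary 1000–1200 range for PTA-stained
lungs) is chosen per specimen. Connectivity defaults to
6-face-connectivity so one-voxel septa cannot be crossed diagonally.
A `max_voxels` guard converts tolerance misconfiguration (flooding
into background) into a distinct `RegionLeakError` rather than a
silently wrong mask.

Non-pulmonary air is excluded by seed connectivity: only the
component of the band mask containing the tracheal seed survives.
The bronchial-tree/terminal split requires an explicit tree
definition — the phantom's truth tree, or user-supplied boundary
voxels whose removal must disconnect the lumen — because the original
workflow drew this boundary manually and any radius heuristic would
be a guess. The lung outline (for V_L) is the seed-connected tissue
component, morphologically closed and hole-filled so internal air
counts as lung.

Noisy volumes are denoised with a 3³ median filter *before* growing
(`airseg.denoise`). The filter is a separate, explicit step: the
grower itself stays a pure band-connectivity operation, which is what
the flood-fill oracle tests verify. At the phantom's default noise
(σ = 800 gray units), ~17 % of air voxels would otherwise fall
outside a ±1100 band and fragment the region; the median filter
reduces the noise roughly fourfold while preserving edges, at the
cost of erasing structures thinner than two voxels — hence the
phantom's 2-voxel minimum feature size and ≥3-voxel pleura.

## Volume and surface estimation

Volume is the foreground voxel count times the voxel volume. Surface
area defaults to a triangulated isosurface: marching cubes at level
0.5 on the mask indicator smoothed with a 2-voxel-σ Gaussian. Raw
marching cubes on a binary mask overestimates a sphere's area by
~9 % (voxel staircase); with the 2-voxel smoothing the error is below
1 % at the calibration resolutions and decreases with finer spacing
(0.50 % at 5 μm, 0.12 % at 2.5 μm for a 200 μm-radius sphere). The
smoothing fuses air gaps thinner than ~3 voxels, so masks should
resolve septa with at least 3 voxels where S_A matters. A
`voxel_face` estimator (exposed faces × face area, ~1.5× staircase
bias on curved surfaces) is kept as a diagnostic.

Terminal air-space metrics follow the subtraction rule: V_A and S_A
are the volume and surface of the "entire air spaces" ROI minus those
of the "bronchial tree" ROI. The surface subtraction is reproduced
literally even though the difference is not the geometric surface of
the terminal region (the tree/terminal interface does not cancel);
it is the convention the reported values are defined by, and the
phantom ground truth applies the identical rule so comparisons are
consistent.

## Stereology

Sections are chosen by a systematic-uniform-random (fractionator)
scheme: the lung's slice extent divided by the number of sections
(default 8) gives the sampling interval, and a random start within
the first interval fixes the sections, so every slice has equal
sampling probability. The sectioning extent runs over slices whose
air area is at least 10 % of the peak per-slice air area; extreme
apical/basal caps and conducting-airway-only planes are not
representative parenchyma and would starve the chord quota.

Per section a line is cast through a uniform random point at a
uniform random angle, the masks are sampled along it at a sub-voxel
step (min spacing / 4), and maximal runs are measured: an air chord
is a maximal run of terminal-air voxels, a septum chord a maximal
tissue run bounded by air on both sides (so pleura and hilar tissue
never count as septa, and conducting-airway lumen — passed as an
excluded class — never masquerades as a septum). The first five valid
chords of each kind are taken per section, with extra lines cast as
needed; a section that cannot meet its quota raises an error rather
than under-reporting. At the defaults this yields exactly 40 diameter
and 40 septum measurements per lung, and summary statistics are means
with sample (n−1) SDs. Interior runs shorter than 1.5 voxels flanked
by equal labels are merged before measurement: resolvable structures
are at least two voxels thick, so such runs are aliasing artifacts of
near-tangent lines crossing a voxel staircase (without the merge they
split single chords and bias the mean low by ~15 %).

Two properties of this estimator matter for interpretation. First,
chords are shorter than diameters: for an isolated sphere of
geometric diameter D the expected measured chord is ≈0.678 D (theory
for hit-weighted uniform sections of a sphere gives exactly 2/3 D;
the measured constant on voxelized spheres, stable across radii
120–230 μm and spacings 4–8 μm, is 0.6785). Second, oblique crossings
lengthen septum chords relative to the perpendicular wall thickness.
Both effects apply equally to the phantom's ground-truth measurement
and to the protocol, so recovery comparisons are estimator-consistent;
absolute "diameter" values from chords should be read as mean
intercept lengths, as in the original screen-ruler protocol.

## The developing-lung phantom

The phantom emulates a PTA-stained μCT volume: bright tissue (30000),
dark air (5000), background below air (1000), Gaussian partial-volume
blur (default 0.3 voxel), additive Gaussian noise (default σ = 800),
clipped to 16 bits. One seeded RNG drives geometry, septation and
noise, so equal seeds give bitwise-identical phantoms.

Geometry: one ellipsoidal lung (semi-axes 1.0/1.1/0.8 × a size
parameter) partitioned into six lobar air sacs by vertical fissure
walls of one septum thickness which meet in a tissue hilum — four
lobes on the right (90° split into 45° sectors), two on the left.
This guarantees that every transverse section shows real interlobar
septa bounded by air on both sides, which point-tangent lobe shapes
cannot. The pleura is max(septum, 3 voxels) thick so denoising cannot
breach the lung boundary. A trachea descends the hilar axis and
per-lobe bronchial tubes run radially into each sac; at the newborn
stage each lobe is one large terminal air sac opening directly from
its lobar tube.

Septation (`subdivide_sacs`) models sacculation/alveolarization
abstractly: each round, every sac above a minimum size is split by a
planar septum of the configured thickness through its centroid with
RNG-drawn orientation, the slab voxels becoming tissue and the two
sides becoming child labels. A circular pore (radius max(3.5 voxels,
2 septa), centred within 0.15 equivalent diameters of the sac
centroid) is left in each septum so the lumen remains one connected
air space — the phantom's analogue of the openings real air spaces
retain; the pore geometry is sized so the opening also survives
denoising.

Stage parameterization uses the per-stage group means of the packaged
table (diameter 349 → 51 μm, septa 41 → 10 μm from neonate to 57 dpn)
with septation rounds 0, 0, 1, 1, 2, 2, 3, 3, 3, 3, 3, 3 for
13 dpc → adult, and voxel spacing clip(septum/3, 2, 8) μm so septa
are always ≥3 voxels. 13 dpc has no printed diameter/septum (the
fetal lung is deflated and was only measured for V_L), so its phantom
reuses the neonate structural parameters. The lung size parameter is
set from two constants calibrated once on reference phantoms and then
frozen: measured mean chord = 0.451 × size at zero rounds, shrinking
by 0.75 per septation round. With these, truth chord means land
within ~5 % of the stage targets across all stages, and both
developmental trends — strictly decreasing air-space diameter and
strictly increasing S_A/V_A — emerge from the geometry.

Ground truth (masks at generation resolution, measured with the
package's own estimators): V_L from the lung mask, V_A from the
terminal mask, S_A by the subtraction rule, diameter/septum from
dense chord sampling (300 lines, all chords). The truth metrics
therefore share the estimators' conventions, which is deliberate:
recovery tests then isolate the segmentation and protocol errors.

What the phantom does not emulate: X-ray projection/reconstruction
physics (gray values are rendered directly), vascular trees,
capillary-layer septal ultrastructure, alveolar-duct micro-anatomy,
pores of Kohn (septal pores exist but are a connectivity device, not
anatomy), fixation shrinkage, or stain heterogeneity. Passing
recovery tests therefore demonstrates the correctness of the
algorithms under controlled contrast and noise, not performance on
real scanner data with beam hardening or uneven staining.

## Specimen table, summary statistics, allometry

The packaged CSV transcribes the study's per-specimen table: 35
records (4 fetal at 13 dpc without body weight, V_A or S_A; 31
postnatal), checksum-verified at load. Group "Mean (SD)" rows are
always recomputed from individuals — sample (n−1) SDs, round-half-up
at the printed precision (191.5 → 192, 19.5 → 20, 0.5325 → 0.53),
conventions verified cell-by-cell against the printed table. Four
printed cells are not reproducible from the printed individual values
(4 dpn septum SD "±0" vs 0.58, 28 dpn septum SD "±0" vs 0.71, 14 dpn
V_A SD "±2.19" vs 2.1953 → 2.20, 49 dpn V_L mean "455.22" vs
455.2133 → 455.21): the published summary rows were evidently
computed on unrounded per-specimen data. The validation report flags
these cells explicitly instead of failing or silently accepting them.

Body-mass correlations are Pearson coefficients over the 31 postnatal
individuals, computed on both raw and log10 scales because the source
does not state which was used. Neither reproduces the published
coefficients (published 0.987/0.915/0.971 for V_L/V_A/S_A; raw gives
0.994/0.977/0.928, log10 gives 0.994/0.992/0.984, and group-mean or
adult-excluded variants do not match either), so the validation
report records the discrepancy against this documented ambiguity
rather than selecting whichever transform looks closest. The log-log
least-squares slope is reported as the allometric exponent; fetal
records, having no body weight, are excluded from all regressions.

## Pipeline, seeds and problem sizes

A pipeline run is fully specified by its config: stage phantom →
median denoise → region growing from the tracheal seed → external-air
exclusion → tree/terminal split against the truth tree → metrics →
lung outline → stereology, with a JSON report and manifest. The
single global seed expands to per-stage seeds by fixed offsets so
stages can be rerun independently yet reproducibly.

Validation suites use phantom groups of five specimens per stage and
apply the 15 % diameter recovery check to the group mean, mirroring
the study's per-age-group averaging (single-lung protocol noise is
±5–6 % SD at 40 chords, so group means are needed for a stable
comparison). Recovery runs on neonate, 7 dpn and
21 dpn phantoms (grids ≈ 2–9 M voxels at 6–8 μm spacing); the
monotone development sweep uses neonate, 7, 14, 35 and 57 dpn, whose
target diameters differ by ≥25 % so strict ordering is insensitive to
protocol sampling noise. At the 57 dpn resolution limit (3-voxel
septa at 3.3 μm) segmentation under-fills small air spaces by up to
~10 % and Dice drops to ≈0.94 — a partial-volume effect that
motivates the finer-spacing requirement if late-stage absolute
volumes are the goal.

## Known limitations

* Chord-based "diameter" is a mean intercept length, not a caliper
  diameter; cross-study comparison requires the same convention.
* The fixed seed-centred band makes segmentation sensitive to the
  seed voxel's noise; denoising mitigates but does not remove this.
* The S_A subtraction convention double-counts nothing but also does
  not represent the closed surface of the terminal region alone.
* Phantom septa are planar and pores are circular; no curvature or
  septal-ridge geometry is modelled, so surface-to-volume ratios are
  phantom-specific, and only their ordering across stages is
  meaningful.
* The 2-voxel-σ surface smoothing biases S_A low for structures under
  ~3 voxels; late-stage phantoms sit near this limit by design.
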