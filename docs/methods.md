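# Methods

`sheath3d` reconstructs human splenic capillary sheaths in 3D from serial
brightfield sections double-stained with DAB (brown: SMA marking arteriolar
smooth muscle, plus CD34 marking endothelium) and Fast Blue (CD271 marking
stromal sheath cells and follicular dendritic cells), and quantifies how
many sheaths sit in a post-arteriolar position. Because no raw specimen
scans are publicly deposited, the package ships a synthetic-specimen
generator with voxel- and graph-level ground truth; every stage is
validated as parameter recovery against that truth.

## Pipeline model

1. **Registration.** Consecutive sections are related by an unknown rigid
   motion. Pairwise alignment uses windowed, mean-free cross-correlation of
   a *saturated* stain-density image (density capped at 15 of 255), so a
   few strongly stained — and often oblique, hence between-section-drifting
   — vessels cannot outvote the ubiquitous faint tissue texture. Rotation
   is found by a small-angle sweep (±6° coarse at 1°, ±0.75° fine at
   0.125°) scored by the post-alignment interior RMS residual, and is
   accepted only when it improves that residual by more than 15%:
   consecutive sections are similar but not identical, and a weakly
   supported rotation does more harm than assuming none. Transforms are
   chained outward from the middle section to halve accumulated drift;
   resampling is bilinear with white fill, which vanishes in both stain
   channels. On phantom stacks (noise SD ≤ 5, misalignment ≤ 10 px) mean
   residuals are ≈ 0.4–1.3 px and ≤ 0.5° across seeds; the error is
   dominated by genuine between-section content change, not by the
   estimator.

2. **Channel separation.** Naive device-independent RGB→CMYK (no ICC
   profile): K′ = 1 − max(R,G,B); C′ = (1 − R − K′)/(1 − K′), with C′ = 0
   at the K′ = 1 singularity. Channel C captures the blue chromogen,
   channel K the brown. Channels are kept as stain intensity (higher =
   more stain). Colour deconvolution with measured absorbance vectors is
   deliberately not used. No white-balance normalisation is applied before
   the conversion.

3. **Inter-slice interpolation.** Sections sample 0.5 µm/px in-plane but
   7 µm axially (14:1 anisotropy). Six intermediate frames per gap bring
   the z sampling to 1 µm/image. Frame t of n uses symmetric two-sided
   warping with a linear cross-blend, w = t/(n+1):
   (1−w)·warp(a, w·f_ab) + w·warp(b, (1−w)·f_ba). Dense flow comes from
   iterative Lucas–Kanade (smoothness-regularised, coarse-to-fine); since
   tissue motion is channel-independent, the pipeline estimates each gap's
   flow once on the summed stain image and reuses it for both channels.
   Original slices appear unchanged at their grid positions and blending
   is convex, so intensities stay within the source range. The residual
   0.5 vs 1 µm xy/z anisotropy is carried in the volume's spacing metadata
   and honoured downstream, never resampled away.

4. **Morphology.** Channel-specific 3D grayscale operations on the
   interpolated grid, kernel triples read as structuring-element
   half-extents (rx, ry, rz) in voxels. Brown channel: closing (7,7,2)
   then Gaussian blur σ = 1.0. Blue channel default: closing (2,2,1),
   dilation (11,11,3), closing (14,14,4), blur σ = 1.0 — the aggressive
   restoration needed because unstained sheath-cell nuclei and
   intercalated macrophages interrupt the CD271 signal. The "up to
   14-14-4" closing is applied to the whole channel (a config flag), as no
   partial mask is defined. Box kernels run as separable max/min filters;
   boundaries pad with the morphological neutral element (0 for dilation,
   255 for erosion) and reflect for the blur. All kernel sizes are
   configuration values.

5. **Meshing.** Marching cubes (Lewiner variant with ambiguity
   resolution, as implemented in scikit-image) at iso-values of 120/255
   (brown) and 30/255 (blue) by default, per-ROI overridable; vertices sit
   at linearly interpolated crossings scaled to µm. The volume can be
   zero-padded one plane per face so structures cut by the block surface
   close there instead of splitting into disconnected inner/outer sheets.
   Healing is a voxel remesh: the surface is rasterised at a pitch of
   (main diagonal)/2^depth (depth 9 default, grid capped at 320 cells per
   axis), holes are sealed by a distance-transform closing
   (dilate → flood-fill → erode, extensive, so the input shape is always
   contained), and a watertight surface is re-extracted from the lightly
   smoothed occupancy field. Smoothing is Taubin's shrink/inflate pair
   (λ = 0.5, µ = −0.53, 10 iterations) on the uniform vertex Laplacian —
   unlike pure Laplacian smoothing it preserves vessel calibre (tested:
   volume drift under one third of the Laplacian baseline). Unconnected
   components whose own bounding-box main diagonal falls below 5% (blue)
   or 2% (brown) of the ROI diagonal are removed — 71 µm and 28 µm for the
   standard 1 mm × 1 mm × 168 µm block. The threshold derives from the ROI
   diagonal while the measured quantity is the component's own diagonal;
   both choices are exposed in configuration. Mesh volume is the signed-
   tetrahedron sum over watertight components; open (boundary-cut)
   components fall back to voxel-count × voxel-volume of their above-iso
   connected region, flagged in the record.

6. **Annotation and classification.** Feeding arterioles are painted red
   by geodesic spheres: all vertices within a given shortest-path distance
   (Dijkstra over the mesh edge graph with Euclidean weights) of a seed
   vertex. Geodesic rather than Euclidean distance prevents label bleed to
   vessels that are close in space but not surface-connected. Seeds are a
   JSON list of (point, radius), replacing the original interactive
   annotation; in phantom mode they are derived from the truth vessel
   graph (one stroke per arterial segment). A blue component is
   **post-arteriolar** (green) when its minimum Euclidean distance to any
   red vertex is ≤ ε = 5 µm (≈ one cell radius; configurable and echoed in
   the run manifest), otherwise **undefined** (blue) — such sheaths may be
   post-arteriolar too, but their feeding vessel was cut at the block
   surface. Since capillary sheaths are periendothelial by definition,
   blue components farther than 20 µm from the entire vessel mesh are
   treated as FDC-like confounders and excluded from the sheath table —
   the mesh analogue of the expert disregarding follicular FDC meshes.
   Any fixed ε is an operationalisation of what was originally an expert
   judgement made in VR.

7. **Quantification.** Per ROI and pooled: sheath count, post-arteriolar
   count and percentage, max/median component volume, boundary-cut count,
   and the ROI reference volume (width·height·pixel² × sections·thickness;
   0.168 ≈ 0.17 mm³ for the standard block, 1.85 mm³ over 11 such ROIs).

## The virtual specimen

`phantom.build_phantom` constructs a block of red pulp with known truth:

- **Arterial tree.** Per arteriole, a feeding artery stub and a main
  arteriolar vessel that divides sequentially and dichotomously: at each
  division an unsheathed main vessel continues and a side branch ends in a
  sheath candidate, until the main vessel itself terminates in one. Roots
  are spread apart (≥ 35% of the block width) and growth pulls back toward
  the interior near walls.
- **Sheaths.** Post-arteriolar sheaths are annular cuffs (inner radius =
  capillary radius 3.5 µm, wall 6 µm, length 30–150 µm by default)
  starting exactly at an arteriole end node, around a capillary that
  continues past the cuff. "Detached" sheaths stand for sheaths whose
  feeding vessel lies outside the block. Cuff placement keeps a 40 µm
  surface clearance between distinct sheaths where geometrically possible
  (red-pulp cords separate real sheaths, and the dilation + closing
  pipeline would otherwise fuse neighbours); candidate directions are
  retried and shortened before a crowded placement is accepted.
  `true_volume_mm3` records the painted voxel volume of each cuff — the
  amount of sheath stain the specimen actually contains.
- **Confounders and texture.** Optional CD271+ FDC blobs (15–30 µm radius
  spheres) placed away from the vasculature, as follicles are; and a faint
  brownish cord texture (thresholded smooth random field, crisp in-plane
  edges, correlated over ~2 sections in z) standing for the ubiquitous
  weakly stained red-pulp fibroblasts — well below the meshing iso-values,
  and the anchor that registration locks onto in real tissue.
- **Degradations.** Per-section rigid misalignment (magnitude ≤ 8 px,
  rotation ≤ 0.5°, rendered on a reflect-padded canvas so no frame-pinned
  fill border appears), additive Gaussian noise (SD 4), and stain dropout:
  spherical patches (3–8 µm) erase sheath stain, each with a fixed
  uniform draw applied when it falls below the dropout rate — so the
  erased set grows monotonically with the rate at a fixed seed.
- **Rendering.** The truth label volume is kept at ~1 µm sub-planes (7 per
  7 µm section); each section is the mean palette projection of its slab
  (a linear stand-in for Beer–Lambert absorbance). Palette: DAB-like brown
  (110, 70, 40), Fast-Blue-like blue (60, 70, 150), warm white background
  (245, 243, 240) — chosen so the CMYK C/K split separates them cleanly.
- **Randomness.** One `SeedSequence` split into a build stream and a
  render stream, in documented draw order; identical (spec, seed) gives
  bit-identical sections.

What the phantom does **not** model: photorealistic staining physics,
scanner optics, follicle/trabecula cytoarchitecture beyond FDC blobs,
non-rigid section deformation, and real CD271 intensity variability.
Passing recovery tests therefore demonstrate the correctness of the
reconstruction machinery under controlled degradations, not performance on
real scans.

## Study calibrations on phantoms

- **Iso-values.** On real stains the iso-value is chosen per ROI against
  the actual chromogen intensities; the printed 120/30 remain the
  configuration defaults. The phantom's colours are known exactly, which
  admits two calibrations, each matched to its study question. The
  *classification* study uses the half-crossing between background and
  stain (C ≈ 77, K ≈ 78): tight surfaces that keep neighbouring cuffs
  maximally separate. The *volume-recovery* study uses a
  partial-volume-inverting threshold (`iso_calibration="mass"`): slab
  integration over 7 µm sections dims thin cuffs asymmetrically, and the
  CMYK channel is nonlinear in the stain mixing fraction, so each voxel's
  intensity is inverted through the known mixing curve to a stain volume
  fraction and the threshold is chosen so that the above-iso voxel count
  preserves that total (C ≈ 51 on typical phantoms; the brown channel
  keeps its mixing-curve half-crossing, since faint cord texture carries
  genuine K mass that would distort the inversion).
- **Blue-channel kernels.** The printed dilation 11-11-3 + closing
  14-14-4 restore continuity across the real specimen's large unstained
  inclusions at the cost of inflating sheath volume (a ~5.5 µm radial
  dilation roughly triples a thin cuff's volume) and of fusing structures
  within ~25 µm. The phantom's dropout patches are ≤ 8 µm, so phantom
  studies use the closing calibrated to them: (7,7,2) for the realistic
  recovery study, (4,4,1) for noiseless volume-recovery runs (no dropout
  to bridge; keeps the capillary lumen open so cuff volume is unbiased).
  Kernels are config values; the defaults stay as printed.

## Problem sizes

Desk-scale runs use 384 × 384 px (192 × 192 µm) blocks of 24 sections —
the full axial extent of the study block at about a fifth of its lateral
extent. The noiseless recovery phantom holds 5 sheaths (2 post-arteriolar)
verified at build time to be well separated; the realistic recovery study
pools 4 independent phantoms of 9 sheaths each (4 post-arteriolar = 44.4%,
matching the configured 44.5% up to rounding) with noise, misalignment,
dropout and FDC confounders active. Sheath density in these blocks is a
few-fold higher than in the real 1 mm ROIs; the placement clearance above
compensates where geometry allows.

## Numerical choices and edge cases

- Iso-values outside a volume's data range yield an empty mesh (logged),
  not an error; empty meshes propagate as empty.
- `build_volume` requires the target z spacing to divide the section
  thickness to an integer factor and suggests the nearest valid target
  otherwise; plane count is exactly n + (n−1)(factor−1).
- Degenerate (constant) images produce exactly zero flow; flat images
  raise `UnregistrableError`, which the stack driver converts to an
  identity transform with a log entry.
- Taubin smoothing requires a shrink/inflate pair (λ > 0, µ < 0) and
  leaves vertex count, faces and labels untouched.
- Geodesic seeds snap to the nearest vertex within 25 µm; farther seeds
  raise (or are skipped in batch mode, e.g. when a seed lands on a pruned
  fragment).
- Boundary contact uses the ROI axis-aligned box in µm, half-open on the
  max faces, with a one-voxel tolerance.
- Pipeline ordering: interpolation runs on the full registered frame and
  ROI cropping is available before it (both orders are reachable through
  the driver); either order is defensible.

## Known limitations

- Rigid registration only; real sections also deform non-rigidly.
- The FDC exclusion rule (vessel distance > 20 µm) is a proxy for expert
  judgement; FDC clusters that touch vessels would not be excluded.
- Sheaths that genuinely touch (or are fused by the restoration
  morphology) are counted as one component — on dense phantoms the
  recovered component count exceeds or falls short of the placed sheath
  count even when the pooled class fraction is recovered.
- Boundary-cut component volumes use the voxel fallback and depend on the
  iso-value more strongly than watertight mesh volumes.
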