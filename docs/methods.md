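# Methods

`micropattern` quantifies spatial patterning in immunofluorescence
z-stacks of circular micropatterned pluripotent-stem-cell colonies. All
intensity quantification is voxel-based: dense epithelial colonies defeat
reliable per-cell segmentation, so per-cell analysis is used only where a
centroid suffices (dot displays, morphometrics), never for intensity
statistics.

## Coordinate and intensity conventions

Stacks are `(channel, z, y, x)` arrays with physical voxel spacing
`(dx, dy, dz)` in μm. Voxel indices are 0-based; the physical position of
voxel *i* along an axis is its center, `(i + 0.5)·d`. Intensities are
arbitrary units on a 16-bit scale (0–65535), the common dialect of
microscopy TIFF. Radial distance is computed in xy only — the colony is a
flat disc and its vertical structure is measured separately as a height
profile.

## Synthetic colony generator

The generator emulates confocal acquisition of colonies 80–1000 μm in
diameter so that every downstream stage can be validated against known
ground truth.

**Cell placement.** Nuclei centroids are placed by Poisson-disc (dart
throwing) sampling in the colony disc at a prescribed areal density
(default 4 cells / 1000 μm², i.e. ~11 μm center spacing — a confluent
epithelial monolayer). The minimum spacing is derived from the density as
`0.7/√λ`, which keeps the process safely below random-sequential-
adsorption saturation; a spec whose density and spacing exceed that limit
raises an infeasibility error rather than silently under-placing. The
requested cell count is always realized exactly. Cells sit in a
monolayer plane with ±1 μm z jitter.

**Nucleus rendering.** Each nucleus is a flat-core ellipsoid (half-axes
4 μm in xy, 3 μm in z) with a Gaussian shoulder of width 1.5 μm,
truncated at three shoulder widths. Inside the core, every channel holds
its model-assigned level *exactly*; overlapping supports combine by
maximum. The exact flat core is deliberate: it makes noise-free stacks a
bit-exact oracle for masking and profiling, while the shoulder preserves
the blob-like confocal appearance that peak detection relies on. The
nuclear (Hoechst) channel level defaults to 20 000 a.u.

**Marker domains.** Each marker channel has a radial domain model —
`uniform`, `center_high`, `edge_high` or `annulus` — with boundary radii,
a logistic boundary sharpness in μm (0 = hard step), inside/outside
levels (defaults 10 000 / 200 a.u.: strong nuclear staining vs residual
background binding), and an optional salt-type misexpression probability.
The marker level is assigned per cell at the cell's radius and painted
over that cell's blob, matching nuclear-localized transcription-factor
staining. Time courses share the placement seed across timepoints and
apply per-channel level multipliers and boundary replacements; identity
transitions reproduce the 0 hr stack bit-for-bit.

**Noise.** Applied last, after ground truth is recorded: an additive
background (default 500 a.u.) with an optional planar tilt
(0.05 a.u./μm), signal-dependent noise with variance-to-mean ratio 2
(Gaussian approximation of shot noise), and Gaussian read noise
(σ = 50 a.u.), clipped to the 16-bit range. All randomness derives from a
single integer seed; identical spec + seed gives bit-identical stacks.

**Vertical structure.** Small colonies (≤140 μm) are generated with
deeper stacks, approximating their growth into taller aggregates. A
ridge model stacks cells in up to N layers (4 μm apart) within an
annulus; the layer count tapers triangularly from the annulus center so
the "volcano" height profile has a well-defined true peak radius — a
flat-topped ridge would leave the peak position undefined to within the
annulus width.

**2D section fixtures** paint polygonal regions with per-channel mean
levels plus Gaussian noise; overlapping regions are rejected. Ground
truth records per-region true means and pixel masks.

What the generator does *not* emulate: signaling dynamics, cell movement
or EMT mechanics (domains are prescribed, not emergent), nuclear shape
variability, chromatin texture, optical PSF blurring between z planes,
tiling/stitching artifacts, and autofluorescence structure. Tests passing
on these synthetics therefore demonstrate the correctness of the
*quantification arithmetic and its robustness to additive/shot noise*,
not performance on every real-microscopy pathology.

## Nuclear probability mask

The mask stands in for an interactively trained pixel classifier, with
the same output contract (a per-voxel nuclear probability in [0, 1]):
anisotropic Gaussian smoothing (default σ = 1 μm, scaled per axis by the
voxel spacing), an Otsu threshold *t*, and a logistic soft assignment
`p = σ((I − t)/(0.1·t))`. Two numerical details matter:

- Otsu is computed over voxels above 5% of the smoothed maximum. Colony
  stacks are mostly empty background; an unrestricted histogram pushes
  the threshold far below the nuclear boundary and inflates the mask
  with halo voxels (voxel F1 vs ground truth drops from ≥0.95 to ~0.4).
- The smoothing σ is kept at 1 μm (a quarter of the nuclear diameter's
  half-axis scale): wider kernels blur the nuclear edge outward and
  again degrade the F1 against the half-maximum object footprint.

The binarization `p > 0.5` is exactly `I > t` and is invariant to
rescaling the channel by any k > 0. The default binarization threshold
of 0.5 is a documented choice. Externally produced masks (HDF5 or float
TIFF) are accepted everywhere a built-in mask is.

Background handling: a rolling-ball subtraction (per z-slice, per
channel, ImageJ-style, with automatic downscaling for large radii) for
structured backgrounds, and a constant estimator (per-channel median of
out-of-mask voxels) for the flat additive component. The pipeline uses
the constant estimator by default — for ratio quantities such as the
central-marker fold change, an unsubtracted additive offset would bias a
true 2.0 ratio toward ~1.9.

## Centroid detection

3D local maxima of the smoothed nuclear channel inside the mask, merged
so no two peaks are closer than a minimum separation (default 0.8× the
expected inter-nuclear distance; in the pipeline, 0.8× the generator's
known minimum spacing). Per-channel cell intensity is the mean over a
3 μm ellipsoidal neighborhood. At study-regime density with default
noise this yields precision and recall ≥ 0.9 (in practice ≈ 1.0);
detections feed dot summaries and morphometrics only.

## Radial profiling

Each masked voxel within the fitted colony radius is assigned its
xy-distance from the colony center and binned into half-open 10 μm bands
(final bin closed; 100 bins for a 1000 μm colony — fine enough to resolve
domain structure without starving bins). Binned means are computed in
float64 by bincount and agree with a per-voxel enumeration oracle to
1e-9 relative; the bin voxel counts partition the masked voxel set
exactly.

- **Center** (the upstream protocol leaves it undefined): the
  probability-weighted centroid of the thresholded mask projected to xy.
  This works on cropped single-colony stacks and matches the symmetric-
  colony limit. Note that a missing 10% angular sector necessarily
  shifts the centroid by ~7% of the radius (the exact centroid of the
  remaining shape); center estimation reproduces that exact centroid.
- **Fitted radius**: the 99th percentile of masked-voxel radii, required
  within 15% of the nominal micropattern radius for a valid colony.
- **Averaging across colonies** is colony-weighted: each colony's bin
  mean enters with equal weight, and bins missing in some colonies
  average over the colonies that have data (tracked in `n_colonies`).
- **Normalization**: `max100_per_timepoint` scales each channel so its
  maximum bin mean is 100; `max100_across_timecourse` takes the maximum
  over a supplied profile set so only the peak timepoint reaches 100;
  `hoechst_relative` divides bin-by-bin by the nuclear-stain profile.
  The maximum is taken over *bin means*, not raw voxel maxima, which are
  noise-dominated.
- **Boundary recovery** (for validation): the half-maximum crossing of a
  channel's profile, linearly interpolated between bin centers; flat
  profiles and profiles without a crossing raise.

## Coexpression gating

One paired intensity per masked voxel. Gates are the 0.99 quantile of
the 0 hr reference distribution per channel — markers absent at the
start of differentiation define their own negative population, and the
high default quantile tolerates the rare spontaneously differentiated
cells present at 0 hr. Positivity is strictly greater-than (ties count
negative — a conservative call). Quadrant percentages are exact
fractions of all pairs and sum to 100. Gating is per colony, with
pooling across colonies available by concatenating pairs; the plotting
density is a fixed 128×128 histogram on log1p axes, avoiding kernel
bandwidth choices.

## Morphometrics

- **Height profile**: per radial bin, the z-extent of the mask between
  the 2.5th and 97.5th percentiles of voxel z (stray voxels would
  otherwise set the colony height), times dz, plus one voxel.
- **Nuclei per 100 μm**: counting positions are 10 full-width chords
  across the colony. `strip` mode counts centroids within a band
  (default width 12 μm ≈ 1.5 nuclear diameters) around the segment —
  this recovers a known linear density and scales linearly with areal
  density. `transect` mode counts the distinct nearest nuclei
  encountered walking the segment — the chain of nuclei one counts by
  eye in a side view — and scales with √(areal density): a 4× increase
  in cell number at fixed area doubles the transect count.
- **Inter-nuclear distance**: nearest-neighbor 3D distance per centroid,
  or distances over explicitly supplied adjacent pairs (mirroring
  manual adjacent-nucleus measurement).

## Section quantification

Polygon ROIs select pixels by center containment; point ROIs use a disc
of default radius 5 μm (a typical nuclear radius at section
magnification). Per-ROI channel means are normalized to the Hoechst mean
over the *identical* pixel set, making the values invariant to global
intensity rescaling. Group summaries report mean ± SD with the n−1
denominator. ROIs are supplied as recorded JSON (polygon/point), keeping
the downstream arithmetic reproducible; no anatomy detection is
attempted — region identity comes from the ROI file.

## Pipeline and determinism

A single YAML config drives generate/ingest → mask → background →
centroids → profile → gate → morphometrics. Every stage logs the
parameters actually used (after defaults) into a JSON manifest along
with a SHA-256 checksum of every output. Masks are written without HDF5
timestamps and TIFFs without date tags, so identical config + seed
reproduces byte-identical outputs; a failing stage is named in the
manifest and the partial outputs are flagged. Seeds for multi-colony
runs are derived from the run seed and kept below 2³¹.

## Problem sizes used in validation

The test suite and the acceptance script validate on: 500 μm colonies
(≈785 cells) for masking/detection quality; 1000 μm colonies at
2 μm/voxel xy (≈3140 cells, ≈480 000 masked voxels) for flatness,
gating, fold-change and volcano-height checks; averaged sets of 3–5
colonies across 10 seeds for boundary recovery; and 225 μm two-colony
runs for end-to-end determinism. These sizes resolve every quantity
being checked while keeping a full validation run around a minute.

## Known limitations

- Domains are radially symmetric by construction; angular asymmetries
  (observed in small aggregates) are not modeled, and no angular
  profiling is provided.
- The stand-in classifier is intensity-based; it will not separate
  touching nuclei of differing brightness the way a trained texture
  classifier can, and it requires a nonempty, non-uniform nuclear
  channel.
- Small-colony 3D aggregate morphology is approximated by deeper stacks
  and the ridge model only; full 3D aggregate shapes are out of scope.
- Proprietary microscope formats (CZI/LIF) and tile stitching are
  upstream concerns; stacks are assumed pre-stitched, one colony each.
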