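# micropattern

Voxel-based quantification of spatial patterning in micropatterned
pluripotent-stem-cell colonies — radial fluorescence profiling,
voxel-level coexpression gating, and colony/embryo morphometrics — plus a
ground-truthed synthetic colony generator so every stage is testable
without microscopy data.

## The problem

When mouse epiblast-like cells differentiate on circular micropatterns
(80–1000 μm diameter) under BMP/WNT/ACTIVIN/FGF, cell fates organize
into concentric radial domains: a central epiblast-like population
(SOX2), a mid primitive-streak ring (BRACHYURY), and an outer
embryonic/extraembryonic mesoderm ring (GATA6/CDX2). Quantifying that
patterning from confocal z-stacks is a segmentation-hostile problem —
thousands of tightly packed nuclei per colony — so the analysis here is
voxel-based throughout:

- **Radial profile.** Every voxel inside the 3D nuclear mask is assigned
  its in-plane distance r from the colony center; the mean fluorescence
  per discrete radial band, I_c(r) = ⟨I_c(v) : r_v ∈ [r, r+Δr)⟩, is
  computed per channel and per colony, averaged across colonies with
  equal colony weight, and normalized to the highest level of expression
  (shown as 100) within a timepoint or across a time course, or to the
  Hoechst nuclear stain.
- **Coexpression gating.** Each masked voxel contributes one paired
  intensity (I_A, I_B); gates are the 0.99 quantile of the 0 hr
  reference distribution (markers absent before differentiation), and
  the four quadrant percentages of total voxels are reported.
- **Morphometrics.** Colony height vs radius (robust z-extent of the
  mask per radial band), nuclei per 100 μm along counting chords, and
  inter-nuclear (nearest-neighbor) distances.
- **Section quantification.** Polygon/point ROIs on 2D sections with
  per-channel means normalized to Hoechst over the identical pixels.

The nuclear mask itself is produced by a deterministic stand-in for an
interactively trained pixel classifier (Gaussian smoothing → Otsu →
logistic soft assignment); externally produced probability masks are
accepted in its place. See `docs/methods.md` for the full model,
parameter defaults and numerical choices.

## Worked example

Generate a 1000 μm colony with the three concentric posterior domains,
mask it, profile it, and read the domain boundaries back:

```python
import numpy as np
import micropattern as mp

spec = mp.SyntheticColonySpec(
    diameter_um=1000.0, seed=42,
    marker_models=[
        mp.MarkerDomainModel("sox2", "center_high", (250.0,), 15.0),
        mp.MarkerDomainModel("brachyury", "annulus", (250.0, 400.0), 15.0),
        mp.MarkerDomainModel("cdx2", "edge_high", (400.0,), 15.0),
    ])
grid, truth = mp.generate_colony(spec, keep_clean=False)
mask = mp.classify_nuclei(grid)
grid = mp.subtract_constant_background(grid, mp.estimate_background(grid, mask))
geom = mp.estimate_center(mask, nominal_radius_um=500.0)
profile = mp.radial_profile(grid, mask, geom)
norm = mp.normalize_profile(profile, "max100_per_timepoint")
for ch, true_b in (("sox2", 250.0), ("cdx2", 400.0)):
    print(f"{ch}: half-max boundary at {mp.recover_boundary(norm, ch):.1f} um "
          f"(true {true_b:.0f})")
```

prints

```
sox2: half-max boundary at 249.5 um (true 250)
cdx2: half-max boundary at 400.4 um (true 400)
```

i.e. from 481 714 masked voxels of a 3142-cell colony with default
acquisition noise, the recovered half-maximum crossings of the central
and outer domains land within half a bin width (10 μm bins) of the
generative boundaries. The normalized profile peaks where each domain
lives: sox2 at r ≈ 65 μm (center), brachyury at r ≈ 325 μm (mid ring),
cdx2 at r ≈ 495 μm (edge).

The same workflow runs from the shell:

```sh
micropattern fixtures plus_bmp --out demo --seed 42
micropattern mask demo/plus_bmp_72hr_meta.json --out demo/mask.h5
micropattern profile demo/plus_bmp_72hr_meta.json demo/mask.h5 \
    --normalization max100_per_timepoint --out demo/profile.csv
```

and a whole batch (generate → mask → profile → gate → morphometrics)
runs from a single YAML config via `micropattern run config.yaml`,
emitting a manifest with the parameters used and a SHA-256 checksum of
every output; identical config + seed reproduces identical bytes.

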