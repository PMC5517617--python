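# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Imaging geometry and coordinate conventions

All analyses assume a volumetric fluorescence stack with voxel spacing given
in μm; the default geometry is 5 μm in-plane and a 5 μm z-step, typical of a
10× confocal acquisition of a cleared organ. Volumes are indexed (x, y, z)
with 0-based voxel indices and half-open z-ranges; the physical position of a
voxel center is (index + 0.5) × spacing. Downsampling (default bilinear,
factor 0.5 when whole-organ stacks are too large at native resolution)
applies in-plane only, because z is already coarse; a config flag is the
place to change that, not the code. Voxel size is recomputed from the
realized output shape so the physical extent of the sample is conserved.

Intensity normalization rescales each channel so its 0.999 quantile maps to
1.0. A robust quantile rather than the maximum sets the scale because
isolated hot pixels (detector noise, debris) would otherwise determine it;
the transform is linear, so voxel ordering is preserved. All-zero volumes
pass through unchanged with a warning.

## MIP sectioning and islet detection

The volume is partitioned into consecutive z-slabs of 150 μm (≈ three
standard deviations beyond the mean islet size, which keeps a whole islet's
brightest cross-section inside one slab) and each slab is max-projected.
The final, possibly shorter slab is analyzed too: discarding tissue would
bias organ-level counts.

Per section: Otsu's global threshold (256-bin histogram), one binary
erosion + dilation pass with a 3×3 (8-connected) structuring element to
remove noise, 8-connected component labeling, and a minimum region size of
5 px (≈ 125 μm² at 5 μm/px, roughly one endocrine cell). Constant sections,
where Otsu is degenerate, produce no candidates.

Each candidate is then refined at full local resolution: its bounding box is
expanded by 20 px (100 μm) laterally, max-projected over the candidate's
z-range, re-thresholded with Otsu, cleaned with one dilation + erosion pass
(the closing order, which bridges small gaps inside an islet rather than
shrinking it), and the connected component with the largest overlap with the
original candidate is kept. The morphological order differs deliberately
between the two stages (open at the section stage, close at refinement) and
both orders are configurable. The convex hull of the refined component
defines the circle-equivalent radius r = √(A_hull/π) · pixel size; a
moments-based ellipse fit supplies major/minor semi-axes and orientation.
Candidates that vanish under the local threshold are flagged
`refinement-empty`, never silently dropped.

Because each 150 μm slab is analyzed independently, an islet spanning a slab
boundary yields one record per slab. An optional post-hoc deduplication
(off by default, for fidelity to the per-section method) clusters records in
adjacent sections whose centroids lie within one population-mean radius and
keeps the largest-radius record — the one nearest the equator. Benchmarks
that compare detected counts against ground truth enable it.

## Innervation scoring and artifact exclusion

The islet neighborhood is the filled convex hull dilated outward by 2 px
(10 μm) — dilation is Euclidean (distance transform ≤ offset), so the
neighborhood is exactly the set of pixels within the offset of the hull.
The neighborhood includes the islet interior: nerve signal both surrounding
and within the islet counts.

Positive nerve pixels are called by an adaptive local-mean threshold
(block 51 px, offset 0 — the block must be much wider than a fiber so the
local mean is pulled down by background) computed on the full section, then
eroded once with a 3×3 element to suppress isolated supra-threshold noise.
The interaction score is positive pixels inside the neighborhood divided by
islet pixel area; it is 0 exactly when the nerve channel is null, and
monotone in added positive pixels.

Artifact exclusion flags records whose neighborhood positive-pixel fraction
or nerve-intensity histogram entropy (Shannon entropy of the 256-bin
histogram over the neighborhood, in bits) lies more than 3 SD from a
reference population's mean, two-sided — bright non-neural debris inflates
the positive fraction, while texture-less autofluorescent blobs show
anomalous entropy in either direction. Thresholds are computed once from the
reference (the pooled current experiment when no held-out reference is
supplied) and held constant across samples; with a zero-variance reference
nothing is flagged (strict inequality). Under Gaussian scores the expected
exclusion fraction per criterion is 2·Φ(−3) ≈ 0.27%, which the tests verify
by Monte Carlo. Flagged records are kept with a reason string, never
deleted.

## Resampling power experiments

`sampling_experiment` draws N islets with replacement from each of two
populations, compares group means with an unpaired two-tailed t-test
(classic equal-variance form; Welch by flag) at α = 0.05, repeats 100 times
(configurable), and reports the fraction of significant repetitions plus the
min–max range of per-repetition means. Min–max (rather than a percentile
interval) is the reported range; a percentile option exists. A single seeded
generator drives all repetitions; results are deterministic given the seed.

## Virtual 2D sections and the 2D-vs-3D comparison

`virtual_sections` extracts MIP slabs of a stated thickness starting at
z = 0; the "every third" spacing turns a ~1 mm volume into eight 40 μm
sections with a ×3 count scale factor (total slabs ÷ slabs sampled).

`compare_2d_3d` runs the full detection pipeline on sections of each
thickness in {5, 10, 20, 40, 80, 110} μm, then re-measures every detected
islet volumetrically: same x,y bounding box, z extended by mean + 3 SD of
the radii from a full 3D pass over the same volume (the sample's own islet
statistics), max-projected and re-thresholded. Each (r₂D, r₃D) pair is
classified with a 10 μm inclusion threshold and a 10% relative tolerance:

| class | rule |
|---|---|
| excluded_small | r₂D < 10 and r₃D < 10 |
| false_negative | r₂D < 10 ≤ r₃D |
| false_positive | r₃D < 10 ≤ r₂D |
| within_tolerance | both ≥ 10 and \|r₂D − r₃D\|/r₃D ≤ 0.10 |
| underestimate / overestimate | both ≥ 10, relative error > 10%, by sign |

The rules are exclusive and exhaustive; boundary conventions are "< 10 μm is
excluded" (10.0 is measurable) and the tolerance is inclusive. The
underestimation factor (r₃D − r₂D)/r₃D is summarized per thickness over
pairs measurable in 3D (r₃D ≥ 10 μm), with its standard error. Slicing a
sphere at a uniform random offset gives E[r₂D/r₃D] = E[√(1 − u²)] = π/4 in
the thin-slice limit, so the mean factor approaches ≈ 0.215 as thickness → 0
and 0 as thickness approaches the volume depth; `thin_section_radius_ratio`
and `slab_section_radius` provide the analytic Monte-Carlo oracles.

`top_k_comparison` averages the largest k = 20 radii per section (all of
them when fewer than 20 exist) and compares 2D against 3D with a two-sided
Mann-Whitney test; ties in the sort are broken by islet id for determinism.

## Clearing kinetics and staining quantification

Clearing progress is modeled as a single-reactant first-order transformation,
y = Y_max(1 − e^(−kt)) with k in h⁻¹, fit by bounded least squares.
Initialization is Y_max₀ = max(y), k₀ = 1/median(t) with five multiplicative
perturbations of k₀ spanning two decades; the best-SSE converged start wins,
and a fit that converges from no start is an error listing the starts tried.
An all-zero series returns a fit flagged `degenerate` (no clearing is a
valid assay outcome). Rates are compared across conditions as k/k_reference.
Fits are invariant to time-unit rescaling up to the matching rescaling of k.

Staining signal-over-background on a 2D section: Otsu threshold, 1 px
erosion, morphological closing, then region filtering by area ∈ [20, 2000] px
and roundness 4π·area/perimeter² ≥ 0.5 to drop non-cellular features
(defaults; all configurable since they depend on magnification). The ratio
is mean intensity over retained region pixels ÷ mean intensity over all
remaining pixels — the background is everything outside detected regions,
not an annulus. No retained regions → NaN with a warning, never a silent 0.
Protein loss is simply μg protein (BCA) per mg starting tissue weight.

## The synthetic-data generator

The generator emulates the features of cleared-pancreas data that the
pipeline's correctness depends on, with exact bookkeeping of what it drew:

- **Islets** as solid bright spheroids with lognormal radii (median 40 μm,
  shape 0.5, clipped to 10–150 μm — the tens-to-∼150 μm range of developing
  islets); optional per-axis ratio jitter for non-spherical variants.
  Spheres are defined in μm space, so they are round under anisotropic
  voxel spacing.
- **Innervation** as a partial spherical shell (default 10 μm thick) around
  each islet: exactly round(f · n_shell) shell voxels are set positive, so
  the realized occupancy matches the drawn fraction f to one voxel —
  emulating the peri-islet sheath at a controllable coverage. Optional
  random-walk filaments add unassociated nerve signal.
- **Background** Gaussian noise, sd 2% of the channel maximum, clipped at 0
  — nonzero but small enough that Otsu stays stable.
- **Placement** by rejection sampling (budget 10,000 attempts per islet,
  then a deterministic error naming the violated constraint) under a
  center-separation floor and non-overlap of spheres. An optional
  `xy_clearance` additionally separates the *projected* xy outlines;
  spheres far apart in z still overlap in a slab MIP, so benchmarks that
  require isolated islets (exact count recovery) set it, while the
  stereology sweep does not.

The generator does **not** simulate optical physics — no point-spread
function, depth attenuation, refractive artifacts, or acinar/ductal
autofluorescence — and no quantitative model of real nerve-channel texture
was available, so the shell + filament model is a stand-in. Passing tests
therefore demonstrate the correctness of the measurement chain on data whose
ground truth is known, not robustness to every artifact of real acquisitions.

## Problem sizes and calibration checks

The standard verification runs (mirrored by `scripts/acceptance.py`):

- Projection fidelity: 20 random volumes, exact pixel-wise equality with a
  direct z-range maximum.
- Detection recovery: 50 noiseless spheres (radii uniform 15–100 μm) in a
  2.2×2.2×0.8 mm volume, separation ≥ 150 μm with 60 μm xy clearance;
  adjacent-section deduplication on. Expected: exact count, ≥ 95% of radii
  within 10%.
- Stereology sweep: 64 lognormal islets in a 1.3×1.3×1.2 mm noiseless
  volume, thicknesses {5, 10, 20, 40, 80, 110} μm plus a full-depth run.
  The mean underestimation factor must be non-increasing in thickness up to
  Monte-Carlo error — a rise between adjacent thicknesses counts only when
  it exceeds twice the standard error of the difference — and ≈ 0 at full
  depth. The thin-slice analytic ratio uses 10⁵ draws (±1% of π/4).
- t-test calibration: identical populations, n = 50, 100 repetitions × 200
  runs (20,000 tests); the significant fraction must sit in the 99% binomial
  band around 0.05. Power/variability patterns use a true 10% mean
  difference (45 vs 49.5 μm, sd 10) over n ∈ {10, 30, 50, 100, 150} at 300
  repetitions, with monotonicity slack sized to 2σ binomial noise.
- Innervation: pixel-counting oracle equality, exact zero on a null
  channel, and the 2·Φ(−3) exclusion fraction at 2×10⁵ Gaussian records.
- Kinetics: the simulated assay reads absorbance every 2 h for 96 h
  (49 points). Noiseless recovery to 10⁻⁶ relative error; median relative
  error of k ≤ 5% over 100 series at 5% noise. Sparser designs (e.g.
  13 points over 48 h) sit at the boundary of that bound — rate recovery is
  design-limited, not optimizer-limited.
- Classification: 10⁴ random pairs all receive exactly one class; boundary
  cases (r = 10 μm, ratio 0.90) are hand-checked.

## Known limitations

- Merged records: two islets overlapping in a slab's xy projection segment
  as one; no watershed splitting is attempted (out of scope).
- The per-section method double-counts boundary-spanning islets unless
  deduplication is enabled; the correction is heuristic (centroid distance
  within one mean radius).
- The adaptive-threshold parameters (block, offset) materially affect
  innervation scores; scores should be compared only across samples analyzed
  with the same parameter set.
- Thin virtual sections of *noisy* volumes can produce pure-noise sections
  where Otsu bisects the background; the stereology sweep therefore runs on
  noiseless synthetic volumes, relying on ROI masking and artifact exclusion
  for real data.
- Absorbance series are fit as measured; no transmittance transform is
  applied before fitting.
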