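# isletscope

Automated morphometry for cleared-pancreas fluorescence volumes, and the
simulation machinery to quantify what volumetric analysis buys over
slice-based histology.

Hydrogel-based tissue clearing makes whole organs optically transparent, so a
confocal stack of an intact pancreas can capture every islet of Langerhans —
thousands of structures — instead of the few dozen visible in a physical 2D
section. This package implements the full analysis chain for such data, for
researchers quantifying endocrine mass and peri-islet innervation across
development or disease models:

- **Preprocessing** — TIFF stack loading, in-plane bilinear downsampling,
  robust intensity normalization, manual-ROI masking, and partitioning of the
  volume into 150 μm maximum-intensity-projection (MIP) sections.
- **Islet detection** — per-section Otsu thresholding with erosion/dilation
  cleanup; connected regions ≥ 5 px become candidates; each candidate is
  re-thresholded at full local resolution in a 20 px-padded crop. The
  circle-equivalent radius is estimated from the convex hull:
  *r* = √(A_hull / π) · pixel size.
- **Innervation scoring** — each islet's neighborhood (convex hull dilated
  outward by 2 px ≈ 10 μm) is scored on the neural-crest/nerve channel with
  an adaptive local-mean threshold and a 1 px erosion; the interaction score
  is positive nerve pixels divided by islet area. Records whose
  positive-pixel fraction or histogram entropy deviates > 3 SD from a
  reference mean are flagged as artifacts.
- **Section-bias simulations** — resampling power experiments (draw N islets
  with replacement per group, unpaired two-tailed t-test, 100 repetitions)
  and virtual 2D-vs-3D comparisons: islets detected on optical sections of
  5–110 μm thickness are re-measured volumetrically, and each (r₂D, r₃D)
  pair is classified against a 10 μm inclusion threshold and 10% tolerance.
  The underestimation factor is (r₃D − r₂D)/r₃D; for infinitesimally thin
  sections its mean converges to 1 − π/4 ≈ 0.215, the classic stereological
  chord result E[√(1 − u²)] = π/4.
- **Assay kinetics** — clearing progress follows first-order kinetics
  *y* = Y_max(1 − e^(−kt)); the package fits (Y_max, k) by least squares,
  normalizes rates across conditions, computes staining signal-over-background
  on 2D sections, and normalizes protein-loss assays by tissue weight.
- **Synthetic data** — no imaging datasets were deposited for this kind of
  analysis, so a seeded generator draws two-channel volumes with known
  ground truth (spheroidal islets, partial nerve shells, background noise)
  against which every stage is validated.

## Worked example

```python
import numpy as np
from isletscope import (
    SynthConfig, generate_islet_volume, detect_islets, DetectionConfig,
    project_sections, score_population, exclude_artifacts,
    generate_clearing_series, fit_clearing_rate, normalize_rate,
)

# a 1×1×0.6 mm two-channel volume with 25 islets of known size
cfg = SynthConfig(volume_shape=(200, 200, 120), n_islets=25, seed=42)
islet_ch, nerve_ch, truth = generate_islet_volume(cfg)

pop = detect_islets(islet_ch, DetectionConfig(deduplicate_adjacent=True))
pop = score_population(pop, project_sections(nerve_ch, 150.0))
pop = exclude_artifacts(pop)

radii = pop.values("radius_um")
scores = pop.values("interaction_score")
print(f"true islets: {len(truth)}, detected: {len(pop.retained)}")
print(f"mean radius: {radii.mean():.1f} um (truth {np.mean(truth.islet_radii):.1f} um)")
print(f"mean innervation score: {scores.mean():.2f}")

series = generate_clearing_series(y_max=1.8, k=0.12,
                                  timepoints=list(np.linspace(0, 96, 49)),
                                  noise_sd=0.05, seed=0)
fit = fit_clearing_rate(series)
ref = fit_clearing_rate(generate_clearing_series(1.5, 0.04, list(np.linspace(0, 96, 49))))
fit = normalize_rate(fit, ref)
print(f"clearing rate k = {fit.k:.3f}/h, {fit.normalized_rate:.1f}x the reference condition")
```

Output:

```
true islets: 25, detected: 24
mean radius: 47.7 um (truth 42.5 um)
mean innervation score: 0.54
clearing rate k = 0.117/h, 2.9x the reference condition
```

24 of 25 islets are recovered at this noise level (two islets overlapping in
one MIP section merge into a single record); the detected mean radius sits a
few μm above the ground-truth mean because each record reports the convex
hull of the thresholded projection, which slightly favors the equatorial
cross-section. The fitted clearing rate recovers k = 0.12/h within noise, and
the normalized rate expresses it relative to the slower reference condition.

A command-line interface wraps the same library:

```
isletscope simulate-volume --config cfg.yaml --out sim/ --seed 1
isletscope detect --islet-ch sim/islet_channel.tif --dedup --out pop.csv
isletscope innervate --islet-ch sim/islet_channel.tif --nerve-ch sim/nerve_channel.tif --out scored.csv
isletscope sampling-sim --pop-a a.csv --pop-b b.csv --n 10,30,50,100,150 --out power.csv
isletscope compare-2d3d --islet-ch sim/islet_channel.tif --out summary.csv
isletscope clearing-fit --csv series.csv
```

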