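# nucleoafm

Quantitative analysis of high-speed AFM (HS-AFM) movies of single
nucleosomes and partially assembled nucleosomal structures (PANS)
disassembling on mica, plus a fully ground-truthed synthetic movie
generator that makes every pipeline stage testable without real data.

HS-AFM images a single nucleosome — a histone core wrapped by ~147 bp of a
Widom-601 positioning sequence, flanked by two DNA arms of unequal length —
at 1–2 frames per second while H2A·H2B heterodimers and then H3·H4 dimers
dissociate:

```
nucleosome → hexasome → tetrasome → disome → bare DNA
```

The package turns those height movies (nm-calibrated pixels) into the
quantities that characterize disassembly:

- **Pixel classification** — every pixel is labeled background / NCP / DNA
  by a small fully connected network (11×11 median-subtracted patch → 121
  ReLU units → 3 class logits); the largest connected NCP component is the
  particle, and DNA components smaller than half the largest are discarded.
- **Arm tracing** — the DNA∪NCP footprint is skeletonized, refined by an
  active-contour relaxation, split into the two arms by a seeded geodesic
  competition that meets at the core center, and measured from the core
  center of mass.  The arm ratio R_DNA = long/short (each length + core
  radius r ≈ 5 nm) distinguishes species: ~1.9:1 for an intact 200W100
  nucleosome, ~1.7:1 for a centered tetrasome after ~35 bp release per side.
- **Arm angles** — each arm's pixels in polar coordinates around the core
  give a smoothed θ(r) spline whose value at the NCP border is the entry
  (θ₂) or exit (θ₁) angle; Δθ(t) relative to time zero flags which side
  released DNA (the exit-side arm swings ~90° at the first ejection).
- **Volumetrics** — the background beneath the particle is refilled by
  smooth inpainting (or a harmonic/Laplacian fill for dried images), the
  NCP volume integrated, stepwise drops (~200 nm³ per dimer) detected by a
  penalized least-squares change-point fit, and segment levels mapped to
  species through measured volume bands (nucleosome 594.8 ± 116.3 nm³,
  hexasome 470.2 ± 113.6, tetrasome 351.7 ± 74.5, chromatosome
  673.7 ± 155.8).  First-ejection lifetimes, their empirical CDF, and
  AIC-based Gaussian-mixture model choice (unimodal vs trimodal) complete
  the statistics.
- **Dynamics** — time-averaged MSD of the histone centroid with its
  confinement plateau (≈ a² for a disc of radius a; ~80–90 nm² observed for
  tetramer diffusion), and k-means clustering of (short, long) arm-length
  pairs against the tetramer-offset geometry model to resolve the T / T_L /
  T_R positioning subpopulations.

The `synthetic` module renders all of this forward: spherical-cap cores
calibrated so the tip-convolved render integrates to the species volume,
worm-like-chain arms (0.33 nm/bp), grayscale tip dilation, scan-line
offsets, drift, noise, arm dropout, and stochastic stepwise schedules —
with exact per-pixel labels, per-frame volumes/angles and the event log as
ground truth.

## Worked example

```python
import numpy as np
from nucleoafm import synthetic, pipeline, volumetrics
from nucleoafm.preprocess import RasterStack

schedule = synthetic.planted_schedule([25.0, 52.0])   # N->H at 25 s, H->T at 52 s
movie = synthetic.simulate_movie(
    spec=synthetic.TET_100W50, schedule=schedule, fps=1.0, n_frames=80,
    seed=42, shape=(110, 110), noise=synthetic.NoiseModel(height_sigma=0.15))

stack = RasterStack(movie.frames, movie.pixel_size, movie.fps)
volumes = pipeline.measure_volumes(stack, movie.truth_masks)
events = volumetrics.detect_steps(volumes["V_nm3"].to_numpy(), fps=1.0, min_step=80.0)
states = volumetrics.state_sequence(volumes["V_nm3"].to_numpy(), events)
for e, s0, s1 in zip(events, states, states[1:]):
    print(f"t = {e.time_s:5.1f} s  dV = {e.dV:+7.1f} nm^3  {e.mode:7s}  {s0} -> {s1}")

arms = pipeline.track_arms(stack, movie.truth_masks)
pre = arms[arms.frame < 20]
print(f"pre-ejection arms: short = {pre.short_nm.median():.1f} nm, "
      f"long = {pre.long_nm.median():.1f} nm, R_DNA = {pre.R_DNA.median():.2f}")
```

prints

```
t =  25.0 s  dV =  -103.3 nm^3  sudden   nucleosome -> hexasome
t =  52.0 s  dV =  -137.3 nm^3  sudden   hexasome -> tetrasome
pre-ejection arms: short = 20.1 nm, long = 35.0 nm, R_DNA = 1.60
```

Both planted ejections are recovered at the right frames with the right
species calls; the measured 100W50 arm lengths (true 16.5 + 5 = 21.5 nm and
33 + 5 = 38 nm from the core center) come back within the tracer's ~1-pixel
truncation of each free DNA end.

The same stages are available from the shell:

```
nucleoafm simulate --config config.json --out run/
nucleoafm measure  --in run/movie.tif --masks run/movie_masks.tif --out run/m0
nucleoafm report   --in run/m0 --out run/report
```

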