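# Methods

This note documents the models, numerical choices and limitations behind
`nucleoafm`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic-data tests do and do not show
about real HS-AFM data.

## The forward model (`synthetic`)

**Histone core.** The core is rendered as a spherical-cap height profile.
A cap of sphere radius R and height h has volume V = πh²(3R − h)/3.  AFM
volumes of molecules imaged in liquid are *apparent* volumes — inflated by
hydration, tip convolution, and the background-under-the-particle
approximation — and the published species bands are on that apparent scale.
The generator therefore plants ground truth on the same scale: given a
nominal species volume, the cap's sphere radius is solved (Brent's method,
1e−3 nm tolerance) so that the **rendered, tip-dilated** profile integrates
to that volume on the pixel grid.  With no tip the closed form is used
directly.  Volumes too small to be reached at the nominal apparent height
(default 5 nm; observed cores are 4–6 nm) fall back to a hemisphere of
reduced height — this affects only the disome placeholder.

**DNA arms.** Arms are discretized 2D worm-like chains at 0.33 nm/bp, step
1 nm, with Gaussian heading increments of variance ds/ℓp (persistence
length default 50 nm — the standard null model; the source movies give no
arm-dynamics parameters).  Arms are resampled every frame (the arms of
adsorbed molecules rearrange between frames at 1–2 fps), start at the core
border along planted entry/exit headings with 5° per-frame jitter, and are
rendered as tubes of 2 nm apparent height and 2 nm half-width
(distance-transform profile).  Chains reflect at the field margins.

**Tip convolution** is grayscale dilation with a spherical apex of default
radius 2 nm: out(x) = max_u [surface(x−u) + tip(u)].  This reproduces the
quasi-spherical appearance and lateral broadening; contact mechanics is
out of scope.

**Artifacts.** Per-scanline offsets (N(0, σ_line)), additive height noise
(N(0, σ_h)), per-frame drift vectors, and arm dropout: with probability p
per arm per frame a contiguous ~30% of the arm path is deleted before
rendering, emulating transient desorption.  No published values exist for
these amplitudes; defaults (σ_h 0.15 nm, σ_line 0.05 nm, p 0) are tunable,
not fitted.

**Schedules.** Disassembly follows the species ladder with exponential
dwell times per transition; the first release is on the short-arm (rigid
601) side, the second on the long (flexible) side.  Sudden events complete
between frames; gradual events ramp linearly over 1.5 s (the observed 1–2 s
range).  Planted arm rotations at the first two ejections default to 90°
(short arm) and 55° (long arm), the observed magnitudes.  Default species
volumes are the measured band means; the disome mean was never published
and defaults to a flagged 200 nm³ placeholder.

**Truth masks** label every rendered pixel (>0.05 nm) with its class, NCP
winning where core and DNA overlap; classes are disjoint and exhaustive by
construction.

**Crowded fields.** `simulate_field` scatters ~20 molecules (min 50 nm
separation) on a 200×200 px field at 1.9 nm/px, which realizes class
proportions near the 89/3/7% background/NCP/DNA balance of manually
labeled training data.  A single molecule per frame cannot reach those
proportions (one core is ~0.2% of such a field); real training micrographs
are similarly crowded (~30 molecules per 500×500 nm²).

The default pixel size of 1.9 nm/px makes 2 px ≈ 3.8 nm, matching the
documented tracer end-truncation.

## Preprocessing

Gaussian smoothing (σ 1 px) precedes per-scanline flattening: a degree-1
polynomial is fit to each line's background pixels (below the global 70th
height percentile, so particles do not bias the fit) and subtracted.
Because the background set depends on the current estimate, the fit is
iterated to a fixed point (≤10 passes, 1e−10 nm tolerance), which makes
flattening idempotent to numerical precision.

Drift correction registers every frame to a reference (default: first) by
plain cross-correlation with upsampled subpixel refinement
(`phase_cross_correlation`, normalization off, upsample 20) and applies
the correction spectrally (Fourier shift) to avoid resampling blur.
Reported shifts are the frame's displacement from the reference; the
applied translation is its negation.  Featureless frames get zero shift
with a warning.

## Segmentation

The classifier is deliberately tiny: 121 inputs (11×11 patch, raw-patch
median subtracted; symmetric mirror padding at edges) → 121 ReLU units → 3
logits, trained by backpropagation (Adam, learning rate 1e−3, batch 256,
50 epochs, seeded — the source description fixes the architecture but not
the optimizer schedule).  Training patches are sampled class-balanced
(default 6000/class) to counter the ~89/3/7 prior.  Evaluation reports
class-conditional correct-labeling rates: joint fraction correct divided
by actual class fraction (e.g. 81.3%/89.2% = 91.1%).

Component rules: the main particle is the largest 8-connected NCP
component (ties break to the component whose lexicographically smallest
pixel sorts first); DNA components strictly smaller than half the largest
are discarded.  Connectivity and the "keep exactly half" boundary are
documented choices.  In the arm-tracking pipeline the filter runs at a
gentler quarter-of-largest threshold: with ~2:1 arm-length constructs the
genuine short arm sits exactly at the half boundary and pixel noise would
delete it; the strict rule remains the default of the standalone filter.
Manual mask correction used in the original workflow is replaced by
optional mask-file overrides; interactivity is out of scope.

## Arm tracing

The DNA∪NCP footprint is thinned (`skimage.skeletonize`), twigs shorter
than 4 px pruned, and chains relaxed by an active-contour style smoothing
(curvature term β = 0.4, attachment to the raw skeleton α = 0.3, 20
iterations, endpoints fixed).  The relaxation removes the staircase bias
of pixel chains: a raw 98 nm contour measures ~3% long through diagonal
steps, the refined polyline is within ~0.5%.

Arm tip 1 is the DNA skeleton pixel at maximal geodesic distance from the
NCP centroid; tip 2 maximizes the minimum of distances to the centroid and
to tip 1, restricted to skeleton chain ends (degree ≤ 1) — without that
restriction a mid-chain pixel of a long arm can out-score the genuine
short-arm tip whenever the long free arm exceeds twice the short one.  A
molecule with no second chain end is flagged degenerate.

DNA pixels are split between the tips by a deterministic two-seed geodesic
competition on the footprint graph with a metric that strongly favors the
skeleton (on-skeleton step cost 1, off-skeleton 10; the constant is
documented, not fitted).  Each seed's distances are offset by its distance
to the core center, so the fronts meet at the nucleosome center even for
unequal arms — the calibration the seeded-competition description demands.
Pixels reachable from neither seed fall back to Euclidean assignment and
are counted in a flag.

Arm length is the geodesic chain from the skeleton node nearest the core
center of mass to the tip, refined, summed, in nm.  Tracing misses ~2 px
(~3.8 nm) at each free DNA end; the +3.8 nm/end correction is applied only
in explicit full-length reporting, never silently.  R_DNA uses lengths
plus the core radius r ≈ 5 nm.  Arm identity (short/long) is assigned by
size on the first usable frame and held by nearest-angle continuity.

## Arm angles

Arm pixels outside the NCP border (radius of the circle with the NCP
component's area) are expressed in polar coordinates about the core
center; θ samples are centered on their circular mean, aggregated per
unique radius, and fit with a smoothing spline (s = m·(5°)², m samples;
SciPy's spline has no generalized cross-validation, so the smoothing scale
encodes the expected per-pixel angular scatter).  The angle is the spline
value at the border radius, clamped to the sampled radius range — cubic
extrapolation outside it is numerically explosive.  Fewer than 5 pixels
outside the border → undefined (NaN), carried as a gap.  Δθ series are
referenced to the first defined frame with steps wrapped to (−180°, 180°].
Absolute θ is arbitrary per movie (adsorption orientation); only Δ series
are compared across movies.  Event reporting restricts to ±8 frames around
detected ejections.

## Volumetrics

Backgrounds under non-empty (NCP∪DNA) pixels are refilled by biharmonic
inpainting (liquid imaging) or by solving the Laplace equation with
Dirichlet boundary data (the dried-image background basis); both reproduce
constant and linear backgrounds essentially exactly and agree within 10%
on synthetic inputs.  Volume is Σ max(height − background, 0)·px² over the
particle pixels.

Step detection is a penalized least-squares change-point fit (exact O(n²)
dynamic program; the original analysis identified steps by inspection, so
the detector is this package's choice).  The penalty defaults to
4σ̂²·ln n with σ̂ a robust difference-based noise estimate; adjacent
segments closer than `min_step` (default 120 nm³, aimed at ~200 nm³ dimer
drops) are merged weakest-first.  A drop is *sudden* if the trace crosses
between levels within 1 s of frames, else *gradual*.  Traces shorter than
10 frames yield no detection.

States are assigned to the nearest volume band in units of that band's SD,
ties toward the lower-volume species, >4 SD from every band →
"unassigned".  The chromatosome band is only enabled for declared
chromatosome runs.  Lifetimes to first ejection are right-censored at the
observation end; the CDF is the ECDF over uncensored times.  Mixture model
choice fits Gaussian mixtures for k ∈ {1, 3} (seeded, 5 restarts) and
keeps the smaller AIC = 2k_params − 2 ln L.

## Dynamics

MSD is time-averaged per track (lags to span/4; pairs spanning missing
frames excluded) and averaged across tracks weighted by pair counts.  The
confinement plateau is the mean over the last 25% of lags, flagged
unreliable if a linear fit still rises >20% of the plateau across the
tail.  For a particle uniformly exploring a disc of radius a the plateau
is E|r₁−r₂|² = a².

Tetrasome positioning clusters (short, long) arm-length pairs with k-means
(k = 3, k-means++ seeding, best of 20 restarts, seeded).  Clusters are
named T/T_L/T_R by nearest expected point of the geometry model
short = (bp_short − δ)·rise + r, long = (bp_long + δ)·rise + r, with δ the
tetramer offset (positive toward the short arm) and |δ| ≤ 45 bp (one dimer
footprint).  Pairs are treated as flank-identified coordinates; sorting by
length would collapse the left-shifted configuration onto the centered one.
Occupancy maps rigidly register each frame's DNA trace (Kabsch, both
polyline orientations tried) onto the first and bin the transformed
histone positions.

## Recovery suites and problem sizes

Because the raw AFM movies behind the published statistics are not
deposited, quantitative behaviour is verified against the generator at
fixed, documented sizes (all seeded):

- classifier: 50 crowded 200×200 px frames (40 train / 10 held out),
  σ_h 0.3 nm; held-out class-conditional rates.
- step recovery: 50 traces × 100 frames, one −200 nm³ drop, σ 30 nm³.
- state ladder: 50 planted schedules with uniform 8–30 s dwells at 1 fps
  (every state resolvable at the frame rate — exponential dwells would
  make a quarter of movies contain sub-frame states no detector could
  report), noise σ 30 nm³, min_step 80 nm³ because consecutive species
  bands sit ~120 nm³ apart.
- lifetimes: 100 molecules per regime, medians 25 vs 50 s, 300 s spans.
  The ratio-of-medians estimator has ~20% sampling SD at this size, so the
  check sits at ~1σ of its own tolerance by construction.
- clustering: n = 130, σ 2 nm, planted fractions 0.55/0.26/0.20.
- MSD: 8 reflected-disc walks (a = 9.5 nm) of 2000 frames at 2 fps.
- angle jumps: 20 rendered 17-frame movies around a single ejection.

Passing these suites shows the pipeline recovers planted truth under the
generator's statistical structure; it does not certify performance on real
mica data, whose tip asymmetries, long-range background bow, molecular
collisions and operator-level manual corrections the generator does not
emulate.

## Known limitations

- The generator's arms are equilibrium WLC resamples, not Langevin
  dynamics; frame-to-frame arm correlation is therefore absent.
- Volume calibration targets the apparent (hydrated, tip-convolved) scale;
  dried-image volume scales are not modeled.
- The tracer's end truncation in the generator (~1 px) is milder than the
  ~2 px observed on real images; the +3.8 nm/end correction is kept as the
  documented reporting convention rather than re-fit.
- H1 density within chromatosome cores is not separately segmented; the
  chromatosome state is a volume band only.
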