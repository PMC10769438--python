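# Methods

This note documents the models, estimators, and numerical choices behind
`bitescape`, and what the synthetic validation does and does not show.

## Kinematic variables and their estimators

Each strike is summarized inside a window from the first frame with an
observed pupil to the frame of maximum pupil displacement from its start
position (the moment of gel impact; earliest frame on ties). Within that
window:

- **peak gape (g, mm)** — maximum premaxilla-tip to dentary-tip
  distance;
- **peak jaw protrusion (jp, mm)** — maximum pupil-center to
  premaxilla-tip distance;
- **minimum lower-jaw angle (ja, degrees)** — smallest angle at the
  quadrate-articular joint between rays to the dentary tip and to the
  anteroventral preopercle point, over the onset-to-peak-gape window
  (arccos of the normalized dot product, argument clipped to [-1, 1];
  zero-length rays yield a missing frame);
- **time to peak gape (TTPG, ms)** — frames from the 20%-of-peak-gape
  onset to the peak-gape frame, times 1000/frame_rate (0.909 ms per
  frame at 1,100 fps); frame-resolution counting, no sub-frame
  interpolation, inclusive indices, earliest frame on ties;
- **ram speed (rs, m/s)** — straight-line pupil displacement between
  the onset and peak frames (mm) divided by TTPG (ms); mm/ms is
  numerically m/s. TTPG = 0 leaves rs missing with a warning.

The ram-distance landmark is the pupil center (the same rigid-head proxy
used for window detection); it is the package's choice where several
head points would serve.

All five variables are invariant to rigid rotation and translation of
the image and to the y-axis pointing downward, and g, jp, ja are
invariant to the frame rate; halving the frame rate with identical
geometry exactly doubles TTPG and halves rs.

### Noisy-landmark mode

Pose estimators leave roughly isotropic per-frame jitter on each
landmark (about 5 px for a well-trained model). With
`smooth_window` set (pipeline default 21 frames, about 19 ms at
1,100 fps, pass band to roughly 50 Hz), extraction uses two filters with
different jobs:

- **Amplitudes** (g, jp) are maxima of the 21-frame moving-average
  series. A moving average cannot overshoot, so the held peak — fish
  reach peak gape well before impact and hold it — is preserved rather
  than inflated; polynomial (Savitzky–Golay) filters were rejected
  because their local quadratic fit overshoots at the rise-to-plateau
  corner and biased peak gape by about +0.3 mm.
- **Timing** (onset and peak frames) is read from a light 5-frame
  moving average, where threshold crossings on the steep gape rise stay
  frame-accurate. Because the literal argmax wanders across the held
  plateau under noise, the peak-gape frame is the first frame entering
  a noise band below the maximum (3 sigma of the timing series,
  sigma estimated from the raw-minus-smoothed residual by MAD), and the
  onset is located by searching backward from the peak for the last
  frame below 20% of peak (the forward first crossing triggers on
  baseline noise). Ram displacement and the jaw-angle series also use
  the light filter; the wide filter rounds the fast approach segment
  and the sharp angle minimum.

On noise-free input the band is zero and every definition reduces to
exact frame counting; noiseless simulated strikes are recovered to
machine precision (timing to the frame). Under the default 5 px jitter
at 10 px/mm, measured recovery over 224 strikes is: g bias +0.08 mm,
jp +0.04 mm, TTPG -1.5 ms, rs -0.05 m/s, ja +4 degrees. The residual
ja bias comes from window truncation (the estimated peak frame sits a
frame or two early, before the angle reaches its true minimum) and is a
known limitation of frame-windowed angle minima at this noise level.

## Landmark I/O

Track files are HDF5 with datasets `tracks` (frames x 5 x 2, image
coordinates, origin top-left), `point_scores` (frames x 5, confidence
in [0, 1]; 0 or NaN marks a missing point), and `node_names` (the fixed
landmark order: premaxilla tip, dentary tip, pupil center,
quadrate-articular joint, anteroventral preopercle point). A 4-D
`tracks` dataset (frames x instances x nodes x 2) is reduced to one
instance per frame by highest mean confidence, since fish are filmed
individually. Calibration divides coordinates by the session's px/mm
ruler scale; calibrating an already-calibrated track is an error. Gap
repair linearly interpolates missing runs of at most `max_gap` frames
(default 5, about 4.5 ms) flanked by observations, flags filled frames
as imputed, and never alters observed frames.

## Multivariate statistics

PCA eigen-decomposes the correlation matrix of the five kinematic
variables (components ordered by decreasing eigenvalue; the
largest-magnitude loading of each component is made positive), making
it invariant to affine rescaling of any variable. LDA forms Fisher
discriminants from the pooled within-class and between-class scatter
and classifies by nearest class mean in discriminant space; accuracy is
resubstitution by default (leave-one-out optional), and a ridge on the
within-class scatter is available for singular cases. Rows with any
missing variable are dropped listwise with a logged count.

## Mixed-effects models

The default structure is `response ~ species + strike_type +
(1 | individual)`, REML-fit with statsmodels MixedLM; reference levels
are generalist (species) and edge (strike type). Candidate structures
(fixed-effect interactions, random slopes) are compared by AIC after
refitting with full ML, because REML likelihoods are not comparable
across fixed-effect sets. Per-coefficient tests are large-sample Wald z;
small-sample denominator-degree-of-freedom corrections (Satterthwaite
style) are deliberately out of scope, so p-values in small samples are
mildly anti-conservative and should be read directionally. A
fixed-variance path (`re_variance_ratio`) computes the closed-form GLS
solution with the intercept-to-residual variance ratio held fixed;
ratio 0 is exactly OLS, which the tests verify against an independent
OLS implementation.

## Penalized spline GAMs

The Gaussian model is penalized least squares: minimize
`||y - X b||^2 + sum_j lambda_j b' S_j b`, where X contains an
intercept, treatment-coded factors, linear covariates, and low-rank
thin-plate regression spline bases. The spline construction follows the
standard truncated-eigenbasis approach: the full radial-kernel matrix
(`r^2 log r / 8 pi` in 2-D, `r^3 / 12` in 1-D, knots at the data) is
truncated to its k largest-magnitude eigenpairs, the polynomial null
space is separated by the usual orthogonality constraint, wiggly
columns are rescaled to unit RMS for conditioning and centered over the
training data, and the smooth's linear columns enter unpenalized (the
constant is absorbed by the intercept). Defaults: k = 30 for the
bivariate `s(g, jp)` surface, k = 10 for univariate smooths.

Smoothing parameters minimize the exact Gaussian REML criterion
(profiled scale) over log-lambda by Nelder–Mead from a lambda = 1
start (xatol 1e-6, log-lambda clipped to ±18). Effective degrees of
freedom are the diagonal of `(X'X + S)^{-1} X'X` summed per term;
deviance explained is 1 - RSS/TSS against the intercept-only model;
AIC uses the conditional convention `-2 logLik + 2 (edf_total + 1)`
with the ML variance RSS/n — comparisons between models depend on this
convention and should use it consistently. Shrinkage (per-smooth flag)
adds a second REML-weighted identity penalty on the smooth's null-space
columns, so a term can be shrunk entirely out of the model
(double-penalty selection). Setting a smooth's lambda override to
infinity removes its penalized columns exactly, which reproduces the
parametric OLS fit to machine precision — the oracle check used in the
tests. The packaged candidate set for model selection covers seven
shapes per response: the full surface model, the surface model without
TTPG, additive univariate smooths for g and jp, all-smooth, all-linear,
and the surface model dropping species or strike type.

## Performance surface and peaks

The fitted surface is evaluated on a 50 x 50 grid spanning the observed
(g, jp) range, with factors at reference levels (generalist, edge) and
other linear covariates at their training means; one surface is drawn
for all strikes. Cells outside the convex hull (Delaunay test) of the
observed points are masked. Peaks are counted by topographic
prominence: cells are activated in decreasing value order with
union-find, each local-maximum component's prominence is its birth
height minus the level at which it merges into higher ground (the
global maximum's prominence is its height above the unmasked minimum),
and one representative cell per plateau avoids double-counting grid
ties. A peak must additionally have all eight neighbors unmasked (hull
interior) and be >= each of them, and its prominence must reach 5% of
the unmasked surface range (default), which suppresses noise ripples.
The count is invariant to monotone affine transforms of the response;
an affine surface has zero interior peaks by construction.

## Synthetic strike generator

The generator emulates the study design: 4 species groups
(generalist, molluscivore, scale-eater, hybrid) x 5 individuals x 8
strikes by default (individual filming capped at 16 strikes), strike
types drawn with probabilities edge 0.55 / corner 0.15 / scrape 0.15 /
miss 0.15. Strike-level kinematic targets are multivariate normal per
species with a 0.4 g–jp correlation and a per-individual offset
(SD 0.3 mm) on g and jp; TTPG is snapped to whole frames. The species
means are synthetic values chosen to reproduce the qualitative ordering
in this system — scale-eaters largest in gape and protrusion (jp mean
7.5 mm, above the 6.5 mm protrusion threshold only scale-eater ancestry
reaches), generalists and molluscivores small, hybrids intermediate
with the largest variance so their strikes span the region between the
optima — without asserting any measured values.

Each strike is rendered geometrically: the head (pupil, quadrate,
preopercle) translates as a rigid triad along a normalized logistic
approach whose total travel is solved so pupil displacement between
gape onset and peak equals rs x TTPG exactly; gape and protrusion rise
along a smoothstep from onset (constructed to sit strictly above the
20% threshold at the onset frame) to their peaks, hold until impact
with a strict 1e-5 per-frame decay (so argmax and threshold crossings
are unambiguous after the pixel round trip), and relax during a
post-impact retreat; the dentary opens ventrally from the premaxilla
tip so gape is realized exactly; and the preopercle is placed so the
jaw angle at the peak-gape frame equals the injected minimum. Ground
truth records the realized noiseless kinematics. Landmarks are emitted
in pixels (default 10 px/mm) with isotropic Gaussian jitter (default
5 px, matching a well-trained detector's mean error) and optional
confidence dropout (default 1%).

Bite dimensions: expected length is a deterministic two-bump surface
over (g, jp) — anisotropic Gaussians at (3.0, 2.8) and (5.5, 7.5) mm
with amplitudes 3.0 and 2.5 mm, widths about 1 mm, baseline 0.8 mm —
plus species and strike-type offsets and a per-individual intercept
(SD 0.3 mm); width tracks jaw size (1.8 + 0.25 g); depth is
near-constant with a 0.4 scrape reduction; misses have all dimensions
zero; each dimension gets independent Gaussian measurement noise
(length SD 0.5 mm, others 0.15 mm) truncated at zero before the volume
product. All randomness flows from `numpy.random.default_rng(seed)`
(PCG64), so fixed seeds reproduce datasets bit for bit.

**What passing the synthetic closure shows — and does not.** Recovering
the two-peak surface from rendered tracks validates the estimator
chain: calibration, smoothing, window detection, variable extraction,
spline fitting, REML, and peak counting, under realistic landmark noise
and a performance signal of realistic magnitude. It does not validate
the trajectory model against real fish (real gape profiles are not
smoothsteps, real noise is not isotropic white jitter, occlusions and
tracking identity errors are absent), and species means are synthetic,
so species-level effect sizes in the demo outputs are illustrative
only.

## Problem sizes

Default validation runs use the 160-strike study (about 70-100 frames
per track). The repeated-seed checks use 20 independent studies for
peak recovery and 20 replicates for model selection — together about
15 seconds on one CPU — which gives a binomial standard error of about
7 percentage points on the reported rates.

## Known limitations

- Timing variables under heavy landmark noise retain a small negative
  TTPG bias (about -1.5 ms at the default noise) and ja a positive bias
  of a few degrees (window truncation at the estimated peak frame).
- REML optimization is derivative-free; with five simultaneous smooths
  it typically needs a few hundred criterion evaluations and can in
  principle stop at a local optimum.
- Mixed-model p-values are Wald z (see above); no Kenward–Roger or
  Satterthwaite correction.
- The GAM family is Gaussian identity-link only; anisotropic
  tensor-product smooths are not implemented (the bivariate thin-plate
  surface treats g and jp isotropically after their natural mm scale).
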