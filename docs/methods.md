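# Methods

`gradconn` implements, and verifies by parameter recovery, the analysis
chain of a controlled-semantic-cognition fMRI experiment: a block-design
first-level GLM, gradient mapping with vectors of ROI, spatial ROC
statistics over functional zones, psychophysiological interaction (PPI)
mapping, and comparison of bilinear effective-connectivity models.  Because
no raw data are distributed, every analysis is driven by a synthetic
generator whose ground truth is known exactly; a test passes when the
analysis recovers what the generator injected.

## Task designs

The main task presents three conditions — *colour* (pairing semantically
unrelated objects by canonical colour), *semantic* (pairing by meaning) and
*control* (visual pattern matching) — in 19-s blocks of five trials (0.8-s
cue + 3-s stimulus).  Six blocks per condition plus six 19-s rests tile a
456-s run, sampled by 163 volumes at TR = 2.8 s.  Orders are seeded,
Latin-square-style: the six permutations of the three conditions are used
equally often across block triples, with a rest after every triple (the
triple-wise rest placement is a package convention exposed as `rest_every`).
The hue localiser alternates *coloured* and *greyscale* 15-s blocks (five
0.5 + 2.5-s trials) with a 10-s rest after every block: 20 blocks give
500 s and 179 volumes.  A per-trial reaction-time covariate is generated
with condition means of 1.569/1.387/1.354 s (colour slowest) and 0.15-s
jitter.

## Ground-truth network and BOLD generator

Neural dynamics follow the bilinear state equation
`dz/dt = (A + Σ_j u_j B_j) z + C u` over five nodes (IFG, ventral ATL,
lateral ATL, occipital-concept, occipital-percept).  The diagonal of A is a
fixed −1 Hz self-decay (not fitted); the 20 off-diagonal couplings are
fixed, mildly heterogeneous positive values (0.05–0.3 Hz) chosen
Gershgorin-stable.  Two candidate architectures differ in input routing and
in one modulated connection:

* **top-down** — the task input (all-condition boxcar, 0.8 Hz) drives IFG
  and ventral ATL; the colour boxcar adds 0.2 Hz to the four hub
  connections (vATL↔IFG, vATL↔lATL) and 0.8 Hz to IFG → occipital-concept;
* **bottom-up** — identical except the input (1.0 Hz) enters via
  occipital-percept and colour modulates occipital-concept → IFG instead.

Integration is forward Euler at dt = 0.1 s, validated against a 1-ms
oracle on two-node systems (< 1 % RMS).  Stochastic "ongoing activity" is
added as Euler–Maruyama innovations with `state_noise_sd = 0.8` Hz·s^-1/2;
this level makes neural fluctuations comparable to task-evoked responses,
which is what PPI detection physically relies on, and was fixed once
together with the modulation strengths so that single-subject PPI detection
is robust — the regime in which block-design PPI analyses are run at all.
The modulated matrices A + B remain stable (max Re eigenvalue ≈ −0.12 Hz).

Spatialisation writes each node's HRF-convolved activity into a Gaussian
blob (σ = 4 mm, 3σ support) on a 40 × 48 × 36 grid of 3-mm voxels with an
MNI-like affine (y negative = posterior).  Two strip masks emulating the
fusiform (FG) and inferior-temporal (ITG) gyri run from y = −78 to +3 mm;
both sway ±10 mm in x and z along their course, like a real gyrus — and,
operationally, so that the five anchor points are far enough apart along
the path for thirteen non-overlapping 3-mm spheres.  Within each strip the
per-condition response weight is linear in y: control falls 1 → 0
caudal→rostral in both strips, while the conceptual conditions rise
(FG: colour and semantic 0.1 → 1.0; ITG: colour 0.45 → 1.0, semantic
0.2 → 1.3).  This builds in the injected facts the analyses must recover:
a perceptual-to-conceptual transition in both strips, an earlier (more
caudal) tipping point in the ITG, and a rostral ITG preference for the
semantic task.  Three disjoint occipital zones (caudal *percept*,
intermediate *concept*, rostral *ppi*) receive fixed condition mixtures
with colour-minus-semantic effects of 0.15 / 0.75 / 0.20 signal units, and
the modulated occipital-concept node sits inside the *ppi* zone; this
yields the qualitative AUC ordering concept > chance > percept for
concept-ranked voxels.  Low-frequency drift (up to three cosines, all
slower than 128 s so the GLM high-pass spans them exactly) and white
measurement noise (sd 1.0 signal units against strip/zone amplitudes of
order 1) complete the run.  One integer seed drives design order, state
noise, embedding noise and RT; regeneration is bit-identical.

What the generator does *not* emulate: autocorrelated scanner noise,
motion, distortion or any acquisition physics, hemodynamic variability
across regions (one canonical HRF everywhere), and spatial noise
correlations.  Passing tests therefore demonstrate the correctness of the
estimators under their own assumptions, not robustness to real-data
violations of them.

## GLM

Condition regressors are boxcars convolved with a canonical double-gamma
HRF — response peak at 6 s, undershoot at 16 s, 6:1 peak ratio, 32-s
support, peak-normalised — on a 0.1-s microtime grid and sampled at
mid-volume times (TR/2 offset; slice timing is out of scope).  Nuisance
terms: a pooled mean-centred RT modulator (per-condition coding available),
optional motion series, a discrete-cosine high-pass basis to 128 s, and a
constant; rest is implicit.  Estimation is voxel-wise OLS without
prewhitening (generator noise is white; this is a documented divergence
from SPM-style AR(1) modelling).  Contrast t maps use pooled residual
variance per voxel; non-estimable contrasts (e.g. a regressor duplicated
into the confounds) report t = 0.  Significance maps use the operational
rule voxel-p threshold plus ≥ 270 mm³ cluster extent (10 voxels here),
18-connectivity, with no random-field correction.  Group maps are
one-sample t over per-subject contrast values — deliberately the simplest
second level.

## Vectors of ROI

A strip mask is cut into segments of equal y extent (remainder voxels to
the last bin); segment centroids are the anchors; the spline through them is
piecewise linear, so arc length is exact.  Each inter-anchor gap is divided
into three equal path distances, giving two intermediates; five anchors
yield 13 spheres (radius 3 mm), asserted pairwise non-overlapping.  The two
vectors are matched so paired ROIs share y and z, differing only in x.
Profiles average voxels whose centre lies in the sphere (centre inclusion,
no partial-volume weighting).  Profile evolution is tested with
within-subject factorial ANOVAs (statsmodels `AnovaRM`; uncorrected F —
no sphericity correction is applied by default) — vector × position per
contrast and contrast × vector × position overall — with partial η²
derived from F and its degrees of freedom.  Position-wise paired t tests
are emitted only under a significant governing interaction (family-wise
gating); degenerate 0/0 sums of squares are reported as F = 0, p = 1.

## Spatial ROC

Voxels above a liberal one-sided threshold (p < .01 at the map's df) inside
a search mask are ranked by statistic, ties broken by voxel index.  Walking
ranks from strongest to weakest, the curve accumulates the proportion of
the target zone filled against the proportion of non-target zones filled;
voxels outside every zone are skipped.  The trapezoidal AUC equals the
pairwise concordance probability (verified exactly against a brute-force
oracle).  AUC uncertainty uses voxel bootstrap (≥ 1000 resamples; the SE
is cross-checked against an exhaustive jackknife); curve comparisons use a
paired bootstrap on the same resamples.  Curves are walked per voxel —
percentile labels are attached for reporting only.  Polynomial trends of
mean-corrected statistic against a world axis summarise spatial shifts
between contrasts.

## PPI

Seed BOLD is the mean over a 6-mm sphere (centre inclusion).  Deconvolution
to neural space inverts the HRF convolution operator on a TR/16 microtime
grid in a discrete-cosine basis of dimension n_volumes, with a ridge
penalty of 10⁻² times the leading eigenvalue of the normal matrix (an
explicit, simple stand-in for SPM's empirical-Bayes deconvolution).  The
final HRF-length of the run is unobservable in principle; round-trip
recovery is < 1 % RMS on the interior for smooth inputs.  The
psychological regressor is the contrast-coded boxcar, mean-centred over
in-task microtime; the interaction is neural × psychological, re-convolved
and sampled at volume times.  The per-condition main-effect regressors are
attached as confounds so purely task-evoked responses cannot masquerade as
coupling changes — with them, the voxel-level interaction false-positive
rate under B = 0 is nominal.  The interaction map is a GLM t map
thresholded at p < .005 with the 270-mm³ extent rule.  The test is
invariant to seed rescaling.  (A multi-run combination rule is not needed
here: each synthetic subject has one run.)

## Network fitting and model selection

Candidate architectures are fitted to per-node BOLD observations by
bounded nonlinear least squares over the free A/B/C entries (27 for these
models): candidate parameters are integrated, convolved with the canonical
HRF, sampled at volume times, and compared to the observations.  The
optimiser is scipy's trust-region-reflective least squares with bounds
±3 Hz and tolerances 10⁻⁶, warm-started by a two-stage linear estimate
(node-wise deconvolution followed by a regression of the Euler increments,
in which all free parameters enter linearly), followed by seeded extra
starts with early termination once starts stop improving.  Unstable
candidate matrices receive a smooth residual penalty instead of an error so
the optimiser can retreat.  Evidence is approximated by −BIC/2 — a
deliberate simplification that preserves the selection logic without a
variational hemodynamic inversion.  FFX selection sums log evidences and
softmaxes; RFX runs the standard variational Dirichlet update over model
frequencies (uniform prior α₀ = 1, convergence 10⁻⁶, cap 64 iterations)
and estimates exceedance probabilities by Monte-Carlo sampling (≥ 10⁴
draws; the two-model case is cross-checked against the exact Beta
integral).

Model-recovery experiments run in the regime the observation model assumes:
deterministic dynamics plus white observation noise (sd 0.1 against node
BOLD amplitudes of order 1–5), the *same-model* test regime; the fitting
HRF is shared with the generator by design.  The recovery experiments use
runs of two blocks per condition (152 s, 55 volumes), a 0.2-s fitting
integration step and a single warm start per fit — problem sizes chosen so
a full recovery matrix (both generating architectures × 20-subject cohorts
× both fitted models, several replicates) completes in minutes while
leaving per-subject evidence differences of order 100 log units, far from
the decision boundary.  Zero-noise self-recovery at matched integration
step is exact to machine precision (well within the 5 % recovery
tolerance asserted).

## Numerical choices and degenerate inputs

Volume counts are the smallest n with n·TR ≥ run duration.  Empty designs
produce confound-only design matrices.  Rank-deficient design matrices
raise an error naming the dependent columns.  Sphere membership everywhere
is by voxel-centre inclusion.  Thresholding with zero survivors raises an
explicit empty-selection error rather than returning an empty curve.  All
stochastic routines take explicit integer seeds; cohort seeds are derived
with `numpy.random.SeedSequence`.

## Known limitations

BIC evidences are not comparable to variational free energies; only the
*selection behaviour*, not evidence magnitudes, is meaningful.  OLS without
prewhitening would be anticonservative on autocorrelated real data.  The
piecewise-linear spline has no curved option, and anchor computation
assumes the strip is monotone in y.  The ROC walker excludes voxels outside
all zones, so its AUC concerns the zone-restricted competition only.
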