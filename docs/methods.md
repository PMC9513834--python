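# Methods

## Optics model

The interferometer is modelled in the 2D incidence plane. The substrate
lies along z = 0; a circular-arc mirror of radius R = 2f stands at the
substrate edge with a vertical tangent at its foot; the collimated beam
arrives at β above the substrate plane (direction (−cos β, −sin β)). Each
mirror point reflects the beam specularly off the local arc normal; the
reflected ray is propagated to the substrate and its in-plane wavevector
component compared with the direct beam's:

Λ(x) = λ / |k_x,reflected(x) − k_x,direct| ,

which reduces to the grating equation λ/(sin θ₁ + sin θ₂) when the beams
arrive from opposite azimuths and to λ/|sin θ₁ − sin θ₂| when they share
one. The λ/2 two-beam limit holds automatically (|Δk_x| ≤ 2).

For a concave arc the reflected rays form a single-valued landing map on
the strip *behind* the mirror foot (the side away from the incoming
beam); near the foot on the other side, rays from different arc heights
fold onto the same positions (a caustic), so `build_topography_profile`
samples only the single-branch strip and trims a 1% margin at both
singular ends (the foot, where the mapping folds, and the far edge, where
the reflected ray becomes parallel to the direct one and Λ diverges).
With β = 67°, f = 10 mm the usable strip is ≈1.7 mm long with periods
from ≈1.3 µm to ≈190 µm (span ×146), and log Λ is nearly linear in
position (R² = 0.956 over the central 80%). Raising β to 72° narrows the
span, lowering it to 62° widens it — the instrument's tuning behavior.
A very long focal length recovers the flat-mirror (Lloyd's) limit:
specular reflection everywhere and a uniform period λ/(2 cos β). This
ray-tracing construction is the package's own surrogate for the
instrument's optical transfer; its constants (strip length, absolute
span) should be read as qualitative.

The mirror can also be set convex (single-branch on the front side, much
narrower gradient). Exposure is modelled as a sinusoidal dose
D(u) = m + v·cos 2πu; the developed duty cycle is
arccos((t − m)/v)/π for negative resist (complement for positive), with
equal-amplitude beams (v = m) and the threshold at the mean (duty 0.5)
by default, since no dose values are specified for the process. Pattern
height is a constant resist thickness, default 0.3 µm; height effects are
not modelled.

The **calibration** is an ordinary least-squares fit of log(period)
against position. `central_fraction = 0.8` restricts the fit to the
central 80% of the sampled strip, away from the near-singular ends. A
zero-variance profile returns slope 0 with R² defined as 0.

## Synthetic data

The generator emulates the screening conditions of a 1 cm² gradient
array: homogeneous Poisson cell positions at 10,000 cells/cm² (the
density used for adhesion/growth-type screens; differentiation screens
use 40,000), 30% cell-free area as randomly chosen rectangular grid cells
(the false-null failure mode the GPR stage corrects), and a log-Gaussian
size response per behavior. Default peaks: adhesion 20 µm (the largest
pattern, i.e. effectively monotone), axonal growth 5 µm, axonal alignment
0.2 µm; proliferation (1 µm) and differentiation (2 µm) are nominal
mid-range choices because no quantitative optimum is available for them.
Amplitude 1.0, baseline 0.2, noise sd 0.1 (10% of amplitude) — a nominal
signal-to-noise of 10 typical of intensity readouts after background
correction. A mechano-insensitive ("patient-like") type is emulated by
scaling all amplitudes, default 0.5, with noise unchanged.

Rendering draws each cell as a soft-edged ellipse (pixel area sampled in
15–60 px to sit inside the 8–80 px screen window, aspect up to 3,
Gaussian edge blur 0.7 px) at 0.65 µm/px into a 16-bit frame with 5%
background and square-root ("shot-like") noise. Intensity channels
(TuJ1/MAP2, CFSE) scale blob amplitude with the behavior value; actin and
DAPI are constant-amplitude. Fiber textures are Gaussian-profile stripes
with Poisson-jittered spacing; a non-positive diameter degenerates to an
isotropic noise control.

What the generator does **not** emulate: cell migration or cell–cell
contact, spatially varying densities, optical aberrations and stitching
seams, realistic neurite arbors, or heterogeneous per-cell response
variance. Passing tests therefore demonstrate that the analysis chain
recovers known structure under idealized imaging, not that it would
survive every artifact of real micrographs.

## Image quantification

Background is estimated by grayscale opening with a disk (rolling-ball
equivalent) on an odd-reflection-padded frame, so linear illumination
gradients are tracked up to the border. Segmentation is global Otsu +
8-connected components + inclusive [8, 80] px area filter; note that a
global Otsu *forces* a split, so a field containing no cells yields
spurious noise detections — callers screening sparse fields should pass
an explicit threshold. Circularity is 4πA/P² from the scikit-image
perimeter convention, clipped into (0, 1]; polarization is defined as
1 − circularity (a bounded "reverse" of circularity). Orientation
analysis uses a structure tensor built from Gaussian-derivative filters
(σ = 1 px derivative, 2 px tensor smoothing) — finite-difference
gradients were rejected because their anisotropy biases recovered angles
by up to ~2.5° at 15–30°; with Gaussian derivatives the worst-case error
over all orientations is below 0.1°. Weights are gradient energy ×
coherence; the alignment score is the resultant length of doubled angles
(1 − circular variance, axial statistics); the dominant angle is the
axial circular mean over ±2 bins around the modal 2° bin. Neurite length
sums orthogonal (1 px) and diagonal (√2 px) links of the skeletonized
component; components with skeleton branch points are excluded as
entangled bundles, and components spanning more than one feature-size
regime are excluded when a regime map is supplied — an automated
surrogate for manual tracing, not a reproduction of it.

## Behavior mapping

The GP uses an anisotropic squared-exponential kernel plus white noise
(Matérn 5/2 available), prior mean equal to the training label mean.
Hyperparameters (two length scales, signal and noise variance) are tuned
on the negative log marginal likelihood over log-uniform bounds — length
scales within [domain/√n, domain], variances within [10⁻⁶, 10] × label
variance — by expected-improvement Bayesian optimization: 8 random
initial evaluations, then EI-maximizing candidates from a 1024-point
random pool under a Matérn-5/2 surrogate, 30 evaluations total by
default, followed by a deterministic L-BFGS polish started at the EI
incumbent (EI explores globally; the gradient step sharpens the final
estimate — on data drawn from a known GP prior the polished length
scales land within a factor of 2 of truth at n = 500). Ill-conditioned
kernel matrices get jitter escalated ×100 from 10⁻¹⁰, logged.

Hold-out validation splits 90/10 (test count = round(0.1 n), at least 1).
Prediction uses a grid of exactly 250,000 points spanning the
observation bounding box, factorized to preserve the box aspect
(500 × 500 for a square box) and evaluated in 20,000-point chunks to
bound memory. Marginalization maps grid columns through the calibration
and averages column means within 8 log-spaced size bins fixed by the
calibration's valid range, so curves from different scenes on the same
array share identical bins; a bin not covered by a particular grid is
filled by log-size interpolation of the column-mean profile.

## Scoring

Levels are equal-width (not quantile) over the value range, 5 by default:
quantiles would rescale every cell type to span all levels and erase
exactly the amplitude differences a mechanosensitivity comparison needs.
For the same reason, tables meant to be compared are built under one
shared per-behavior range pooled across cell types
(`build_radar_tables`); a standalone table may use its own range. A
zero-range curve maps to all level 1 with a warning. The optimal feature
size is the argmax bin center, ties toward the smallest size; it is
invariant under strictly monotone transforms of the values. The
sensitivity index is the per-behavior level range (max − min, 0–4) with
the overall index the mean across behaviors — the simplest statistic that
orders a flat responder below a full-range responder; a variance-based
index would weight intermediate bins but adds a tuning choice.

## Problem sizes and determinism

The end-to-end statistical checks run at reduced problem sizes chosen as
a deliberate accuracy/turnaround trade-off: per scene, 250 observations
are subsampled from the ~7,000 generated cells, the EI search uses 12
evaluations, and ground-truth comparison grids use 2,500 points (the
250,000-point default is exercised where the grid itself is the
quantity). At these sizes the 20-scene peak-recovery and 20-replicate
sensitivity-contrast suites complete in well under a minute while leaving
wide margins (typically 19–20/20 successes, mean hold-out R² ≈ 0.9).

Every stochastic step takes an explicit seed; pipelines fan one master
seed out through `numpy.random.SeedSequence` spawn keys per stage, cell
type and behavior, so a config + seed pair reproduces byte-identical
observation tables and manifest checksums.

## Known limitations

- The arc-mirror ray trace is a geometric surrogate; no vector
  electromagnetic effects, resist kinetics, or 2D dot/pillar patterns.
- Segmentation is a functional stand-in with a global threshold; it has
  no nucleus/cytoplasm model and misbehaves on cell-free fields (above).
- Behaviors are mapped independently; no multi-output GP, no
  spatio-temporal modelling.
- Dead/round cell bodies inflate alignment readouts in real screens; the
  package logs no correction for this — curves for alignment should be
  read with that caveat.
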