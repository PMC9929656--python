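# Methods

This note documents the models, numerical choices and known
limitations of `coatfit`.

## Geometry

A coat is a spherical cap: sphere radius `r` (nm), closing angle
`theta` (radians internally; degrees only at I/O boundaries), pole
toward +z in the model frame.  All derived quantities are closed
forms; the dimensionally complete definitions are used throughout:
projected area `A_p = pi r^2 sin^2(theta)` (the rim-disc/aperture
area, which decreases again past the hemisphere) and rim length
`epsilon = 2 pi r sin(theta)`.  The cap surface centroid sits at
`r (1 + cos theta)/2` from the sphere center; fitted positions are
reported at the centroid while the internal parametrization uses the
sphere center.  Quasi-uniform surface lattices use golden-angle
spirals with equal-area stratification of `cos(polar)`.

## Growth models

Four curvature laws `H(theta)` are fitted to per-site populations of
(θ, observable) with unweighted nonlinear least squares
(`scipy.optimize.curve_fit`, positivity bounds), where the observable
is curvature `H`, area `A`, rim length `epsilon` or projected area
`A_p`, all derived from `H(theta)` through the cap geometry:

- CAM: `H = sqrt(2 pi (1 - cos theta) / A)`, one parameter `A`;
- CCM: `H = 1/R`, one parameter `R`;
- CoopCM: `H = H0 tanh(gamma theta / H0)` (solution of
  `dH/dtheta = gamma (1 - H^2/H0^2)`), parameters `(gamma, H0)`;
- LinearCM: `H = H0 (1 - exp(-gamma theta / H0))` (solution of the
  non-cooperative `dH/dtheta = gamma (1 - H/H0)`).

Sites with `theta = 0` are substituted by 0.0001° before evaluation.
BIC uses the Gaussian-residual convention with the variance profiled
out, `BIC = n ln(RSS/n) + k ln n`, identically for every model, so
ranks are comparable; a zero-RSS (noiseless) fit is floored at the
smallest positive double.

Derived parameters: `R0 = 1/H0` and the flat-preassembly fraction
`A0 = A(0.01 rad)/A(pi)`.

### Coat dynamics and pseudotime

Area grows at the rim with a single rate constant: `dA/dt = k_on
epsilon` (`k_on` in nm per pseudotime unit).  Combining with the
CoopCM curvature law and expanding at small θ gives the square-root
law

    theta(t) = sqrt( 24 gamma k_on t / (8 gamma^2 H0^-2 - 1) ),

which is the `closed_form` method of `theta_of_time` and the default
model for fitting `k_on` to pseudotime-sorted closing angles (a
one-parameter least squares with `(gamma, H0)` held fixed from the
corresponding observable's CoopCM fit; joint fitting is available but
not default).

The `ode` method integrates the full chain-rule equation
`dtheta/dt = k_on epsilon(theta) / (dA/dtheta)`.  Two numerical facts
matter:

1. The RHS is a difference of two `O(1/theta)` terms; below
   `theta = 0.04` rad the package integrates a series expansion of
   `theta * dtheta/dt` (orders 0, 2, 4, 6 in θ, derived symbolically)
   to avoid catastrophic cancellation.
2. Under the CoopCM the area `A(theta)` peaks slightly before closure
   (at `theta* ≈ 0.94 pi` for the SK-MEL-2 parameters) because
   `1 - cos theta` saturates while `H` still grows; the chain-rule
   equation is singular there.  The integration stops just below
   `theta*` and holds the angle afterwards.  Physically, the
   coupled rim-growth/curvature model loses validity at the point of
   near-closure, where scission machinery takes over.

Consequently the square-root law and the ODE agree to 1e-6 relative
only in the asymptotic regime (verified to 1.1e-7 for pseudotimes
≤ 1e-6; the deviation grows roughly linearly in t, reaching ~1 % at
t = 0.01 and ~16 % near closure).  The square-root law is therefore a
small-angle approximation that happens to describe the full
trajectory well, not an exact solution; the package keeps the ODE as
the reference and the closed form as the fitting model.

## Cap fitting (maximum likelihood)

Each localization `i` contributes

    p_i = (1 - w_bg) (1/M) sum_m N3(x_i | p_m, Sigma_i) + w_bg / V_roi

with `M` cap-surface model points (spacing 6 nm at the refinement
stage, 12 nm during multistart; `M` scales with the cap area so the
discretization density is θ-independent), `Sigma_i` diagonal with
variances `sigma_xy_i^2 + sigma_extra^2` (lateral) and `sigma_z_i^2 +
sigma_extra^2` (axial), and `V_roi` the padded bounding-box volume
(padding 50 nm).  `sigma_extra` (initialized at 10 nm, bounded to
[0, 30] nm) absorbs coat thickness, antibody displacement and
residual blur; `w_bg` is bounded to [0, 0.5] so the background term
cannot absorb nearly-closed caps.

Nine parameters are optimized: sphere center (3), log radius, closing
angle, axis polar/azimuth, `w_bg`, `sigma_extra`.  Optimization is
derivative-free Nelder-Mead with an explicit initial simplex whose
per-parameter steps reflect physical scales (≈12 nm for positions,
≈0.2 rad for angles); without this the default 5 %-of-coordinate
simplex stalls.  Multistart runs over closing angles
{20°, 60°, 100°, 140°, 170°} plus a data-driven estimate (98th
percentile of angular spread around a robust algebraic sphere fit);
initial center/axis come from an outlier-trimmed algebraic sphere fit
(falling back to the best-fit-plane normal for nearly flat clouds).
The best coarse start is refined at fine spacing; ties are broken
toward the smaller closing angle.  The likelihood kernel is a
numba-compiled log-sum-exp (numpy fallback).  Budget defaults
(400 evaluations per start, 1000 in refinement) were chosen so a site
fits in ~1-2 s with recovery errors indistinguishable from a 4000-
evaluation budget.

Orientation has two degrees of freedom (the cap is rotationally
symmetric).  A fitted pole pointing toward the coverslip corresponds
to negative signed curvature; the flat-site rule sets `H = 0`,
`theta = 0` and a `flat` flag whenever the signed curvature is ≤ 0
(boundary inclusive).

## Simulator

The generator reproduces the experimental imaging conditions it
emulates: per `protein_density_nm2` (default 600 nm², a documented
free constant, ≈110 positions for a 65,000 nm² coat) one protein
position on a quasi-uniform surface lattice; Bernoulli labeling
(p = 0.6); isotropic normal linkage displacement (5 nm), redrawn per
blink (the fluorophore rotates freely between blinks); blink count
1 + geometric (continue probability 0.5); exponential on-times (mean
1.6 frames) at uniformly random start times; per-frame photons
Poisson with mean 11,000 × (on-fraction of the frame); localization
noise with the Thompson-style Gaussian-PSF Cramér-Rao bound computed
from that frame's photons and 130 background photons per 100 nm
pixel.  The PSF calibration constants (`psf_sigma_xy = 243.414` nm,
axial factor 3.2051) are fixed once so the defaults reproduce modal
precisions of 3.9 nm (xy) and 12.5 nm (z).

Two data-quality steps mirror how experimental tables are produced
before any model fitting and default ON:

- a precision filter (`sigma_xy ≤ 20 nm`, `sigma_z ≤ 30 nm`) that
  discards dim partial-frame detections;
- merging of persistent detections (within 35 nm laterally, ≤ 1 dark
  frame) into single localizations with inverse-variance-weighted
  positions and summed photons.

Without these, a site's table contains several dependent records per
blink plus near-uninformative dim localizations; fitting such tables
biases the recovered closing angle low by ~5°.  With them, the
estimator calibration over θ ∈ (10°, 170°) shows |mean error| < 3°
with a spread of ~3-5° that grows toward the extremes (flat caps
barely constrain θ; nearly closed caps have label-free holes
indistinguishable from real openings).

What the simulator does *not* emulate: camera-frame image formation
and PSF fitting, drift, sample-preparation artifacts, non-spherical
(ellipsoidal/irregular) coats, labeling inhomogeneity beyond Bernoulli
thinning, and fluorophore photophysics beyond the two-state +
bleaching model.  Passing recovery tests therefore validate the
estimator under the stated noise model, not against every real-data
pathology.

## Site detection and QC

Fields are rendered as 2D 10-nm-pixel histograms, blurred with a
100 nm Gaussian; peaks above a threshold (default: Otsu of the
blurred image, an explicit stand-in for a manually chosen level) are
site candidates, merged when closer than 200 nm.  ROIs are 300 nm
lateral crops.  Disconnected (non-endocytic, high-curvature)
structures are flagged by `H` strictly above a cell-line threshold
(SK-MEL-2 0.016, U2OS 0.013, 3T3 0.014 nm⁻¹) and excluded from growth
fits and pseudotime; flat sites are excluded from growth fits but
enter pseudotime at rank 0.  An upside-down heuristic (pole toward
the coverslip for curved sites) is report-only.

## Pseudotime and averaging

Sites are stably sorted by θ (ties by site id); all flat sites share
rank 0; `t = rank / max_rank`.  Rolling medians are centered with
truncated boundary windows (window = 5 % of the series by default).
Equal-count binning assigns `floor(N / n_bins)` sites per bin in
t-order and drops the trailing remainder (the highest-t sites) with a
warning.

For averaging, each converged site is translated so its fitted sphere
center is at the origin (rescaling is therefore isotropic about the
sphere center; scaling about the centroid is available as an option),
rotated so the fitted axis is +z, scaled by (bin median radius /
site radius), duplicated at 72 azimuthal rotations of 5°, and
rendered into 5 nm voxels smoothed with a 3 nm Gaussian.  Sliding-
window movie frames cover ranks [0, 30), [20, 50), ... and are
labeled with the median pseudotime of their members.

## Problem sizes used in the tests

The simulation-based suites use 100 U-shaped sites (hemisphere
R = 97 nm + cylinder R/2) for the bias experiment, 200 sites with
θ ~ U(10°, 170°) for the calibration sweep, 1,500-point populations
for growth-model recovery and BIC selection (20 seeds), and small
(≤ 12-site) cohorts for the end-to-end pipeline checks.  These sizes
give standard errors comfortably below the asserted tolerances.

## Known limitations

- The MLE shows a residual ≈ −3° closing-angle bias at mid-to-high θ
  driven by the clustered (per-fluorophore) structure of real
  localization data; it is within the calibration contract but not
  zero.
- The background model is uniform over the ROI box; structured
  background (neighboring sites) is handled by cropping, not by the
  model.
- The disconnected-population threshold is a single curvature cut;
  no attempt is made to model the non-endocytic population.
- Manual curation steps of the original workflow (doubles,
  upside-down sites, plaques) are reduced to automatic flags.
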