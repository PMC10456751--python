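# Methods

This note documents the statistical models, conventions and numerical
choices behind `dxtrack`, and what the synthetic-data validation does and
does not establish about real recordings.

## The measurement model

A DXT recording yields, per diffraction spot, a time series of the
nanocrystal orientation in two angles: tilt θ (the Bragg-sensitive
direction) and twist χ (azimuthal rotation about the surface normal),
both in mrad.  All analyses work on *displacements* within a trajectory,
so absolute angular offsets cancel and linear (non-circular) statistics
are appropriate: observed excursions are a few mrad, vastly below a
radian.

The observed mean squared displacement is modelled as

    MSD(t) = D_α t^α + 2β²

with units mrad²/ms^α for D_α and mrad for β.  α < 1 is subdiffusion,
α > 1 superdiffusion; an independent per-frame measurement error of
standard deviation β enters each displacement twice, contributing the
constant 2β².

Two standard acquisition geometries are built in as defaults: a fast
recording (0.1 ms/frame × 450 frames) and a slow recording (12.5 ms/frame
× 5000 frames).  Lifetime classes (below) are only meaningful for the
fast geometry.

## MSD estimation and fitting

* **Estimator** — the time-averaged MSD with overlapping windows, pooled
  over trajectories with pair-count weighting: for lag nΔt, the sum of
  (x(t+nΔt) − x(t))² over all trajectories and all start frames, divided
  by the total pair count.  This is the standard single-particle-tracking
  estimator; with overlapping windows it extracts the maximum number of
  displacement pairs from short-lived spots.  Lags with zero pairs are
  omitted.  Its exactness is verified against a brute-force double-loop
  oracle.
* **Anomalous fit** — weighted nonlinear least squares (σ ∝ 1/√pair_count)
  with bounds D_α ≥ 0, 0 < α ≤ 2, β ≥ 0.  Initialisation: β² from the
  short-lag linear extrapolation (2·MSD₁ − MSD₂)/2, then (D_α, α) from a
  log–log ordinary least squares of the floor-subtracted curve.
  Non-convergence triggers up to three multiplicatively jittered restarts
  (log-normal, σ = 0.3, fixed internal seed); a persistent failure is
  returned as an explicit failure object, never as silent zeros.  An
  all-zero curve returns D_α = β = 0 with α flagged unidentifiable.
* **Linear slope** — ordinary least squares of MSD against lag with a
  free intercept, which absorbs the noise floor 2β².  The default window
  is lags up to 25 % of the longest available lag (config-exposed); the
  quoted "slope of the MSD curve" in mrad²/ms is this quantity.  Both the
  anomalous fit and the linear slope are always reported side by side.
* **Radiation-damage check** — the ensemble is split into first and
  second acquisition halves (file order when no per-spot clock exists;
  the first half receives the extra trajectory for odd counts) and the
  slope ratio second/first is reported with a 95 % percentile bootstrap
  over trajectories resampled within each half.  A ratio compatible with
  1 is the no-damage diagnostic.

## Lifetime filtering

Lifetime is the duration of uninterrupted spot visibility,
LT = n_frames × Δt by default (the spot is present for the whole of its
n-frame run).  The alternative (n−1)×Δt span convention is available via
a flag and the convention in force is stamped into results.  Classes are
half-open intervals [min, max): the standard fast-recording classes are
LT < 2.5 ms and 2.5 ms ≤ LT < 4.0 ms, so a 2.4 ms spot is "short" and a
2.5 ms spot is "medium".  Applying a class whose finite upper bound is at
or below the two-frame minimum lifetime (e.g. the 2.5/4.0 ms classes on a
12.5 ms/frame recording) is a configuration error, not an empty result.
Trajectories that fill the entire nominal recording are right-censored in
lifetime; they are retained and counted in the filter metadata.

A frame gap in an input table terminates a trajectory and the remainder
becomes a new trajectory: a re-appearing spot cannot be distinguished
from a new one, and lifetime semantics require uninterrupted visibility.

## Rotational bias

Each trajectory is classified by the sign of its net twist displacement
(last − first χ): positive = counterclockwise under the fixed convention
*+χ = CCW viewed from the cytoplasmic side*.  The opposite
(extracellular-side) viewing convention of earlier work is a global sign
flip, exposed as a parameter.  The summary reports raw counts, the CCW
fraction among directed trajectories with a 95 % trajectory-level
percentile-bootstrap interval (seeded, 1000 resamples by default), and
the linear MSD slope of the CCW and CW sub-ensembles separately; a
direction with fewer than 5 members reports no slope rather than an
unstable one.

## Histograms, Gaussian fits and subtraction maps

The displacement statistic is the per-trajectory net Δχ by default — the
same quantity that carries the direction classification; a pooled
fixed-lag mode is available and the active mode is stamped into results.
Histograms use a fixed bin width (default 0.25 mrad) on a grid with a bin
centred on zero, so the edge set is exactly mirror-symmetric and the
χ → −χ flip of an ensemble mirrors its histogram bitwise.  Densities are
unit-area (1/mrad).

The Gaussian fit is least squares of A/(σ√2π)·exp(−(x−loc)²/2σ²) to
bin-centre densities, initialised from the histogram's moments, requiring
at least 5 occupied bins.  The amplitude A ("peak area") is free and may
be below 1 when the Gaussian captures only the core of a heavier-tailed
distribution.  FWHM = 2√(2 ln 2)·σ is derived from σ exactly, and its
standard error propagated exactly from σ's, so the identity holds on
every emitted fit by construction.  Shift equivariance of the fit is
exact up to the (negligible) leverage of far-tail zero bins whose number
depends on the data range.

Subtraction maps difference two unit-normalized histograms
(treatment − control) on a common grid.  Identical-phase grids are
differenced directly; offset grids with the same bin width are first
rebinned by exact piecewise-constant overlap weighting, which conserves
probability mass, so the difference always integrates to 0 (within
rounding).  Extrema are picked on a 3-bin moving average built from
symmetric pairs (bitwise reversal-invariant); each maximal sign-constant
run contributes its largest-|value| bin (exact ties averaged), kept when
it exceeds 2× the RMS of the outer 20 % of bins.  Threshold factor,
smoothing width and tail fraction are parameters.

## The simulator

The generator inverts the analysis model.  Per particle and axis the
latent path satisfies Var[x(t) − x(0)] = m·t^α where m (mrad²/ms^α) is
the *observable* MSD coefficient — the same number the analysis reports
as a slope — rather than a bare diffusion constant, so simulation
settings and analysis output are directly comparable and factor-of-two
conventions cannot creep in.  α = 1 uses iid Gaussian increments of
variance m·Δt; α ≠ 1 uses fractional Gaussian noise with Hurst exponent
H = α/2, generated from the exact increment covariance by Cholesky
factorisation (cached per (length, α); practical to 5000 frames).  Twist
adds an optional constant drift (mrad/ms, + = CCW); both axes receive
independent per-frame observation noise N(0, β²).

Spot lifetime arises from a first-passage mechanism: the spot is visible
while the latent tilt stays within a halfwidth w of its initial value
(the window is centred on each particle's starting tilt, since spots are
by construction visible when they appear; twist motion never terminates a
spot, because the Bragg condition is a tilt condition).  The first
contiguous visible run becomes the observed trajectory; single-frame runs
are discarded as untrackable.  This reproduces the central premise of
lifetime filtering — faster particles exit the window sooner, verified by
a rank-test in the suite.

The default halfwidth w = 6.0 mrad was fixed once by the shipped
calibration scan (`scripts/calibrate_window.py`): at m = 10 mrad²/ms and
0.1 ms/frame it places the median lifetime at ≈ 3.4 ms, inside the
2.5–4.0 ms medium class.  This is a modelling choice that makes the
lifetime classes well-populated at the documented simulation settings; it
is not a claim about any instrument's physical acceptance.

Determinism: a (config, seed) pair fully determines the output.  Each
particle draws from its own substream spawned from the seed, and
observation noise is drawn for the full nominal recording length, so the
random stream layout is independent of the window setting and of other
particles.

### What the simulator does and does not emulate

It reproduces the statistical structure the analysis assumes — power-law
ensemble MSD, additive Gaussian measurement noise, constant rotational
drift, speed-dependent spot lifetimes, the two acquisition geometries.
It does **not** model photon statistics or spot intensity profiles,
rocking-curve shape, detector distortion, tracking/linking errors,
heterogeneity of attachment geometry, or state-switching dynamics within
one trajectory.  Passing the validation suite therefore demonstrates that
the estimators are correct and well-calibrated *for data obeying the
stated model*, not that any particular biological conclusion is
reproduced.

## Geometry conventions

Bragg angle θ_B = arcsin(λ/2d) with λ(Å) = 12.3984/E(keV); the
flat-detector mapping is the tangent-plane r = L·tan 2θ with azimuth from
the +x axis, χ ∈ (−π, π] (the −x axis maps to +π).  The bandwidth
acceptance used for ring assignment is the first-order width
Δ(2θ) = tan θ_B · ΔE/E.  Shipped d-spacings: Au(111) 2.3549 Å, ZnO(100)
2.8143 Å, ZnO(002) 2.6033 Å, ZnO(101) 2.4759 Å — standard lattice values,
overridable per run.  The analysis modules never need absolute geometry;
it exists for simulation and optional detector-coordinate input.

## Problem sizes and tolerances

The validation suite uses 1000 particles × 450 frames for parameter
recovery (recovering m within 10 %, α within ±0.1, β within ±0.15 mrad),
50 seeded replicates of 1000 particles for the null calibration of the
bias interval (≥ 90 % coverage of 0.5 expected), 500 + 500 particles for
the lifetime/speed rank test, and 5000 samples for Gaussian FWHM
recovery (within 5 %).  Estimator exactness is held to 1e-12 relative
against the brute-force oracle; conservation laws (histogram area 1,
subtraction integral 0) to 1e-9; time-step consistency to 1e-9 ms.

## Known limitations

* The anomalous fit's β is weakly identified when 2β² is small relative
  to the first-lag MSD; its seed-to-seed scatter is a few tenths of a
  mrad at 1000 particles.  The linear slope is insensitive to this.
* Bootstrap intervals are percentile intervals; no BCa correction.
* The subtraction-map extremum list depends on the smoothing and
  threshold parameters in flat, quantized tails; the map itself does not.
* Lifetime right-censoring at the recording end is flagged but not
  modelled (no survival analysis, by design).
* Fractional-noise generation is exact but O(n³) in trajectory length
  for the one-time Cholesky factor; beyond ~5000 frames a circulant
  embedding would be preferable.
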