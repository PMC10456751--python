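# dxtrack

Analysis of **diffracted X-ray tracking (DXT)** angular trajectories.

DXT follows single protein molecules by attaching a gold or ZnO
nanocrystal to a chosen domain and tracking the Laue diffraction spot it
produces in a polychromatic ("pink") X-ray beam.  The spot position maps
to the nanocrystal orientation in two angles — tilt (θ) and twist (χ) —
so each spot trajectory is a direct readout of the domain's orientational
dynamics with picometer-scale sensitivity at microsecond-to-millisecond
frame rates.  This package implements the trajectory-level analysis used
to compare ligand conditions of a membrane channel (e.g. an agonist vs. a
competitive antagonist acting on TRPV1):

* **MSD analysis** — the pooled time-averaged mean squared angular
  displacement, fitted with the anomalous-diffusion model
  `MSD(t) = D_α t^α + 2β²` (D_α: anomalous diffusion coefficient, α:
  anomalous exponent, β: measurement error) and, alongside it, the plain
  linear slope in mrad²/ms that is quoted for a recording.
* **Lifetime filtering** — a spot stays visible only while the crystal
  tilt remains inside the Bragg acceptance window of the beam bandwidth,
  so fast-moving molecules produce short-lived spots.  Partitioning by
  lifetime (LT < 2.5 ms; 2.5 ms ≤ LT < 4.0 ms) partitions the ensemble by
  speed.
* **Rotational-bias statistics** — clockwise vs. counterclockwise
  classification of the twist motion (sign convention: +χ = CCW viewed
  from the cytoplasmic side), with per-direction MSD slopes and a
  trajectory-bootstrap confidence interval on the CCW fraction.
* **Displacement histograms & subtraction maps** — unit-area histograms
  of angular displacement fitted with a Gaussian (location, FWHM =
  2√(2 ln 2)·σ, peak area), and treatment-minus-control difference maps
  whose signed extrema summarize ligand-induced shifts.
* **A synthetic trajectory simulator** — rotational (fractional) Brownian
  motion with optional twist drift, per-frame measurement noise and the
  Bragg-window first-passage lifetime mechanism, so every analysis stage
  can be validated against known ground truth without beamline data.
* **Detector geometry** — Bragg angles, flat-detector ↔ angle conversion
  and powder-ring assignment (Au(111), ZnO(100)/(002)/(101)) for
  detector-coordinate input and simulation.

## Worked example

Simulate a fast recording (0.1 ms/frame × 450 frames) of 1000 particles
with MSD slope 10 mrad²/ms per axis, measurement noise β = 0.5 mrad and a
counterclockwise twist drift of 0.2 mrad/ms, then analyze it:

```python
import numpy as np
from dxtrack import (SimulationConfig, simulate_ensemble, compute_msd,
                     fit_msd_anomalous, linear_slope, rotational_bias,
                     filter_by_lifetime, SHORT, compute_lifetime)

cfg = SimulationConfig(n_particles=1000, msd_slope_theta=10.0,
                       msd_slope_chi=10.0, beta=0.5, drift_chi=0.2, seed=1)
ens, truth = simulate_ensemble(cfg)
print(f"observed spots: {len(ens)} / {cfg.n_particles}")
lts = [compute_lifetime(t, cfg.frame_interval) for t in ens]
print(f"median lifetime: {np.median(lts):.2f} ms")

short = filter_by_lifetime(ens, SHORT)
print(f"short-lifetime class (LT < 2.5 ms): {len(short)} spots")

curve = compute_msd(ens, "chi", max_lag_frames=25)
fit = fit_msd_anomalous(curve)
slope = linear_slope(curve)
print(f"linear MSD slope: {slope.slope:.2f} mrad^2/ms")
print(f"anomalous fit: D_alpha={fit.d_alpha:.2f}, alpha={fit.alpha:.2f}, "
      f"beta={fit.beta:.2f} mrad")

bias = rotational_bias(ens, n_bootstrap=1000, seed=1)
print(f"CCW {bias.n_ccw} / CW {bias.n_cw}, "
      f"ccw fraction {bias.ccw_fraction:.3f} "
      f"[{bias.ci_low:.3f}, {bias.ci_high:.3f}]")
```

which prints

```
observed spots: 1000 / 1000
median lifetime: 3.30 ms
short-lifetime class (LT < 2.5 ms): 366 spots
linear MSD slope: 10.32 mrad^2/ms
anomalous fit: D_alpha=10.60, alpha=0.98, beta=0.38 mrad
CCW 534 / CW 466, ccw fraction 0.534 [0.501, 0.565]
```

The pooled MSD slope recovers the configured 10 mrad²/ms, the anomalous
exponent is compatible with ordinary Brownian motion (α ≈ 1), and the
drift shows up as a CCW fraction whose 95 % bootstrap interval excludes
0.5.  Because spot visibility is terminated by the tilt window, lifetimes
cluster around 3 ms and about a third of the spots fall into the
fast-mover class.

The same analysis is available from the shell:

```sh
dxt simulate --config sim.yaml --seed 1 --out ens.csv
dxt analyze --input ens.csv --frame-interval 0.1 --axis chi --out msd.json
dxt report --config run.yaml --out results/
dxt fixtures --out fixtures/ --seed 0
```

Trajectory tables are plain CSV/TSV with header
`id,frame,time_ms,theta_mrad,chi_mrad[,ring]`; all run artifacts are CSV
and JSON with explicit units in key names.

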