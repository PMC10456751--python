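"""Calibrate the default Bragg-acceptance halfwidth of the simulator.

Scans window halfwidths and reports the median observed spot lifetime at
the reference fast-recording condition (MSD slope 10 mrad^2/ms per axis,
0.1 ms/frame, 450 frames).  The shipped default
(`dxtrack.simulate.DEFAULT_WINDOW_HALFWIDTH_MRAD`) is chosen so the median
lifetime falls inside the 2.5-4.0 ms medium class — a documented modelling
choice, since the physical angular acceptance of the instrument is not
published.

Usage: python scripts/calibrate_window.py [--seed N]
"""

import argparse

import numpy as np

from dxtrack import SimulationConfig, compute_lifetime, simulate_ensemble


def median_lifetime_ms(halfwidth: float, seed: int, n: int = 500) -> float:
    cfg = SimulationConfig(
        n_particles=n, theta_window_halfwidth=halfwidth, seed=seed
    )
    ens, truth = simulate_ensemble(cfg)
    # include sub-threshold (discarded) spots via ground truth so the
    # median is over all particles, not survivors
    return float(
        np.median(truth.true_lifetime_frames) * cfg.frame_interval
    )


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    print("halfwidth_mrad  median_lifetime_ms  in_medium_class")
    for w in (3.0, 4.0, 5.0, 5.5, 6.0, 6.5, 7.0, 8.0):
        med = median_lifetime_ms(w, args.seed)
        print(f"{w:14.1f}  {med:18.2f}  {2.5 <= med < 4.0}")


if __name__ == "__main__":
    main()
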