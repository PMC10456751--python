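"""MSD estimation and model fitting against independent oracles."""

import numpy as np
import pytest

from dxtrack import (
    EmptyEnsembleError,
    FitError,
    MSDCurve,
    SimulationConfig,
    compute_msd,
    fit_msd_anomalous,
    linear_slope,
    radiation_damage_check,
    simulate_ensemble,
)

from conftest import make_ensemble


def brute_force_msd(chis, frame_interval, max_lag):
    """Independent O(N^2) oracle: explicit double loop over start frames."""
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for x in chis:
        for n in range(1, max_lag + 1):
            for i in range(len(x) - n):
                sums[n - 1] += (x[i + n] - x[i]) ** 2
                counts[n - 1] += 1
    keep = counts > 0
    lags = np.arange(1, max_lag + 1) * frame_interval
    return lags[keep], sums[keep] / counts[keep], counts[keep]


class TestComputeMsd:
    def test_hand_enumerated_ramp(self):
        # chi = [0,1,2,3] at 1 ms frames: displacement pairs give
        # msd = [1, 4, 9] at lags [1, 2, 3] ms (3, 2, 1 pairs)
        ens = make_ensemble([[0.0, 1.0, 2.0, 3.0]])
        curve = compute_msd(ens, "chi", 3)
        np.testing.assert_allclose(curve.lag, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(curve.msd, [1.0, 4.0, 9.0])
        np.testing.assert_array_equal(curve.pair_count, [3, 2, 1])

    def test_constant_trajectory_is_identically_zero(self):
        ens = make_ensemble([[2.5] * 6])
        curve = compute_msd(ens, "chi", 5)
        np.testing.assert_array_equal(curve.msd, np.zeros(5))

    def test_matches_brute_force_oracle(self, rng):
        chis = [rng.normal(0, 2, size=rng.integers(4, 11))
                for _ in range(5)]
        ens = make_ensemble(chis, frame_interval=0.5)
        curve = compute_msd(ens, "chi", 9)
        lags, msd, counts = brute_force_msd(chis, 0.5, 9)
        np.testing.assert_allclose(curve.msd, msd, rtol=1e-12)
        np.testing.assert_allclose(curve.lag, lags)
        np.testing.assert_array_equal(curve.pair_count, counts)

    def test_lags_beyond_all_trajectories_are_omitted(self):
        ens = make_ensemble([[0.0, 1.0, 2.0]])
        curve = compute_msd(ens, "chi", 10)
        assert len(curve.lag) == 2

    def test_empty_ensemble_rejected(self):
        from dxtrack import TrajectoryEnsemble

        ens = TrajectoryEnsemble([], frame_interval=1.0, n_frames_nominal=5)
        with pytest.raises(EmptyEnsembleError):
            compute_msd(ens, "chi", 3)

    def test_noise_only_msd_is_flat_at_twice_beta_squared(self):
        # m = 0, beta = 0.7: MSD(t) = 2*beta^2 at every lag
        cfg = SimulationConfig(
            n_particles=400, n_frames=100, msd_slope_theta=0.0,
            msd_slope_chi=0.0, beta=0.7, theta_window_halfwidth=np.inf,
            seed=3,
        )
        ens, _ = simulate_ensemble(cfg)
        curve = compute_msd(ens, "chi", 20)
        np.testing.assert_allclose(
            curve.msd, 2 * 0.7**2, rtol=0.05
        )


def model_curve(t, d, a, b, counts=None):
    t = np.asarray(t, dtype=float)
    msd = d * t**a + 2 * b**2
    counts = np.full(len(t), 1000) if counts is None else counts
    return MSDCurve(lag=t, msd=msd, pair_count=counts, axis="chi",
                    n_trajectories=1)


class TestAnomalousFit:
    def test_exact_linear_curve(self):
        t = np.arange(1, 30) * 0.1
        fit = fit_msd_anomalous(model_curve(t, 10.0, 1.0, 0.0))
        assert fit.d_alpha == pytest.approx(10.0, abs=1e-6)
        assert fit.alpha == pytest.approx(1.0, abs=1e-6)
        assert fit.beta == pytest.approx(0.0, abs=1e-3)

    def test_exact_subdiffusive_curve_with_noise_floor(self):
        # forward-evaluated 5*t^0.5 + 2*0.3^2 recovered to 1e-4
        t = np.arange(1, 40) * 0.1
        fit = fit_msd_anomalous(model_curve(t, 5.0, 0.5, 0.3))
        assert fit.d_alpha == pytest.approx(5.0, abs=1e-4)
        assert fit.alpha == pytest.approx(0.5, abs=1e-4)
        assert fit.beta == pytest.approx(0.3, abs=1e-4)

    def test_all_zero_curve_flagged_unidentifiable(self):
        t = np.arange(1, 10) * 0.1
        curve = MSDCurve(lag=t, msd=np.zeros(9),
                         pair_count=np.full(9, 10), axis="chi")
        fit = fit_msd_anomalous(curve)
        assert fit.d_alpha == 0.0
        assert fit.beta == 0.0
        assert "alpha_unidentifiable" in fit.flags

    def test_too_few_points_rejected(self):
        t = np.array([0.1, 0.2, 0.3])
        with pytest.raises(FitError, match=">= 4"):
            fit_msd_anomalous(model_curve(t, 1.0, 1.0, 0.0))

    def test_fit_range_restricts_lags(self):
        t = np.arange(1, 50) * 0.1
        fit = fit_msd_anomalous(model_curve(t, 8.0, 1.0, 0.2),
                                fit_range=(0.1, 2.0))
        assert fit.fit_range == (pytest.approx(0.1), pytest.approx(2.0))
        assert fit.n_points == 20


class TestLinearSlope:
    def test_exact_line_with_intercept(self):
        t = np.arange(1, 20) * 0.1
        res = linear_slope(model_curve(t, 10.0, 1.0, 0.5), (0.1, 2.0))
        assert res.slope == pytest.approx(10.0, abs=1e-9)
        assert res.intercept == pytest.approx(0.5, abs=1e-9)

    def test_matches_independent_ols_on_curved_input(self):
        # 5*t^0.5 on t in [0.1, 4.5]: compare to closed-form OLS
        t = np.arange(1, 46) * 0.1
        y = 5 * t**0.5
        tm, ym = t.mean(), y.mean()
        expected = np.sum((t - tm) * (y - ym)) / np.sum((t - tm) ** 2)
        res = linear_slope(model_curve(t, 5.0, 0.5, 0.0), (0.1, 4.5))
        assert res.slope == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_constant_offset(self):
        t = np.arange(1, 20) * 0.1
        a = linear_slope(model_curve(t, 7.0, 1.0, 0.0), (0.1, 1.9))
        b = linear_slope(model_curve(t, 7.0, 1.0, 1.3), (0.1, 1.9))
        assert a.slope == pytest.approx(b.slope, rel=1e-12)

    def test_single_point_range_rejected(self):
        t = np.arange(1, 20) * 0.1
        with pytest.raises(FitError, match=">= 2"):
            linear_slope(model_curve(t, 1.0, 1.0, 0.0), (0.1, 0.15))


class TestRadiationDamageCheck:
    def test_identical_halves_give_ratio_one(self):
        rng = np.random.Generator(np.random.PCG64(8))
        walks = [np.cumsum(rng.normal(0, 1, 30)) for _ in range(10)]
        ens = make_ensemble(walks + walks[:], frame_interval=0.1)
        check = radiation_damage_check(ens, n_bootstrap=20, seed=0)
        assert check.ratio == pytest.approx(1.0, rel=1e-12)

    def test_stationary_ensemble_ci_contains_one(self):
        cfg = SimulationConfig(n_particles=500, n_frames=100, seed=17,
                               theta_window_halfwidth=np.inf)
        ens, _ = simulate_ensemble(cfg)
        check = radiation_damage_check(ens, n_bootstrap=100, seed=1)
        assert check.ci_low < 1.0 < check.ci_high

    def test_doubled_second_half_detected(self):
        # second half built with doubled slope: ratio ~ 2 and inside CI
        def sim(m, seed, n):
            cfg = SimulationConfig(
                n_particles=n, n_frames=100, msd_slope_chi=m,
                msd_slope_theta=m, beta=0.0, seed=seed,
                theta_window_halfwidth=np.inf,
            )
            return simulate_ensemble(cfg)[0]

        first = sim(5.0, 31, 250)
        second = sim(10.0, 32, 250)
        trajs = list(first) + [
            type(t)(id=f"h2_{t.id}", frame_index=t.frame_index,
                    time=t.time, theta=t.theta, chi=t.chi)
            for t in second
        ]
        ens = first.replace(trajs)
        check = radiation_damage_check(ens, n_bootstrap=60, seed=2)
        assert check.ratio == pytest.approx(2.0, rel=0.15)
        assert check.ci_low <= check.ratio <= check.ci_high
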