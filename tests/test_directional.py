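"""Rotational bias, displacement histograms, Gaussian fits, subtraction maps."""

import math

import numpy as np
import pytest

from dxtrack import (
    FWHM_FACTOR,
    AngularHistogram,
    DataError,
    FitError,
    SimulationConfig,
    classify_rotation,
    displacement_histogram,
    fit_gaussian,
    net_displacement,
    rotational_bias,
    simulate_ensemble,
    subtract_histograms,
)

from conftest import make_ensemble, make_trajectory


def histogram_from_samples(samples, bin_width=0.25):
    ens = make_ensemble([[0.0, float(v)] for v in samples])
    return displacement_histogram(ens, bin_width=bin_width)


def gaussian_histogram(loc, sigma, lo=-12.0, hi=12.0, width=0.05):
    """Histogram whose densities are an exact unit Gaussian evaluated and
    renormalized on the grid (independent of any sampling)."""
    edges = np.arange(lo, hi + width / 2, width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = np.exp(-((centers - loc) ** 2) / (2 * sigma**2))
    dens /= np.sum(dens) * width
    return AngularHistogram(
        bin_edges=edges, density=dens,
        counts=np.zeros(len(dens), dtype=int), axis="chi", normalized=True,
    )


class TestNetDisplacementAndCounts:
    def test_net_displacement_is_last_minus_first(self):
        assert net_displacement(make_trajectory("a", [0, 1, 2])) == 2.0
        assert net_displacement(make_trajectory("b", [5, 5])) == 0.0

    def test_sign_flips_under_mirroring(self):
        t = make_trajectory("a", [0.0, 0.4, -1.2])
        assert net_displacement(t.mirrored()) == -net_displacement(t)

    def test_pure_drift_ensemble_is_all_ccw(self):
        ens = make_ensemble([[0, 1, 2], [0, 2, 4], [1, 2, 3]])
        assert classify_rotation(ens) == (3, 0, 0)

    def test_mirroring_swaps_ccw_and_cw_exactly(self):
        rng = np.random.Generator(np.random.PCG64(2))
        ens = make_ensemble(
            [np.cumsum(rng.normal(0.1, 1, 20)) for _ in range(40)]
        )
        ccw, cw, null = classify_rotation(ens)
        m_ccw, m_cw, m_null = classify_rotation(ens.mirrored())
        assert (m_ccw, m_cw, m_null) == (cw, ccw, null)

    def test_sign_convention_flag_equals_mirroring(self):
        ens = make_ensemble([[0, 1], [0, -2], [0, 3]])
        assert classify_rotation(ens, sign=-1) == classify_rotation(
            ens.mirrored()
        )


class TestRotationalBias:
    def test_driftless_simulation_ci_contains_half(self):
        cfg = SimulationConfig(
            n_particles=1000, theta_window_halfwidth=np.inf, seed=101
        )
        ens, _ = simulate_ensemble(cfg)
        res = rotational_bias(ens, n_bootstrap=500, seed=7)
        assert res.ci_low <= 0.5 <= res.ci_high
        assert res.n_total == 1000

    def test_injected_drift_detected(self):
        cfg = SimulationConfig(
            n_particles=1000, drift_chi=0.2,
            theta_window_halfwidth=np.inf, seed=14,
        )
        ens, _ = simulate_ensemble(cfg)
        res = rotational_bias(ens, n_bootstrap=500, seed=7)
        assert res.ccw_fraction > 0.5
        assert res.ci_low > 0.5

    def test_zero_drift_direction_slopes_agree(self):
        cfg = SimulationConfig(
            n_particles=800, theta_window_halfwidth=np.inf, seed=15
        )
        ens, _ = simulate_ensemble(cfg)
        res = rotational_bias(ens, n_bootstrap=200, seed=3)
        assert res.msd_slope_ccw == pytest.approx(
            res.msd_slope_cw, rel=0.15
        )

    def test_single_trajectory_degenerate_ci(self):
        ens = make_ensemble([[0.0, 1.0]])
        res = rotational_bias(ens, n_bootstrap=50, seed=0)
        assert (res.n_ccw, res.n_cw, res.n_null) == (1, 0, 0)
        assert (res.ci_low, res.ci_high) == (0.0, 1.0)
        assert "degenerate_ci_single_trajectory" in res.flags
        assert res.msd_slope_ccw is None  # below the minimum class size

    def test_bootstrap_ci_mirrors_under_sign_flip(self):
        rng = np.random.Generator(np.random.PCG64(5))
        ens = make_ensemble(
            [np.cumsum(rng.normal(0.05, 1, 15)) for _ in range(60)]
        )
        a = rotational_bias(ens, n_bootstrap=300, seed=11)
        b = rotational_bias(ens.mirrored(), n_bootstrap=300, seed=11)
        assert b.ccw_fraction == pytest.approx(1 - a.ccw_fraction)
        assert b.ci_low == pytest.approx(1 - a.ci_high)
        assert b.ci_high == pytest.approx(1 - a.ci_low)


class TestDisplacementHistogram:
    def test_identical_displacements_occupy_single_bin(self):
        ens = make_ensemble([[0.0, 1.1]] * 7)
        h = displacement_histogram(ens)
        assert np.count_nonzero(h.counts) == 1
        assert h.integral() == pytest.approx(1.0, abs=1e-12)

    def test_unit_area_on_random_data(self, random_ensemble):
        h = displacement_histogram(random_ensemble)
        assert h.integral() == pytest.approx(1.0, abs=1e-9)

    def test_zero_is_a_bin_center_and_edges_symmetric(self):
        ens = make_ensemble([[0.0, 0.9], [0.0, -1.7]])
        h = displacement_histogram(ens)
        np.testing.assert_allclose(h.bin_edges, -h.bin_edges[::-1])
        assert 0.0 in np.round(h.centers, 12)

    def test_mirrored_data_gives_mirrored_histogram(self, random_ensemble):
        h = displacement_histogram(random_ensemble)
        hm = displacement_histogram(random_ensemble.mirrored())
        np.testing.assert_array_equal(hm.density, h.density[::-1])
        np.testing.assert_allclose(hm.bin_edges, -h.bin_edges[::-1])

    def test_fixed_lag_mode_pools_all_pairs(self):
        ens = make_ensemble([[0.0, 1.0, 2.0, 3.0]])
        h = displacement_histogram(ens, lag_frames=1)
        assert h.statistic == "lag:1"
        assert int(np.sum(h.counts)) == 3


class TestGaussianFit:
    def test_fwhm_sigma_identity_on_exact_gaussian(self):
        h = gaussian_histogram(0.0, 1.0)
        fit = fit_gaussian(h)
        assert fit.fwhm == FWHM_FACTOR * fit.sigma  # exact identity
        assert fit.fwhm == pytest.approx(2.35482, abs=1e-4)
        assert fit.location == pytest.approx(0.0, abs=1e-9)
        assert fit.peak_area == pytest.approx(1.0, rel=1e-6)

    def test_recovery_from_seeded_samples(self):
        rng = np.random.Generator(np.random.PCG64(99))
        samples = rng.normal(0.5, 1.4, size=5000)
        fit = fit_gaussian(histogram_from_samples(samples))
        assert fit.location == pytest.approx(0.5, abs=0.1)
        assert fit.fwhm == pytest.approx(FWHM_FACTOR * 1.4, rel=0.05)

    def test_shift_equivariance(self):
        rng = np.random.Generator(np.random.PCG64(7))
        samples = rng.normal(0.0, 1.0, size=4000)
        f0 = fit_gaussian(histogram_from_samples(samples))
        f1 = fit_gaussian(histogram_from_samples(samples + 2.0))
        # shifting by a whole number of bins leaves the binning phase
        # unchanged; the grid extent (far-tail zero bins) may differ, so
        # equivariance is exact up to their negligible leverage on the fit
        assert f1.location - f0.location == pytest.approx(2.0, abs=1e-4)
        assert f1.fwhm == pytest.approx(f0.fwhm, abs=1e-4)

    def test_too_few_occupied_bins_rejected(self):
        ens = make_ensemble([[0.0, 1.1]] * 7)
        with pytest.raises(FitError, match="occupied"):
            fit_gaussian(displacement_histogram(ens))


class TestSubtractHistograms:
    def test_self_subtraction_is_zero_with_no_extrema(self, random_ensemble):
        h = displacement_histogram(random_ensemble)
        smap = subtract_histograms(h, h)
        np.testing.assert_array_equal(smap.difference, 0.0)
        assert smap.extrema == []

    def test_difference_integrates_to_zero(self, rng):
        a = histogram_from_samples(rng.normal(0, 1, 500))
        b = histogram_from_samples(rng.normal(0.5, 2, 800))
        smap = subtract_histograms(a, b)
        assert smap.integral() == pytest.approx(0.0, abs=1e-9)

    def test_broad_minus_narrow_gaussian_structure(self):
        # equal means: negative central extremum, positive flanks
        narrow = gaussian_histogram(0.0, 1.0, width=0.25)
        broad = gaussian_histogram(0.0, 2.0, width=0.25)
        smap = subtract_histograms(broad, narrow)
        center = [a for p, a in smap.extrema if abs(p) < 1.0]
        flanks = [a for p, a in smap.extrema if abs(p) >= 1.0]
        assert len(center) == 1 and center[0] < 0
        assert len(flanks) == 2 and all(a > 0 for a in flanks)
        positions = sorted(p for p, _ in smap.extrema)
        assert positions[0] < 0 < positions[2]

    def test_incompatible_bin_widths_rejected(self, rng):
        a = histogram_from_samples(rng.normal(0, 1, 300), bin_width=0.25)
        b = histogram_from_samples(rng.normal(0, 1, 300), bin_width=0.4)
        with pytest.raises(DataError, match="bin width"):
            subtract_histograms(a, b)

    def test_unnormalized_input_rejected(self, rng):
        h = histogram_from_samples(rng.normal(0, 1, 300))
        bad = AngularHistogram(
            bin_edges=h.bin_edges, density=h.density * 2.0,
            counts=h.counts, axis="chi", normalized=False,
        )
        with pytest.raises(DataError, match="normalized"):
            subtract_histograms(h, bad)

    def test_offset_grids_are_rebinned_conservatively(self):
        # same width, quarter-bin phase offset: rebinning must conserve mass
        w = 0.2
        edges_a = np.arange(-2.0, 2.0 + w / 2, w)
        edges_b = edges_a + 0.05
        ca = 0.5 * (edges_a[:-1] + edges_a[1:])
        cb = 0.5 * (edges_b[:-1] + edges_b[1:])
        da = np.exp(-(ca**2) / 2)
        da /= np.sum(da) * w
        db = np.exp(-(cb**2) / (2 * 1.5**2))
        db /= np.sum(db) * w
        ha = AngularHistogram(edges_a, da, np.zeros(len(da)), "chi", True)
        hb = AngularHistogram(edges_b, db, np.zeros(len(db)), "chi", True)
        smap = subtract_histograms(ha, hb)
        assert smap.integral() == pytest.approx(0.0, abs=1e-9)


class TestMirrorEquivariance:
    def test_full_directional_pipeline_mirrors(self):
        cfg = SimulationConfig(
            n_particles=300, drift_chi=0.15,
            theta_window_halfwidth=np.inf, n_frames=100, seed=23,
        )
        ens, _ = simulate_ensemble(cfg)
        ctrl_cfg = SimulationConfig(
            n_particles=300, theta_window_halfwidth=np.inf,
            n_frames=100, seed=24,
        )
        ctrl, _ = simulate_ensemble(ctrl_cfg)

        h_t, h_c = (displacement_histogram(e) for e in (ens, ctrl))
        hm_t, hm_c = (
            displacement_histogram(e.mirrored()) for e in (ens, ctrl)
        )
        smap = subtract_histograms(h_t, h_c)
        smap_m = subtract_histograms(hm_t, hm_c)
        np.testing.assert_array_equal(
            smap_m.difference, smap.difference[::-1]
        )
        np.testing.assert_allclose(
            smap_m.bin_edges, -smap.bin_edges[::-1]
        )
        for (p, a), (pm, am) in zip(
            sorted(smap.extrema), sorted(smap_m.extrema, reverse=True)
        ):
            assert pm == pytest.approx(-p, abs=1e-12)
            assert am == pytest.approx(a, abs=1e-12)
        # histogram/map stages are bitwise equivariant; the Gaussian fit
        # is equivariant to the optimizer's convergence tolerance
        fit = fit_gaussian(h_t)
        fit_m = fit_gaussian(hm_t)
        assert fit_m.location == pytest.approx(-fit.location, abs=1e-6)
        assert fit_m.fwhm == pytest.approx(fit.fwhm, abs=1e-6)
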