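"""Ground-truth generator and raw-data renderers."""

import numpy as np
import pytest

from layermet.config import ImagingConfig, NoiseParams, SimulationParams
from layermet.flim import decay_model, make_gaussian_irf
from layermet.redox import per_cell_ratio, redox_to_fluorescence
from layermet.synthetic import (
    build_true_traction,
    expected_flim_curve,
    render_bead_images,
    render_peredox_frames,
    render_uptake_images,
    simulate_monolayer,
    synthesize_flim_stack,
)


class TestSimulateMonolayer:
    def test_zero_velocity_freezes_positions(self):
        p = SimulationParams(domain_um=(300.0, 80.0), n_cells=60, n_frames=5,
                             front_x0_um=200.0, edge_speed_um_h=0.0,
                             bulk_speed_um_h=0.0)
        truth = simulate_monolayer(p, seed=0)
        for f in range(1, 5):
            np.testing.assert_allclose(truth.positions_by_frame[f],
                                       truth.positions_by_frame[0])

    def test_deterministic_under_seed(self):
        p = SimulationParams(domain_um=(300.0, 80.0), n_cells=60, n_frames=3)
        a = simulate_monolayer(p, seed=42)
        b = simulate_monolayer(p, seed=42)
        np.testing.assert_array_equal(a.positions_by_frame, b.positions_by_frame)
        np.testing.assert_array_equal(a.true_speeds, b.true_speeds)

    def test_front_advance_matches_prescribed_speed(self):
        """Front position advances by v*T (independent integration of the
        prescribed front motion)."""
        v = 24.0  # µm/h
        p = SimulationParams(domain_um=(800.0, 80.0), n_cells=60, n_frames=5,
                             front_x0_um=300.0, edge_speed_um_h=v)
        truth = simulate_monolayer(p, seed=1)
        T_h = (5 - 1) * 15.0 / 60.0
        advance = truth.front_position[-1] - truth.front_position[0]
        assert advance == pytest.approx(v * T_h, rel=1e-6)
        assert np.all(np.diff(truth.front_position) >= 0)

    def test_jammed_bulk_nearly_static(self, small_truth):
        """Bulk cells barely move relative to edge cells (jammed core,
        flowing margin)."""
        pos0 = small_truth.positions_by_frame[0]
        center = (small_truth.left_front_position[0]
                  + small_truth.front_position[0]) / 2
        disp = np.linalg.norm(
            small_truth.positions_by_frame[-1] - pos0, axis=1)
        bulk = np.abs(pos0[:, 0] - center) < 20.0
        edge = np.abs(pos0[:, 0] - center) > 0.8 * (
            small_truth.front_position[0] - center)
        assert disp[bulk].max() < 0.2 * disp[edge].mean()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_cells=0)
        with pytest.raises(ValueError):
            SimulationParams(domain_um=(-5.0, 10.0))
        with pytest.raises(ValueError):
            SimulationParams(tau1_ns=3.0, tau2_ns=1.0)


class TestRenderPeredox:
    def test_round_trip_single_cell_ratio(self, calib, imaging):
        p = SimulationParams(domain_um=(80.0, 80.0), n_cells=1, n_frames=1,
                             front_x0_um=60.0, edge_redox=120.0,
                             bulk_redox=120.0)
        truth = simulate_monolayer(p, seed=2)
        out = render_peredox_frames(truth, calib, imaging, NoiseParams(), seed=0)
        df = per_cell_ratio(out["red"][0], out["green"][0], out["labels"][0])
        expected = float(redox_to_fluorescence(120.0, calib))
        assert df["F_raw"].iloc[0] == pytest.approx(expected, rel=0.01)

    def test_equal_redox_equal_ratio(self, calib, imaging):
        p = SimulationParams(domain_um=(160.0, 60.0), n_cells=2, n_frames=1,
                             front_x0_um=120.0, edge_redox=200.0,
                             bulk_redox=200.0)
        truth = simulate_monolayer(p, seed=3)
        out = render_peredox_frames(truth, calib, imaging, NoiseParams(), seed=1)
        df = per_cell_ratio(out["red"][0], out["green"][0], out["labels"][0])
        assert len(df) == 2
        # expression amplitudes differ (log-normal) but ratios agree
        assert df["F_raw"].iloc[0] == pytest.approx(df["F_raw"].iloc[1], rel=0.01)
        assert df["mean_red"].iloc[0] != pytest.approx(
            df["mean_red"].iloc[1], rel=0.01)

    def test_seeded_render_reproducible(self, calib, imaging, small_truth):
        a = render_peredox_frames(small_truth, calib, imaging, NoiseParams(
            poisson=True), seed=9)
        b = render_peredox_frames(small_truth, calib, imaging, NoiseParams(
            poisson=True), seed=9)
        np.testing.assert_array_equal(a["red"], b["red"])
        np.testing.assert_array_equal(a["green"], b["green"])


class TestSynthesizeFlim:
    def test_expected_curve_total_equals_budget(self, imaging, small_truth):
        curve = expected_flim_curve(small_truth, imaging, x_um=300.0,
                                    photons_per_pixel=5000.0)
        assert curve.sum() == pytest.approx(5000.0)

    def test_single_exponential_limit(self, imaging):
        """With a delta IRF, no background, and alpha1 = 1 the expected
        histogram is proportional to exp(-t/tau1)."""
        p = SimulationParams(domain_um=(100.0, 50.0), n_cells=10, n_frames=1,
                             edge_alpha1=1.0, bulk_alpha1=1.0,
                             flim_background_frac=0.0)
        truth = simulate_monolayer(p, seed=4)
        irf = np.zeros(imaging.n_time_bins_raw)
        irf[0] = 1.0
        curve = expected_flim_curve(truth, imaging, x_um=50.0,
                                    photons_per_pixel=1.0, irf=irf)
        t = (np.arange(imaging.n_time_bins_raw) + 0.5) * imaging.time_bin_width_ns
        expected = np.exp(-t / p.tau1_ns)
        np.testing.assert_allclose(curve / curve[0], expected / expected[0],
                                   rtol=1e-9)

    def test_poisson_mean_matches_expectation(self, imaging, small_truth):
        """Mean of repeated Poisson draws tracks the expected curve
        within 3 standard errors per bin."""
        n_rep = 100
        stack = synthesize_flim_stack(
            small_truth, imaging, photons_per_pixel=2000.0, seed=5,
            shape=(n_rep, 1))
        # all rows share one expected curve (same x column)
        x = 0.5 * small_truth.params.domain_um[0] / 1
        expected = expected_flim_curve(small_truth, imaging, x_um=x,
                                       photons_per_pixel=2000.0)
        mean = stack.histograms[:, 0, :].mean(axis=0)
        se = np.sqrt(np.maximum(expected, 1e-9) / n_rep)
        frac_inside = np.mean(np.abs(mean - expected) <= 3 * se)
        assert frac_inside > 0.98

    def test_lifetime_ordering_enforced(self, imaging):
        with pytest.raises(ValueError):
            SimulationParams(tau1_ns=2.5, tau2_ns=0.4)

    def test_positive_budget_required(self, imaging, small_truth):
        with pytest.raises(ValueError):
            synthesize_flim_stack(small_truth, imaging, photons_per_pixel=0)


class TestTractionRendering:
    def test_true_traction_net_force_zero(self, small_truth):
        t, spacing = build_true_traction(small_truth, grid_n=48)
        assert np.abs(t.sum(axis=(0, 1))).max() < 1e-9 * np.abs(t).sum()

    def test_zero_displacement_identical_pair(self):
        u = np.zeros((16, 16, 2))
        out = render_bead_images(u, 10.0, (64, 64), 1.0, n_beads=200, seed=0)
        np.testing.assert_array_equal(out["reference"], out["deformed"])

    def test_seeded_reproducible(self):
        u = np.zeros((16, 16, 2))
        a = render_bead_images(u, 10.0, (64, 64), 1.0, n_beads=200, seed=3)
        b = render_bead_images(u, 10.0, (64, 64), 1.0, n_beads=200, seed=3)
        np.testing.assert_array_equal(a["reference"], b["reference"])
        np.testing.assert_array_equal(a["bead_positions_px"],
                                      b["bead_positions_px"])

    def test_ambiguous_displacement_warns(self):
        u = np.full((16, 16, 2), 50.0)  # huge displacement vs bead spacing
        with pytest.warns(UserWarning, match="ambiguous"):
            render_bead_images(u, 10.0, (64, 64), 1.0, n_beads=500, seed=1)


class TestUptakeRendering:
    def test_flat_profile_flat_trace(self, imaging, small_truth):
        out = render_uptake_images(small_truth, lambda x: np.full_like(x, 80.0),
                                   imaging)
        inside = out["image"][out["mask"]]
        assert inside.std() < 1e-9
        assert inside.mean() == pytest.approx(80.0)

    def test_mask_matches_layer_footprint(self, imaging, small_truth):
        out = render_uptake_images(small_truth, lambda x: np.full_like(x, 1.0),
                                   imaging)
        px = imaging.pixel_size_redox
        xs = (np.arange(out["mask"].shape[1]) + 0.5) * px
        expected = small_truth.in_layer(xs, frame=0)
        np.testing.assert_array_equal(out["mask"][0], expected)

    def test_step_profile_located_at_front(self, imaging, small_truth):
        """A step in the prescribed profile is recovered at the front
        position within one profile bin."""
        front = small_truth.front_position[0]
        step_at = front - 50.0
        out = render_uptake_images(
            small_truth, lambda x: np.where(x > step_at, 200.0, 50.0), imaging)
        px = imaging.pixel_size_redox
        col = out["image"].mean(axis=0)
        xs = (np.arange(col.size) + 0.5) * px
        in_layer = small_truth.in_layer(xs, frame=0)
        jump = np.nanargmax(np.abs(np.diff(np.where(in_layer, col, np.nan))))
        assert xs[jump] == pytest.approx(step_at, abs=2 * px)


class TestGradientOrdering:
    def test_prescribed_profiles_monotone_from_edge(self, small_truth):
        """Retrograde gradients: redox rises, alpha1 falls, tau_m rises
        moving from the front into the bulk."""
        front = small_truth.front_position[0]
        center = (front + small_truth.left_front_position[0]) / 2
        xs = np.linspace(center, front - 1.0, 30)
        redox = small_truth.redox_profile(xs)
        a1 = small_truth.alpha1_profile(xs)
        tau = small_truth.tau_m_profile(xs)
        assert np.all(np.diff(redox) < 0)      # falls toward the edge
        assert np.all(np.diff(a1) > 0)         # free NADH rises at edge
        assert np.all(np.diff(tau) < 0)        # tau_m shortens at edge
        assert np.all(np.diff(
            small_truth.traction_magnitude_profile(xs)) > 0)
        assert np.all(np.diff(small_truth.speed_profile(xs)) > 0)
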