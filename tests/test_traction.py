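"""Elastic forward/inverse operators and bead displacement measurement."""

import numpy as np
import pytest

from layermet.synthetic import _stamp_gaussians, render_bead_images
from layermet.traction import (
    GelProps,
    compute_tractions,
    forward_displacement,
    measure_bead_displacements,
    per_cell_traction,
)

GEL = GelProps(shear_modulus_pa=9600.0, poisson_ratio=0.5)


def smooth_random_traction(n=64, seed=0, amplitude=30.0):
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    t = ndimage.gaussian_filter(rng.standard_normal((n, n, 2)), (6, 6, 0))
    t *= amplitude / np.abs(t).max()
    t -= t.mean(axis=(0, 1))
    return t


def real_space_greens_displacement(tractions, spacing, gel):
    """Direct real-space summation of the tangential surface Green's
    tensor (Cerruti/Boussinesq) — independent O(n^2) oracle.

    G(r) = (1+nu)/(pi E r^3) [[(1-nu)r^2 + nu x^2, nu x y],
                              [nu x y, (1-nu)r^2 + nu y^2]]
    """
    nu = gel.poisson_ratio
    E = 2.0 * gel.shear_modulus_pa * (1.0 + nu)
    ny, nx = tractions.shape[:2]
    ys, xs = np.meshgrid(np.arange(ny) * spacing, np.arange(nx) * spacing,
                         indexing="ij")
    u = np.zeros_like(tractions)
    dA = spacing * spacing
    for i in range(ny):
        for j in range(nx):
            dx = xs - xs[i, j]
            dy = ys - ys[i, j]
            r = np.hypot(dx, dy)
            r[i, j] = 1.0  # placeholder; self-term zeroed below
            pref = (1.0 + nu) / (np.pi * E * r**3)
            pref[i, j] = 0.0  # exclude singular self-term
            gxx = pref * ((1 - nu) * r**2 + nu * dx**2)
            gyy = pref * ((1 - nu) * r**2 + nu * dy**2)
            gxy = pref * nu * dx * dy
            u[i, j, 0] = np.sum((gxx * tractions[..., 0] + gxy * tractions[..., 1])) * dA
            u[i, j, 1] = np.sum((gxy * tractions[..., 0] + gyy * tractions[..., 1])) * dA
    return u


class TestForwardOperator:
    def test_zero_traction_zero_displacement(self):
        u = forward_displacement(np.zeros((16, 16, 2)), 10.0, GEL)
        assert np.allclose(u, 0.0)

    def test_linearity(self):
        t = smooth_random_traction(32, seed=1)
        u1 = forward_displacement(t, 10.0, GEL)
        u2 = forward_displacement(2.0 * t, 10.0, GEL)
        np.testing.assert_allclose(u2, 2.0 * u1, rtol=1e-12)

    def test_localized_patch_against_real_space_oracle(self):
        """A compact traction patch: displacement decays with distance,
        aligns with the traction at the patch, and agrees with direct
        real-space Green's summation away from the patch."""
        n, sp = 48, 10.0
        t = np.zeros((n, n, 2))
        yy, xx = np.mgrid[0:n, 0:n]
        patch = np.exp(-(((xx - n / 2) ** 2 + (yy - n / 2) ** 2) / (2 * 2.0**2)))
        t[..., 0] = 50.0 * patch
        t[..., 0] -= t[..., 0].mean()  # self-equilibrate
        u = forward_displacement(t, sp, GEL)
        c = n // 2
        # direction at patch center aligns with traction (+x)
        assert u[c, c, 0] > 0
        assert abs(u[c, c, 1]) < 0.05 * abs(u[c, c, 0])
        # monotone decay along +x away from the patch
        profile = u[c, c + 2:c + 16, 0]
        assert np.all(np.diff(np.abs(profile)) < 0)
        # real-space oracle agreement in an annulus (periodic images and
        # the self-term make the very near/far fields differ)
        u_oracle = real_space_greens_displacement(t, sp, GEL)
        r = np.hypot(xx - c, yy - c)
        ring = (r > 3) & (r < 10)
        num = np.linalg.norm((u - u_oracle)[ring])
        den = np.linalg.norm(u_oracle[ring])
        assert num / den < 0.15


class TestInversion:
    def test_zero_displacement_zero_traction(self):
        t = compute_tractions(np.zeros((16, 16, 2)), 10.0, GEL)
        assert np.allclose(t, 0.0)

    def test_round_trip_noise_free(self):
        """forward -> invert at vanishing regularization: < 2% error."""
        t = smooth_random_traction(64, seed=2)
        u = forward_displacement(t, 10.0, GEL)
        t_rec = compute_tractions(u, 10.0, GEL, regularization=0.0)
        rel = np.linalg.norm(t_rec - t) / np.linalg.norm(t)
        assert rel < 0.02

    def test_net_force_balance(self):
        t = smooth_random_traction(64, seed=3)
        u = forward_displacement(t, 10.0, GEL)
        t_rec = compute_tractions(u, 10.0, GEL, regularization=1e-3)
        net = np.abs(t_rec.sum(axis=(0, 1))).sum()
        total = np.abs(t_rec).sum()
        assert net / total < 0.01

    def test_regularization_monotonically_damps_power(self):
        t = smooth_random_traction(32, seed=4)
        u = forward_displacement(t, 10.0, GEL)
        powers = [np.sum(compute_tractions(u, 10.0, GEL, regularization=r) ** 2)
                  for r in (0.0, 1e-3, 1e-2, 1e-1, 1.0)]
        assert np.all(np.diff(powers) <= 1e-9)

    def test_axis_swap_equivariance(self):
        """The isotropic operator commutes with the x<->y reflection:
        transposing the grid and swapping vector components maps the
        forward solution accordingly."""
        t = smooth_random_traction(32, seed=5)
        u = forward_displacement(t, 10.0, GEL)
        t_swap = np.swapaxes(t, 0, 1)[..., ::-1].copy()
        u_swap = forward_displacement(t_swap, 10.0, GEL)
        u_expected = np.swapaxes(u, 0, 1)[..., ::-1]
        np.testing.assert_allclose(u_swap, u_expected, atol=1e-12)

    def test_two_patches_resolved(self):
        """Patches > 4 grid spacings apart reappear as distinct maxima."""
        n, sp = 64, 10.0
        yy, xx = np.mgrid[0:n, 0:n]
        t = np.zeros((n, n, 2))
        for cx in (24, 40):  # 16 spacings apart
            t[..., 0] += 40.0 * np.exp(
                -(((xx - cx) ** 2 + (yy - 32) ** 2) / (2 * 1.5**2)))
        t[..., 0] -= t[..., 0].mean()
        u = forward_displacement(t, sp, GEL)
        t_rec = compute_tractions(u, sp, GEL, regularization=1e-3)
        row = t_rec[32, :, 0]
        peaks = [i for i in range(1, n - 1) if row[i] > row[i - 1]
                 and row[i] > row[i + 1] and row[i] > 0.3 * row.max()]
        assert len(peaks) == 2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_tractions(np.zeros((8, 8, 2)), 0.0, GEL)
        bad = np.zeros((8, 8, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            compute_tractions(bad, 10.0, GEL)


class TestBeadDisplacements:
    def test_identical_pair_zero_field(self):
        rng = np.random.default_rng(0)
        img = _stamp_gaussians((96, 96), rng.uniform(0, 96, (400, 2)),
                               np.full(400, 100.0), 1.2)
        _, _, disp = measure_bead_displacements(img, img, window_px=32,
                                                register=False)
        assert np.nanmax(np.abs(disp)) < 1e-6

    def test_uniform_shift_recovered(self):
        rng = np.random.default_rng(1)
        beads = np.column_stack([rng.uniform(0, 256, 1500),
                                 rng.uniform(0, 256, 1500)])
        amp = np.full(1500, 120.0)
        ref = _stamp_gaussians((256, 256), beads, amp, 1.2)
        defo = _stamp_gaussians((256, 256), beads + np.array([1.5, 0.0]), amp, 1.2)
        _, _, disp = measure_bead_displacements(defo, ref, window_px=32,
                                                register=False)
        assert np.nanmean(disp[..., 0]) == pytest.approx(1.5, abs=0.05)
        assert np.nanmean(disp[..., 1]) == pytest.approx(0.0, abs=0.05)

    def test_stage_drift_removed_by_registration(self):
        """A rigid stage shift between acquisitions is estimated on the
        full field and removed; the recovered deformation is zero."""
        rng = np.random.default_rng(2)
        beads = np.column_stack([rng.uniform(0, 192, 900),
                                 rng.uniform(0, 192, 900)])
        amp = np.full(900, 120.0)
        ref = _stamp_gaussians((192, 192), beads, amp, 1.2)
        drifted = _stamp_gaussians((192, 192), beads + np.array([2.0, 1.0]),
                                   amp, 1.2)
        _, _, disp = measure_bead_displacements(drifted, ref, window_px=32,
                                                register=True)
        assert np.nanmax(np.abs(np.nanmean(disp, axis=(0, 1)))) < 0.1

    def test_synthetic_field_rms_error(self):
        """Bead pair rendered from a known smooth displacement field is
        recovered with RMS error < 0.1 px."""
        from scipy.interpolate import RegularGridInterpolator

        t = smooth_random_traction(32, seed=6, amplitude=60.0)
        sp = 8.0
        u = forward_displacement(t, sp, GEL)
        px = 1.0
        pair = render_bead_images(u, sp, (256, 256), px, n_beads=1500, seed=3)
        gy, gx, disp = measure_bead_displacements(
            pair["deformed"], pair["reference"], window_px=32, register=False)
        gc = (np.arange(32) + 0.5) * sp
        itp = RegularGridInterpolator((gc, gc), u, bounds_error=False,
                                      fill_value=None)
        pts = np.stack(np.meshgrid(gy * px, gx * px, indexing="ij"), axis=-1)
        u_true_px = itp(pts.reshape(-1, 2)).reshape(disp.shape) / px
        resid = disp - u_true_px  # both ordered (dx, dy)
        rms = np.sqrt(np.nanmean(resid**2))
        assert rms < 0.1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            measure_bead_displacements(np.zeros((32, 32)), np.zeros((32, 16)))


class TestPerCellTraction:
    def test_uniform_field(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[10:20, 10:20] = 1
        tm = np.full((8, 8), 50.0)
        df = per_cell_traction(tm, 5.0, labels, 1.0)
        assert df.loc[0, "mean_traction_pa"] == pytest.approx(50.0)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        labels = np.zeros((40, 40), dtype=int)
        labels[5:15, 5:15] = 1
        labels[22:30, 20:32] = 2
        tm = rng.uniform(10, 90, (8, 8))
        base = per_cell_traction(tm, 5.0, labels, 1.0)["mean_traction_pa"].values
        double = per_cell_traction(2 * tm, 5.0, labels, 1.0)["mean_traction_pa"].values
        np.testing.assert_allclose(double, 2 * base, rtol=1e-12)

    def test_small_footprint_flagged(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[0, 0] = 1  # single pixel << one traction grid cell
        df = per_cell_traction(np.full((8, 8), 10.0), 5.0, labels, 1.0)
        assert df.loc[0, "qc_flag"] == "undersampled"
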