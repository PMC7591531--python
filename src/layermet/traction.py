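"""Traction force microscopy: bead displacements -> substrate tractions.

Cell-substrate tractions are recovered from the displacement of fiducial
beads embedded just below the gel surface, comparing the stressed image
(cells attached) against the relaxed image (after trypsinization).
Displacements are measured by windowed cross-correlation with sub-pixel
peak localization; tractions follow from Tikhonov-regularized inversion
of the elastic half-space (Boussinesq) Green's operator in Fourier
space.  The gel (shear modulus 9.6 kPa, thickness 100 µm) is treated as
a semi-infinite incompressible half-space: at cellular wavelengths the
displacement field decays well within the gel thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.fft import fft2, ifft2, fftfreq
from scipy.interpolate import RegularGridInterpolator, griddata

from ._correlation import subpixel_shift


@dataclass
class GelProps:
    """Elastic substrate parameters."""

    shear_modulus_pa: float = 9600.0
    poisson_ratio: float = 0.5
    thickness_um: float = 100.0


@dataclass
class TractionField:
    """Congruent displacement and traction fields on a regular grid."""

    spacing_um: float
    displacements_um: np.ndarray     # (ny, nx, 2) -> (ux, uy)
    tractions_pa: np.ndarray | None  # (ny, nx, 2) -> (tx, ty)
    gel: GelProps
    regularization: float = 0.0

    @property
    def traction_magnitude(self) -> np.ndarray:
        if self.tractions_pa is None:
            raise ValueError("tractions not yet computed")
        return np.linalg.norm(self.tractions_pa, axis=-1)


def _greens_components(shape: tuple[int, int], spacing_um: float, gel: GelProps):
    """Fourier-space Boussinesq surface Green's tensor components.

    For wavevector k the surface displacement responds to surface
    traction as u(k) = G(k) t(k) with

        G(k) = 1/(mu k^3) * [[(1-nu)k^2 + nu ky^2,  -nu kx ky],
                             [-nu kx ky,            (1-nu)k^2 + nu kx^2]]

    (mu shear modulus, nu Poisson ratio).  The k=0 mode is excluded —
    a zero-mean traction field determines displacements only up to a
    rigid shift, pinned to zero mean here.
    """
    ny, nx = shape
    kx = 2 * np.pi * fftfreq(nx, d=spacing_um)
    ky = 2 * np.pi * fftfreq(ny, d=spacing_um)
    KX, KY = np.meshgrid(kx, ky)
    k = np.hypot(KX, KY)
    k_safe = np.where(k == 0, 1.0, k)
    mu, nu = gel.shear_modulus_pa, gel.poisson_ratio
    pref = 1.0 / (mu * k_safe**3)
    gxx = pref * ((1 - nu) * k_safe**2 + nu * KY**2)
    gyy = pref * ((1 - nu) * k_safe**2 + nu * KX**2)
    gxy = pref * (-nu * KX * KY)
    zero = k == 0
    for g in (gxx, gyy, gxy):
        g[zero] = 0.0
    return gxx, gyy, gxy


def forward_displacement(
    tractions_pa: np.ndarray,
    spacing_um: float,
    gel: GelProps,
) -> np.ndarray:
    """Surface displacement field generated by a gridded traction field.

    Linear in the traction; the (zero-mean) rigid mode is dropped, so
    the input should carry zero net force over the full domain.
    """
    t = np.asarray(tractions_pa, dtype=float)
    if t.ndim != 3 or t.shape[-1] != 2:
        raise ValueError("tractions must have shape (ny, nx, 2)")
    if spacing_um <= 0:
        raise ValueError("grid spacing must be positive and equal in x and y")
    gxx, gyy, gxy = _greens_components(t.shape[:2], spacing_um, gel)
    tx_hat, ty_hat = fft2(t[..., 0]), fft2(t[..., 1])
    ux = ifft2(gxx * tx_hat + gxy * ty_hat).real
    uy = ifft2(gxy * tx_hat + gyy * ty_hat).real
    return np.stack([ux, uy], axis=-1)


def compute_tractions(
    displacements_um: np.ndarray,
    spacing_um: float,
    gel: GelProps,
    regularization: float = 0.0,
) -> np.ndarray:
    """Invert displacements for tractions (regularized FTTC).

    Solves, independently per wavevector, the 2x2 Tikhonov system

        (G^T G + lambda^2 I) t = G^T u

    where ``lambda = regularization * max|G|`` (the dimensionless
    ``regularization`` scales the penalty relative to the softest,
    longest-wavelength modes).  At ``regularization=0`` this is the exact
    inverse of :func:`forward_displacement` on the non-rigid modes.
    """
    u = np.asarray(displacements_um, dtype=float)
    if u.ndim != 3 or u.shape[-1] != 2:
        raise ValueError("displacements must have shape (ny, nx, 2)")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field contains non-finite values")
    if spacing_um <= 0:
        raise ValueError("grid spacing must be positive")
    gxx, gyy, gxy = _greens_components(u.shape[:2], spacing_um, gel)
    lam2 = (regularization * max(np.max(np.abs(gxx)), np.max(np.abs(gyy)), 1e-300)) ** 2
    ux_hat, uy_hat = fft2(u[..., 0]), fft2(u[..., 1])
    # normal equations for symmetric real G, per wavevector
    a = gxx * gxx + gxy * gxy + lam2
    b = gxy * (gxx + gyy)
    c = gxy * gxy + gyy * gyy + lam2
    rx = gxx * ux_hat + gxy * uy_hat
    ry = gxy * ux_hat + gyy * uy_hat
    det = a * c - b * b
    det = np.where(np.abs(det) < 1e-300, 1.0, det)
    tx_hat = (c * rx - b * ry) / det
    ty_hat = (a * ry - b * rx) / det
    tx_hat.flat[0] = 0.0
    ty_hat.flat[0] = 0.0
    return np.stack([ifft2(tx_hat).real, ifft2(ty_hat).real], axis=-1)


def measure_bead_displacements(
    image_stressed: np.ndarray,
    image_relaxed: np.ndarray,
    window_px: int = 32,
    overlap: float = 0.5,
    register: bool = True,
    min_quality: float = 0.6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gridded sub-pixel bead displacements, relaxed -> stressed.

    Windowed cross-correlation (overlap-normalized, parabolic sub-pixel
    peak) with 50% window overlap by default.  When ``register`` is
    set, a whole-field rigid shift (stage positioning error) is
    estimated first and removed.  Windows whose peak correlation falls
    below ``min_quality`` (decorrelated or near-empty) are masked and
    filled by nearest-neighbor interpolation from valid windows.

    Returns ``(grid_y, grid_x, displacements)`` with window-center
    coordinates in pixels and displacements of shape (ny, nx, 2) in
    pixels, ordered (dx, dy).
    """
    a = np.asarray(image_stressed, dtype=float)
    b = np.asarray(image_relaxed, dtype=float)
    if a.shape != b.shape:
        raise ValueError("image pair must share a shape")
    if register:
        drift, _ = subpixel_shift(b, a)   # rigid stage shift relaxed -> stressed
        a = ndimage.shift(a, -drift, order=1, mode="nearest")
    step = max(int(window_px * (1 - overlap)), 1)
    ys = np.arange(0, a.shape[0] - window_px + 1, step)
    xs = np.arange(0, a.shape[1] - window_px + 1, step)
    disp = np.full((len(ys), len(xs), 2), np.nan)
    valid = np.zeros((len(ys), len(xs)), dtype=bool)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            wa = a[y0:y0 + window_px, x0:x0 + window_px]
            wb = b[y0:y0 + window_px, x0:x0 + window_px]
            # displacement of the stressed content relative to relaxed
            shift, quality = subpixel_shift(wb, wa)
            if quality < min_quality:
                continue
            disp[i, j] = [shift[1], shift[0]]
            valid[i, j] = True
    if valid.any() and not valid.all():
        gy, gx = np.meshgrid(ys + window_px / 2, xs + window_px / 2, indexing="ij")
        pts = np.column_stack([gy[valid], gx[valid]])
        for c in range(2):
            disp[~valid, c] = griddata(
                pts, disp[valid, c], (gy[~valid], gx[~valid]), method="nearest")
    return ys + window_px / 2, xs + window_px / 2, disp


def per_cell_traction(
    traction_magnitude_pa: np.ndarray,
    grid_spacing_um: float,
    label_image: np.ndarray,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Mean traction magnitude under each labeled cell footprint.

    The traction grid (spacing ``grid_spacing_um``, origin at half a
    grid cell) is linearly interpolated onto image pixels, then averaged
    over each label.  Footprints smaller than one traction grid cell are
    flagged ``undersampled``.
    """
    tm = np.asarray(traction_magnitude_pa, dtype=float)
    gy = (np.arange(tm.shape[0]) + 0.5) * grid_spacing_um
    gx = (np.arange(tm.shape[1]) + 0.5) * grid_spacing_um
    interp = RegularGridInterpolator((gy, gx), tm, bounds_error=False, fill_value=None)
    ny, nx = label_image.shape
    py = (np.arange(ny) + 0.5) * pixel_size_um
    px = (np.arange(nx) + 0.5) * pixel_size_um
    PY, PX = np.meshgrid(py, px, indexing="ij")
    tm_px = interp(np.stack([PY.ravel(), PX.ravel()], axis=-1)).reshape(ny, nx)
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    means = ndimage.mean(tm_px, labels=label_image, index=labels)
    counts = ndimage.sum(np.ones_like(tm_px), labels=label_image, index=labels)
    area_um2 = counts * pixel_size_um**2
    under = area_um2 < grid_spacing_um**2
    return pd.DataFrame({
        "label": labels.astype(int),
        "mean_traction_pa": means,
        "footprint_um2": area_um2,
        "qc_flag": np.where(under, "undersampled", ""),
    })
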