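"""Layer-aligned composite maps and x-profile traces.

Per-cell quantities are linearly interpolated onto a regular grid
(35 px ≈ 11 µm at the widefield pixel size, matching typical cell
spacing in the dense layer), layers are aligned by their center of
mass, averaged pixel-by-pixel, and collapsed along y into x-bins of
~260 µm.  Each imaged strip spans two advancing fronts; the two halves
are split at the layer center and mirrored so every front advances
toward +x.  Error bars are the layer-to-layer standard deviation of the
per-layer bin means.  Peredox data are composited in fluorescence-ratio
units and converted to NAD+/NADH only afterwards (the nonlinear
conversion does not commute with averaging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import griddata

from .config import ProfileConfig
from .redox import CalibrationModel, fluorescence_to_redox, propagate_error


@dataclass
class LayerProfile:
    """x-binned trace of one quantity with layer-to-layer dispersion."""

    x_centers: np.ndarray       # µm, relative to layer center, front toward +x
    mean: np.ndarray
    sd: np.ndarray              # layer-to-layer SD of per-layer bin means
    n_layers: np.ndarray
    quantity_name: str = ""


def grid_cell_values(
    positions_um: np.ndarray,
    values: np.ndarray,
    grid_spacing_um: float,
    domain_um: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate scattered per-cell values onto a regular grid.

    Grid nodes outside the convex hull of the cells are NaN (missing).
    Returns ``(grid_x, grid_y, field)`` with ``field`` shaped (ny, nx).
    """
    pos = np.asarray(positions_um, dtype=float)
    vals = np.asarray(values, dtype=float)
    if len(pos) < 3:
        raise ValueError("need at least 3 cells to grid")
    gx = np.arange(grid_spacing_um / 2, domain_um[0], grid_spacing_um)
    gy = np.arange(grid_spacing_um / 2, domain_um[1], grid_spacing_um)
    GX, GY = np.meshgrid(gx, gy)
    ok = np.isfinite(vals)
    field = griddata(pos[ok], vals[ok], (GX, GY), method="linear")
    if not np.any(np.isfinite(field)):
        raise ValueError("gridding produced an all-missing field")
    return gx, gy, field


def layer_center(positions_or_mask, pixel_size_um: float | None = None) -> float:
    """Center of mass of the layer along x (µm).

    Cell mode: mean x of an (n, 2) position array.  Mask mode: mean x of
    the True pixels of a 2D boolean mask (requires ``pixel_size_um``).
    """
    arr = np.asarray(positions_or_mask)
    if arr.ndim == 2 and arr.dtype != bool and arr.shape[1] == 2:
        if arr.size == 0:
            raise ValueError("no cell positions supplied")
        return float(arr[:, 0].mean())
    mask = arr.astype(bool)
    if not mask.any():
        raise ValueError("empty layer mask")
    if pixel_size_um is None:
        raise ValueError("mask mode requires pixel_size_um")
    xs = np.nonzero(mask)[1]
    return float((xs.mean() + 0.5) * pixel_size_um)


def split_and_orient_fronts(
    grid_x_um: np.ndarray,
    field: np.ndarray,
    center_um: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a strip field at the layer center into two +x-oriented layers.

    Each imaged strip crosses the layer edge-to-edge and therefore holds
    two advancing fronts; both halves are returned with x measured from
    the layer center and the front toward +x (the left half is
    mirrored).  Output: list of ``(x_rel_um, half_field)``.
    """
    gx = np.asarray(grid_x_um, dtype=float)
    if not gx[0] <= center_um <= gx[-1]:
        raise ValueError("layer center lies outside the strip")
    right_sel = gx >= center_um
    left_sel = gx <= center_um
    halves = []
    x_right = gx[right_sel] - center_um
    halves.append((x_right, field[..., right_sel]))
    x_left = (center_um - gx[left_sel])[::-1]
    halves.append((x_left, field[..., left_sel][..., ::-1]))
    return halves


def composite(
    layers: list[tuple[np.ndarray, np.ndarray]],
    config: ProfileConfig | None = None,
    grid_spacing_um: float | None = None,
    quantity_name: str = "",
) -> tuple[np.ndarray, np.ndarray, LayerProfile]:
    """Average aligned layers pixel-wise and bin the trace along x.

    Layers (already aligned: x relative to their centers, fronts toward
    +x) are resampled onto a common grid by nearest-node shift (offsets
    are multiples of the grid spacing by construction, so no
    interpolation smoothing occurs), averaged ignoring missing pixels,
    then collapsed over y and binned in ~260 µm x-bins.  The trace SD is
    the dispersion of per-layer bin means; bins with fewer than
    ``min_layers_for_sd`` contributing layers report NaN SD.
    """
    config = config or ProfileConfig()
    if not layers:
        raise ValueError("no layers to composite")
    if grid_spacing_um is None:
        xa = layers[0][0]
        grid_spacing_um = float(np.median(np.diff(xa))) if len(xa) > 1 else 1.0
    x_max = max(l[0][-1] for l in layers)
    nx = int(np.floor(x_max / grid_spacing_um)) + 1
    common_x = np.arange(nx) * grid_spacing_um + layers[0][0][0] % grid_spacing_um
    # per-layer y-collapsed traces on the common x-axis
    aligned_fields = []
    for x, fld in layers:
        f2 = np.atleast_2d(fld)
        out = np.full((f2.shape[0], nx), np.nan)
        idx = np.rint((x - common_x[0]) / grid_spacing_um).astype(int)
        ok = (idx >= 0) & (idx < nx)
        out[:, idx[ok]] = f2[:, ok]
        aligned_fields.append(out)
    import warnings as _warnings

    stack = np.stack(aligned_fields)             # (n_layers, ny, nx)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        mean_map = np.nanmean(stack, axis=0)

    # x-binned trace from per-layer means
    edges = np.arange(common_x[0] - grid_spacing_um / 2,
                      common_x[-1] + config.x_bin_um + grid_spacing_um,
                      config.x_bin_um)
    bin_idx = np.digitize(common_x, edges) - 1
    n_bins = bin_idx.max() + 1
    per_layer_binmeans = np.full((len(layers), n_bins), np.nan)
    for li, fld in enumerate(aligned_fields):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            col = np.nanmean(fld, axis=0) if fld.shape[0] > 1 else fld[0]
        for b in range(n_bins):
            sel = bin_idx == b
            vals = col[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                per_layer_binmeans[li, b] = vals.mean()
    n_layers = np.sum(np.isfinite(per_layer_binmeans), axis=0)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_trace = np.nanmean(per_layer_binmeans, axis=0)
        sd_trace = np.nanstd(per_layer_binmeans, axis=0, ddof=1)
    sd_trace = np.where(n_layers >= config.min_layers_for_sd, sd_trace, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])[:n_bins]
    keep = n_layers > 0
    profile = LayerProfile(
        x_centers=centers[keep], mean=mean_trace[keep], sd=sd_trace[keep],
        n_layers=n_layers[keep], quantity_name=quantity_name)
    return common_x, mean_map, profile


def normalize_uptake_by_area(
    intensity_profile: LayerProfile,
    area_profile: LayerProfile,
    reference_intensity: float,
    reference_area: float,
) -> LayerProfile:
    """Per-cell uptake index: intensity × cell area, doubly normalized.

    Fluorescence uptake images report signal per unit substrate area; a
    region of larger cells at the same per-area intensity has more
    uptake per cell.  The index is
    ``(I / I_ref) * (area / area_ref)``, with the reference taken at the
    center of the confined (pre-release) layer so the index is 1 there
    by construction.  Bins missing either input are missing.
    """
    if reference_intensity <= 0 or reference_area <= 0:
        raise ValueError("reference values must be positive")
    if intensity_profile.x_centers.shape != area_profile.x_centers.shape or \
            not np.allclose(intensity_profile.x_centers, area_profile.x_centers):
        raise ValueError("intensity and area profiles must share bins")
    area_rel = area_profile.mean / reference_area
    mean = (intensity_profile.mean / reference_intensity) * area_rel
    with np.errstate(invalid="ignore"):
        sd = (intensity_profile.sd / reference_intensity) * np.abs(area_rel)
    mean = np.where(area_profile.mean > 0, mean, np.nan)
    return LayerProfile(
        x_centers=intensity_profile.x_centers.copy(), mean=mean, sd=sd,
        n_layers=np.minimum(intensity_profile.n_layers, area_profile.n_layers),
        quantity_name="uptake_per_cell")


def transform_profile_to_redox(
    profile: LayerProfile,
    model: CalibrationModel,
) -> pd.DataFrame:
    """Convert a composited fluorescence-ratio trace to NAD+/NADH.

    Applied bin-wise *after* compositing (composite first, convert
    second; the nonlinear conversion and the average do not commute).
    The symmetric fluorescence SD maps to asymmetric redox bounds.
    """
    ok = np.isfinite(profile.mean)
    redox = np.full_like(profile.mean, np.nan)
    lo = np.full_like(profile.mean, np.nan)
    hi = np.full_like(profile.mean, np.nan)
    sd = np.where(np.isfinite(profile.sd), profile.sd, 0.0)
    if ok.any():
        r, l, h = propagate_error(profile.mean[ok], sd[ok], model)
        redox[ok], lo[ok], hi[ok] = r, l, h
    return pd.DataFrame({
        "x_center_um": profile.x_centers,
        "redox_mean": redox,
        "redox_lo": lo,
        "redox_hi": hi,
        "n_layers": profile.n_layers,
    })


def profile_table(profile: LayerProfile) -> pd.DataFrame:
    """Tidy CSV-ready table of a trace."""
    return pd.DataFrame({
        "quantity": profile.quantity_name,
        "x_center_um": profile.x_centers,
        "mean": profile.mean,
        "sd": profile.sd,
        "n_layers": profile.n_layers,
    })
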