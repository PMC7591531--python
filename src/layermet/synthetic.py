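"""Synthetic expanding-monolayer generator with known ground truth.

Emulates the imaging experiment end to end: a confluent epithelial
strip, initially confined, expands symmetrically about its center with
two advancing fronts.  Prescribed edge-vs-bulk gradients (speed, Voronoi
aspect ratio, NAD+/NADH, NADH lifetime composition, traction) decay
exponentially with distance from the nearer front, creating the
retrograde patterns the analysis pipeline must resolve.  Every raw
input the pipeline consumes can be rendered from the ground truth —
two-channel Peredox nucleus images, bead image pairs consistent with a
prescribed traction field, Poisson-noise TCSPC decay stacks, and
uptake/dye images — so each downstream stage has an exact oracle.

This is a phenomenological emulation (prescribed velocity field, 2D
Gaussian nuclei), not a mechanistic jamming model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ImagingConfig, NoiseParams, SimulationParams
from .flim import FlimStack, make_gaussian_irf
from .redox import CalibrationModel, redox_to_fluorescence
from .traction import GelProps, forward_displacement


@dataclass
class MonolayerGroundTruth:
    """Prescribed monolayer state: positions, gradients, and fields.

    The layer occupies ``[left_front, right_front]`` in x and the full
    domain in y.  Gradient profiles are evaluated by distance to the
    nearer front; ``front_position`` tracks the right (+x oriented)
    front and is non-decreasing.
    """

    params: SimulationParams
    cell_ids: np.ndarray
    positions_by_frame: np.ndarray      # (n_frames, n_cells, 2), µm
    true_speeds: np.ndarray             # µm/h per cell
    front_position: np.ndarray          # right-front x per frame, µm
    left_front_position: np.ndarray     # left-front x per frame, µm
    rng_seed: int
    frame_interval_min: float = 15.0
    true_traction: np.ndarray | None = None     # (ng, ng, 2) Pa
    traction_spacing_um: float | None = None

    def _edge_distance(self, x: np.ndarray, frame: int = 0) -> np.ndarray:
        """Distance to the nearer advancing front (µm, >=0 inside)."""
        return np.minimum(self.front_position[frame] - x,
                          x - self.left_front_position[frame])

    def redox_profile(self, x: np.ndarray, frame: int = 0) -> np.ndarray:
        p = self.params
        d = np.clip(self._edge_distance(x, frame), 0.0, None)
        return p.bulk_redox + (p.edge_redox - p.bulk_redox) * np.exp(-d / p.redox_decay_um)

    def alpha1_profile(self, x: np.ndarray, frame: int = 0) -> np.ndarray:
        p = self.params
        d = np.clip(self._edge_distance(x, frame), 0.0, None)
        return p.bulk_alpha1 + (p.edge_alpha1 - p.bulk_alpha1) * np.exp(-d / p.redox_decay_um)

    def tau_m_profile(self, x: np.ndarray, frame: int = 0) -> np.ndarray:
        a1 = self.alpha1_profile(x, frame)
        return a1 * self.params.tau1_ns + (1 - a1) * self.params.tau2_ns

    def speed_profile(self, x: np.ndarray, frame: int = 0) -> np.ndarray:
        """Prescribed |v| (µm/h) at position x."""
        p = self.params
        right = np.clip(self.front_position[frame] - x, 0, None)
        left = np.clip(x - self.left_front_position[frame], 0, None)
        v = np.abs(np.exp(-right / p.speed_decay_um) - np.exp(-left / p.speed_decay_um))
        return p.bulk_speed_um_h + (p.edge_speed_um_h - p.bulk_speed_um_h) * v

    def traction_magnitude_profile(self, x: np.ndarray, frame: int = 0) -> np.ndarray:
        p = self.params
        right = np.clip(self.front_position[frame] - x, 0, None)
        left = np.clip(x - self.left_front_position[frame], 0, None)
        tx = (p.bulk_traction_pa
              + (p.edge_traction_pa - p.bulk_traction_pa)
              * np.abs(np.exp(-right / p.traction_decay_um)
                       - np.exp(-left / p.traction_decay_um)))
        return tx

    def in_layer(self, x: np.ndarray, frame: int = 0) -> np.ndarray:
        return (x >= self.left_front_position[frame]) & (x <= self.front_position[frame])


def _velocity_x(x, left, right, p: SimulationParams):
    """Signed x-velocity (µm/h): outward toward the nearer front."""
    vr = np.exp(-np.clip(right - x, 0, None) / p.speed_decay_um)
    vl = np.exp(-np.clip(x - left, 0, None) / p.speed_decay_um)
    return (p.edge_speed_um_h - p.bulk_speed_um_h) * (vr - vl)


def simulate_monolayer(params: SimulationParams, seed: int = 0) -> MonolayerGroundTruth:
    """Generate ground-truth positions and fields for an expanding strip.

    Cells sit on a jittered lattice whose column spacing is stretched by
    the prescribed aspect-ratio profile (so the Voronoi tessellation of
    the centroids carries the elongation gradient).  Per frame, cells
    are advected by the prescribed front-relative velocity field; both
    fronts advance at the edge speed.  Deterministic given ``seed``.
    """
    p = params
    rng = np.random.default_rng(seed)
    Lx, Ly = p.domain_um
    dt_h = 0.25  # integration step, hours

    # initial layer bounds: strip centered in the domain, width front_x0
    half = min(p.front_x0_um, Lx * 0.8) / 2.0
    cx = Lx / 2.0
    left0, right0 = cx - half, cx + half

    # --- seed positions: aspect-stretched columns ---------------------
    area_per_cell = (right0 - left0) * Ly / p.n_cells
    base = np.sqrt(area_per_cell)
    # accumulate column positions with local spacing ~ base*sqrt(aspect)
    cols = [left0 + base / 2]
    while cols[-1] < right0 - base / 2:
        x = cols[-1]
        d = min(right0 - x, x - left0)
        aspect = p.bulk_aspect + (p.edge_aspect - p.bulk_aspect) * np.exp(
            -max(d, 0.0) / p.redox_decay_um)
        dy = base / np.sqrt(aspect)          # row spacing shrinks at edge
        dx = base * np.sqrt(aspect)          # column spacing grows at edge
        cols.append(x + dx)
    positions = []
    for x in cols:
        d = min(right0 - x, x - left0)
        aspect = p.bulk_aspect + (p.edge_aspect - p.bulk_aspect) * np.exp(
            -max(d, 0.0) / p.redox_decay_um)
        dy = base / np.sqrt(aspect)
        ys = np.arange(dy / 2, Ly, dy)
        for y in ys:
            positions.append((x, y))
    pos0 = np.array(positions)
    if len(pos0) > p.n_cells:
        keep = rng.choice(len(pos0), size=p.n_cells, replace=False)
        pos0 = pos0[np.sort(keep)]
    pos0 = pos0 + rng.normal(0, 0.08 * base, size=pos0.shape)
    pos0[:, 0] = np.clip(pos0[:, 0], left0 + 1e-3, right0 - 1e-3)
    pos0[:, 1] = np.clip(pos0[:, 1], 1e-3, Ly - 1e-3)
    n = len(pos0)

    # --- advect -------------------------------------------------------
    frame_interval_h = 15.0 / 60.0
    frames = [pos0.copy()]
    lefts, rights = [left0], [right0]
    pos = pos0.copy()
    left, right = left0, right0
    for _ in range(p.n_frames - 1):
        t = 0.0
        while t < frame_interval_h - 1e-12:
            step = min(dt_h, frame_interval_h - t)
            vx = _velocity_x(pos[:, 0], left, right, p)
            pos[:, 0] += vx * step
            left -= p.edge_speed_um_h * step
            right += p.edge_speed_um_h * step
            t += step
        left = max(left, 1e-3)
        right = min(right, Lx - 1e-3)
        pos[:, 0] = np.clip(pos[:, 0], left, right)
        frames.append(pos.copy())
        lefts.append(left)
        rights.append(right)
    frames = np.array(frames)

    if p.n_frames > 1:
        deltas = np.linalg.norm(np.diff(frames, axis=0), axis=-1)  # (nf-1, n)
        speeds = deltas.mean(axis=0) / frame_interval_h
    else:
        speeds = np.zeros(n)

    truth = MonolayerGroundTruth(
        params=p,
        cell_ids=np.arange(1, n + 1),
        positions_by_frame=frames,
        true_speeds=speeds,
        front_position=np.array(rights),
        left_front_position=np.array(lefts),
        rng_seed=seed,
    )
    return truth


def build_true_traction(
    truth: MonolayerGroundTruth,
    grid_n: int = 64,
    frame: int = 0,
) -> tuple[np.ndarray, float]:
    """Prescribed self-equilibrated traction field on a regular grid.

    The grid has ``grid_n`` columns across the domain width and square
    cells (row count follows the domain aspect).  Tractions point
    inward (cells pull the substrate toward the layer center), with
    magnitude elevated at both fronts and decaying into the bulk;
    mirror symmetry about the layer center makes the net force vanish.
    Stored on the truth object for downstream oracles.
    """
    p = truth.params
    Lx, Ly = p.domain_um
    spacing = Lx / grid_n
    ny = max(int(round(Ly / spacing)), 2)
    xc = (np.arange(grid_n) + 0.5) * spacing
    X = np.tile(xc, (ny, 1))
    left = truth.left_front_position[frame]
    right = truth.front_position[frame]
    inside = (X >= left) & (X <= right)
    vr = np.exp(-np.clip(right - X, 0, None) / p.traction_decay_um)
    vl = np.exp(-np.clip(X - left, 0, None) / p.traction_decay_um)
    tx = -(p.edge_traction_pa - p.bulk_traction_pa) * (vr - vl) * inside
    t = np.stack([tx, np.zeros_like(tx)], axis=-1)
    t[..., 0] -= t[..., 0].mean()   # numerical net-force balance
    truth.true_traction = t
    truth.traction_spacing_um = spacing
    return t, spacing


def _stamp_gaussians(shape, centers_px, amplitudes, sigma_px):
    """Accumulate 2D Gaussian blobs onto an image (patch-local, fast)."""
    img = np.zeros(shape)
    r = int(np.ceil(4 * sigma_px))
    ax = np.arange(-r, r + 1)
    for (cx, cy), amp in zip(centers_px, amplitudes):
        ix, iy = int(round(cx)), int(round(cy))
        fx, fy = cx - ix, cy - iy
        gx = np.exp(-0.5 * ((ax - fx) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((ax - fy) / sigma_px) ** 2)
        patch = np.outer(gy, gx) * amp
        y0, y1 = iy - r, iy + r + 1
        x0, x1 = ix - r, ix + r + 1
        sy0, sx0 = max(-y0, 0), max(-x0, 0)
        sy1 = patch.shape[0] - max(y1 - shape[0], 0)
        sx1 = patch.shape[1] - max(x1 - shape[1], 0)
        if sy1 <= sy0 or sx1 <= sx0:
            continue
        img[max(y0, 0):min(y1, shape[0]), max(x0, 0):min(x1, shape[1])] += \
            patch[sy0:sy1, sx0:sx1]
    return img


def render_peredox_frames(
    truth: MonolayerGroundTruth,
    calib: CalibrationModel,
    config: ImagingConfig,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> dict:
    """Render red/green channel sequences plus ground-truth label masks.

    Each nucleus is a 2D Gaussian blob.  The red (expression) amplitude
    is drawn log-normally per cell and held fixed across frames; the
    green amplitude is set so the red/green ratio equals the normalized
    fluorescence ratio implied by the cell's true NAD+/NADH — the
    ratiometric design makes the ratio insensitive to expression level.
    Returns ``{"red", "green", "labels", "n_clipped"}`` with arrays of
    shape (n_frames, ny, nx).
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    p = truth.params
    px = config.pixel_size_redox
    ny = int(np.ceil(p.domain_um[1] / px))
    nx = int(np.ceil(p.domain_um[0] / px))
    n = len(truth.cell_ids)
    red_amp = 200.0 * rng.lognormal(0.0, 0.25, size=n)
    n_clipped = 0
    sig = p.nucleus_sigma_px

    reds, greens, labels = [], [], []
    for f in range(truth.positions_by_frame.shape[0]):
        pos = truth.positions_by_frame[f]
        redox = truth.redox_profile(pos[:, 0], frame=f)
        bad = redox <= 0
        n_clipped += int(bad.sum())
        redox = np.where(bad, 1e-6, redox)
        F = redox_to_fluorescence(redox, calib)
        green_amp = red_amp / F
        centers_px = pos / px
        red = _stamp_gaussians((ny, nx), centers_px, red_amp, sig)
        green = _stamp_gaussians((ny, nx), centers_px, green_amp, sig)
        lab = np.zeros((ny, nx), dtype=np.int32)
        rr = int(round(2 * sig))
        yy, xx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
        disk = yy**2 + xx**2 <= rr**2
        for cid, (cx, cy) in zip(truth.cell_ids, centers_px):
            ix, iy = int(round(cx)), int(round(cy))
            y0, x0 = iy - rr, ix - rr
            ys = slice(max(y0, 0), min(y0 + disk.shape[0], ny))
            xs = slice(max(x0, 0), min(x0 + disk.shape[1], nx))
            dys = slice(ys.start - y0, ys.stop - y0)
            dxs = slice(xs.start - x0, xs.stop - x0)
            sub = lab[ys, xs]
            sub[disk[dys, dxs]] = cid
        for img in (red, green):
            img += noise.background
        if noise.poisson:
            red = rng.poisson(red).astype(float)
            green = rng.poisson(green).astype(float)
        if noise.gaussian_sd > 0:
            red = red + rng.normal(0, noise.gaussian_sd, red.shape)
            green = green + rng.normal(0, noise.gaussian_sd, green.shape)
        reds.append(red)
        greens.append(green)
        labels.append(lab)
    if n_clipped:
        warnings.warn(f"{n_clipped} cell-frame redox value(s) outside the invertible "
                      "range were clipped", stacklevel=2)
    return {
        "red": np.array(reds),
        "green": np.array(greens),
        "labels": np.array(labels),
        "n_clipped": n_clipped,
    }


def synthesize_flim_stack(
    truth: MonolayerGroundTruth,
    config: ImagingConfig,
    photons_per_pixel: float = 5000,
    seed: int = 0,
    irf: np.ndarray | None = None,
    shape: tuple[int, int] | None = None,
    frame: int = 0,
) -> FlimStack:
    """Poisson TCSPC histogram stack from the monolayer's lifetime field.

    Per pixel, the expected histogram is the IRF-convolved biexponential
    with the local free-NADH fraction alpha1(x) and the global (tau1,
    tau2), plus a constant background (default 1% of peak), normalized
    so total expected counts equal the photon budget; counts are then
    drawn Poisson.  Pixels outside the layer get background-only decays
    at 2% of the budget.
    """
    from .flim import decay_model  # local import to avoid cycle at module load

    p = truth.params
    if not p.tau1_ns < p.tau2_ns:
        raise ValueError("lifetime ordering violated: tau1 must be < tau2")
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be positive")
    rng = np.random.default_rng(seed)
    nb = config.n_time_bins_raw
    bw = config.time_bin_width_ns
    if irf is None:
        irf = make_gaussian_irf(config.irf_fwhm_ps, bw, nb)
    if shape is None:
        pxs = config.pixel_size_flim
        shape = (int(np.ceil(p.domain_um[1] / pxs)),
                 int(np.ceil(p.domain_um[0] / pxs)))
    ny, nx = shape
    xs = (np.arange(nx) + 0.5) * p.domain_um[0] / nx
    times = (np.arange(nb) + 0.5) * bw
    hist = np.empty((ny, nx, nb))
    alpha_cols = truth.alpha1_profile(xs, frame=frame)
    inside_cols = truth.in_layer(xs, frame=frame)
    expected_cols = np.empty((nx, nb))
    for j in range(nx):
        if inside_cols[j]:
            curve = decay_model(times, irf, alpha_cols[j], p.tau1_ns, p.tau2_ns,
                                C=0.0, amplitude=1.0)
            curve = curve + p.flim_background_frac * curve.max()
            expected = curve / curve.sum() * photons_per_pixel
        else:
            expected = np.full(nb, 0.02 * photons_per_pixel / nb)
        expected_cols[j] = expected
    for i in range(ny):
        hist[i] = rng.poisson(expected_cols)
    return FlimStack(histograms=hist, bin_width_ns=bw, irf=irf)


def expected_flim_curve(
    truth: MonolayerGroundTruth,
    config: ImagingConfig,
    x_um: float,
    photons_per_pixel: float,
    irf: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free expected histogram at position x (oracle for tests)."""
    from .flim import decay_model

    p = truth.params
    nb = config.n_time_bins_raw
    bw = config.time_bin_width_ns
    if irf is None:
        irf = make_gaussian_irf(config.irf_fwhm_ps, bw, nb)
    times = (np.arange(nb) + 0.5) * bw
    a1 = float(truth.alpha1_profile(np.array([x_um]))[0])
    curve = decay_model(times, irf, a1, p.tau1_ns, p.tau2_ns, C=0.0, amplitude=1.0)
    curve = curve + p.flim_background_frac * curve.max()
    return curve / curve.sum() * photons_per_pixel


def forward_displacement_field(
    tractions_pa: np.ndarray,
    spacing_um: float,
    gel: GelProps,
) -> np.ndarray:
    """Half-space surface displacements for a prescribed traction field.

    Thin oracle wrapper over the elastic forward operator; see
    :func:`layermet.traction.forward_displacement`.
    """
    return forward_displacement(tractions_pa, spacing_um, gel)


def render_bead_images(
    displacements_um: np.ndarray,
    spacing_um: float,
    shape_px: tuple[int, int],
    pixel_size_um: float,
    n_beads: int = 2000,
    psf_sigma_px: float = 1.2,
    seed: int = 0,
) -> dict:
    """Reference/deformed bead image pair from a displacement field.

    Beads are placed uniformly at random (seeded); the deformed image
    shifts each bead by the bilinearly interpolated local displacement.
    Returns the image pair plus true bead coordinates (px).  Warns when
    the peak displacement exceeds half the mean bead spacing (tracking
    would be ambiguous).
    """
    from scipy.interpolate import RegularGridInterpolator

    rng = np.random.default_rng(seed)
    ny, nx = shape_px
    beads = np.column_stack([rng.uniform(0, nx, n_beads), rng.uniform(0, ny, n_beads)])
    u = np.asarray(displacements_um, dtype=float)
    gy = (np.arange(u.shape[0]) + 0.5) * spacing_um
    gx = (np.arange(u.shape[1]) + 0.5) * spacing_um
    interp = RegularGridInterpolator(
        (gy, gx), u, bounds_error=False, fill_value=None)
    pts_um = np.column_stack([beads[:, 1] * pixel_size_um, beads[:, 0] * pixel_size_um])
    disp_um = interp(pts_um)
    disp_px = disp_um / pixel_size_um
    mean_spacing = np.sqrt(nx * ny / n_beads)
    if np.max(np.linalg.norm(disp_px, axis=1)) > mean_spacing / 2:
        warnings.warn("peak bead displacement exceeds half the mean bead spacing; "
                      "correlation tracking may be ambiguous", stacklevel=2)
    amp = 150.0 * rng.lognormal(0, 0.2, n_beads)
    reference = _stamp_gaussians(shape_px, beads, amp, psf_sigma_px)
    deformed = _stamp_gaussians(shape_px, beads + disp_px, amp, psf_sigma_px)
    return {
        "reference": reference,
        "deformed": deformed,
        "bead_positions_px": beads,
        "bead_displacements_px": disp_px,
    }


def render_uptake_images(
    truth: MonolayerGroundTruth,
    profile,
    config: ImagingConfig,
    background: float = 10.0,
    frame: int = 0,
) -> dict:
    """Single-channel uptake/dye image with its layer mask.

    ``profile`` is a callable mapping x (µm) to intensity; inside the
    layer the image follows the profile, outside it sits at the
    background level.  Emulates glucose-analog (2-NBDG) or mitochondrial
    potential (TMRE) acquisitions.
    """
    p = truth.params
    px = config.pixel_size_redox
    ny = int(np.ceil(p.domain_um[1] / px))
    nx = int(np.ceil(p.domain_um[0] / px))
    xs = (np.arange(nx) + 0.5) * px
    inside = truth.in_layer(xs, frame=frame)
    row = np.where(inside, profile(xs), background)
    image = np.tile(row, (ny, 1)).astype(float)
    mask = np.tile(inside, (ny, 1))
    return {"image": image, "mask": mask}
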