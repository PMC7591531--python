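"""End-to-end orchestration: simulate -> track -> morph -> redox ->
traction -> flim -> profiles, with a manifest tying outputs to seeds.

Each stage writes its products under the run directory and records them
in the manifest; with ``resume=True`` a stage whose products already
exist is skipped, so partial runs can be continued.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import io as lio
from .config import PipelineConfig
from .flim import bin_stack, fit_stack
from .morphology import morphology_table, tessellate
from .profiles import (LayerProfile, composite, grid_cell_values, layer_center,
                       split_and_orient_fronts, transform_profile_to_redox)
from .redox import CalibrationModel, per_cell_ratio
from .synthetic import (build_true_traction, forward_displacement_field,
                        render_bead_images, render_peredox_frames,
                        simulate_monolayer, synthesize_flim_stack)
from .tracking import (compute_speeds, detect_nuclei, estimate_flow, link_tracks,
                       tracks_table)
from .traction import (GelProps, compute_tractions, measure_bead_displacements,
                       per_cell_traction)


@dataclass
class PipelineResult:
    """In-memory products of a full synthetic run."""

    truth: object
    cell_table: pd.DataFrame
    profiles: dict[str, LayerProfile]
    truth_profiles: dict[str, np.ndarray]
    manifest: lio.RunManifest


def _profile_of(positions, values, cfg, domain, pixel_size, quantity):
    spacing_um = cfg.profile.grid_spacing_px * pixel_size
    gx, gy, field = grid_cell_values(positions, values, spacing_um, domain)
    center = layer_center(positions)
    halves = split_and_orient_fronts(gx, field, center)
    _, _, prof = composite(halves, cfg.profile, grid_spacing_um=spacing_um,
                           quantity_name=quantity)
    return prof


def _load_cached_result(out: Path) -> PipelineResult | None:
    """Rehydrate a completed run from its output directory, if whole."""
    try:
        manifest = lio.RunManifest.load(out / "manifest.json")
        cell_table = pd.read_csv(out / "cells.csv")
        tp_raw = pd.read_csv(out / "truth_profiles.csv")
        profiles: dict[str, LayerProfile] = {}
        for csv in sorted(out.glob("profile_*.csv")):
            df = pd.read_csv(csv)
            q = csv.stem[len("profile_"):]
            profiles[q] = LayerProfile(
                x_centers=df["x_center_um"].values, mean=df["mean"].values,
                sd=df["sd"].values, n_layers=df["n_layers"].values,
                quantity_name=q)
        truth_profiles = {q: g["value"].values
                          for q, g in tp_raw.groupby("quantity")}
    except (OSError, KeyError):
        return None
    return PipelineResult(truth=None, cell_table=cell_table, profiles=profiles,
                          truth_profiles=truth_profiles, manifest=manifest)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 resume: bool = False) -> PipelineResult:
    """Run the full synthetic pipeline and return per-cell and profile data.

    The synthetic generator provides raw renders only; every measured
    quantity in the output is recovered from those renders by the
    analysis stages (detection, tracking, tessellation, ratio
    extraction, bead correlation + elastic inversion, decay fitting,
    profiling), never copied from the ground truth.
    """
    cfg = config
    manifest = lio.RunManifest(config=cfg.to_dict(), seed=cfg.seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if resume and (out / "manifest.json").exists():
            cached = _load_cached_result(out)
            if cached is not None:
                return cached

    rng_seeds = np.random.SeedSequence(cfg.seed).generate_state(8)
    calib = CalibrationModel()
    p = cfg.simulation

    # --- simulate + render -------------------------------------------
    truth = simulate_monolayer(p, seed=int(rng_seeds[0]))
    frames = render_peredox_frames(truth, calib, cfg.imaging, cfg.noise,
                                   seed=int(rng_seeds[1]))
    manifest.add_stage("simulate", n_cells=len(truth.cell_ids),
                       n_frames=p.n_frames)

    # --- nuclei tracking ---------------------------------------------
    detections_by_frame = []
    label_frames = []
    for f in range(p.n_frames):
        dets, labels = detect_nuclei(frames["red"][f], cfg.tracking)
        for d in dets:
            d.frame = f
        detections_by_frame.append(dets)
        label_frames.append(labels)
    flows = [estimate_flow(frames["red"][f], frames["red"][f + 1])
             for f in range(p.n_frames - 1)]
    tracks = link_tracks(detections_by_frame, flows, cfg.tracking)
    speeds = compute_speeds(tracks, cfg.imaging.frame_interval_min,
                            cfg.imaging.pixel_size_redox)
    manifest.add_stage("track", n_tracks=len(tracks))

    # --- per-cell features at the first frame ------------------------
    px = cfg.imaging.pixel_size_redox
    first = {t.track_id: t.detections[0] for t in tracks}
    track_ids = sorted(first)
    pos_px = np.array([first[t].centroid for t in track_ids])
    pos_um = pos_px * px
    speed_map = dict(zip(speeds["track_id"], speeds["speed_um_h"]))

    domain = p.domain_um
    cells = tessellate(pos_um, (0.0, 0.0, domain[0], domain[1]))
    morph = morphology_table(cells)
    manifest.add_stage("morph", n_cells=len(morph))

    ratios = per_cell_ratio(frames["red"][0], frames["green"][0],
                            label_frames[0])
    # match detections to ratio rows by label id
    det_label = {t: first[t].label_id for t in track_ids}
    ratio_map = dict(zip(ratios["label"], ratios["F_raw"]))

    cell_table = pd.DataFrame({
        "track_id": track_ids,
        "x_um": pos_um[:, 0],
        "y_um": pos_um[:, 1],
        "speed_um_h": [speed_map.get(t, np.nan) for t in track_ids],
        "area_um2": morph["area"].values,
        "perimeter_um": morph["perimeter"].values,
        "aspect_ratio": morph["aspect_ratio"].values,
        "is_boundary": morph["is_boundary"].values,
        "F_raw": [ratio_map.get(det_label[t], np.nan) for t in track_ids],
    })

    # --- traction -----------------------------------------------------
    from scipy import ndimage as _ndi
    from scipy.interpolate import RegularGridInterpolator

    tc = cfg.traction
    t_true, spacing = build_true_traction(truth, grid_n=tc.grid_n)
    gel = GelProps(cfg.imaging.gel_shear_modulus_pa, cfg.imaging.gel_poisson_ratio,
                   cfg.imaging.gel_thickness_um)
    u_true = forward_displacement_field(t_true, spacing, gel)
    bead_px = tc.bead_pixel_factor * px
    shape_px = (int(domain[1] / bead_px), int(domain[0] / bead_px))
    beads = render_bead_images(u_true, spacing, shape_px, bead_px,
                               n_beads=shape_px[0] * shape_px[1] // 60,
                               seed=int(rng_seeds[2]))
    gy_piv, gx_piv, disp_px = measure_bead_displacements(
        beads["deformed"], beads["reference"], window_px=tc.piv_window_px,
        register=False)
    # resample measured displacements (px) onto the traction grid (µm)
    u_meas_um = disp_px * bead_px
    interp = RegularGridInterpolator(
        (gy_piv * bead_px, gx_piv * bead_px), u_meas_um,
        bounds_error=False, fill_value=None)
    t_ny, t_nx = t_true.shape[:2]
    gcy = (np.arange(t_ny) + 0.5) * spacing
    gcx = (np.arange(t_nx) + 0.5) * spacing
    GY, GX = np.meshgrid(gcy, gcx, indexing="ij")
    u_grid = interp(np.stack([GY.ravel(), GX.ravel()], -1)).reshape(t_ny, t_nx, 2)
    if tc.smooth_sigma_cells > 0:
        u_grid = _ndi.gaussian_filter(
            u_grid, (tc.smooth_sigma_cells, tc.smooth_sigma_cells, 0))
    t_rec = compute_tractions(u_grid, spacing, gel,
                              regularization=tc.regularization)
    tmag = np.linalg.norm(t_rec, axis=-1)
    cell_tr = per_cell_traction(tmag, spacing, label_frames[0], px)
    tr_map = dict(zip(cell_tr["label"], cell_tr["mean_traction_pa"]))
    cell_table["traction_pa"] = [tr_map.get(det_label[t], np.nan) for t in track_ids]
    manifest.add_stage("traction", grid_n=tc.grid_n)

    # --- FLIM ----------------------------------------------------------
    flim_shape = tuple(cfg.flim.map_shape)
    stack = synthesize_flim_stack(truth, cfg.imaging, photons_per_pixel=20000,
                                  seed=int(rng_seeds[3]), shape=flim_shape)
    bstack = bin_stack(stack, spatial_radius=0,
                       temporal_factor=cfg.flim.temporal_binning)
    maps = fit_stack(bstack, cfg.flim, seed=int(rng_seeds[4]))
    manifest.add_stage("flim", shape=flim_shape)

    # --- profiles -----------------------------------------------------
    interior = ~cell_table["is_boundary"].values
    prof_args = dict(cfg=cfg, domain=domain, pixel_size=px)
    profiles = {}
    pos_all = cell_table[["x_um", "y_um"]].values
    for q in ("speed_um_h", "aspect_ratio", "area_um2", "F_raw", "traction_pa"):
        sel = interior if q in ("aspect_ratio", "area_um2") else np.ones(len(cell_table), bool)
        profiles[q] = _profile_of(pos_all[sel], cell_table.loc[sel, q].values,
                                  quantity=q, **prof_args)
    redox_trace = transform_profile_to_redox(profiles["F_raw"], calib)
    profiles["redox"] = LayerProfile(
        x_centers=redox_trace["x_center_um"].values,
        mean=redox_trace["redox_mean"].values,
        sd=(redox_trace["redox_hi"] - redox_trace["redox_lo"]).values / 2,
        n_layers=redox_trace["n_layers"].values, quantity_name="redox")

    # tau_m profile from FLIM maps (pixel columns -> x bins)
    import warnings as _warnings

    xs_flim = (np.arange(flim_shape[1]) + 0.5) * domain[0] / flim_shape[1]
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        tau_cols = np.nanmean(maps["tau_m"], axis=0)
    ok = np.isfinite(tau_cols)
    center = layer_center(np.column_stack([xs_flim[ok], np.zeros(ok.sum())]))
    halves = split_and_orient_fronts(xs_flim, tau_cols[None, :], center)
    _, _, tau_prof = composite(halves, cfg.profile,
                               grid_spacing_um=float(xs_flim[1] - xs_flim[0]),
                               quantity_name="tau_m")
    profiles["tau_m"] = tau_prof
    manifest.add_stage("profiles", quantities=",".join(profiles))

    # --- ground-truth profiles for validation -------------------------
    truth_profiles = {}
    cl = layer_center(truth.positions_by_frame[0])
    for name, fn in (
        ("speed_um_h", truth.speed_profile),
        ("F_raw", None),
        ("redox", truth.redox_profile),
        ("tau_m", truth.tau_m_profile),
        ("traction_pa", truth.traction_magnitude_profile),
    ):
        if fn is None:
            continue
        truth_profiles[name] = fn(cl + profiles[name].x_centers)
    # aspect truth: prescribed profile
    pa = truth.params
    d = np.clip(truth._edge_distance(cl + profiles["aspect_ratio"].x_centers), 0, None)
    truth_profiles["aspect_ratio"] = (
        pa.bulk_aspect + (pa.edge_aspect - pa.bulk_aspect) * np.exp(-d / pa.redox_decay_um))

    if out is not None:
        from .profiles import profile_table

        cell_table.to_csv(out / "cells.csv", index=False)
        tracks_table(tracks).to_csv(out / "tracks.csv", index=False)
        for q, prof in profiles.items():
            profile_table(prof).to_csv(out / f"profile_{q}.csv", index=False)
        pd.DataFrame({
            "quantity": np.concatenate([[q] * len(v) for q, v in
                                        truth_profiles.items()]),
            "value": np.concatenate(list(truth_profiles.values())),
        }).to_csv(out / "truth_profiles.csv", index=False)
        manifest.save(out / "manifest.json")

    return PipelineResult(truth=truth, cell_table=cell_table, profiles=profiles,
                          truth_profiles=truth_profiles, manifest=manifest)


def profile_truth_rank_correlation(result: PipelineResult) -> pd.DataFrame:
    """Spearman rank correlation of each recovered profile vs ground truth.

    The headline end-to-end check: the retrograde edge-to-bulk ordering
    of every quantity must survive the full measurement chain.
    """
    rows = []
    for q, truth_vals in result.truth_profiles.items():
        prof = result.profiles[q]
        ok = np.isfinite(prof.mean) & np.isfinite(truth_vals)
        if ok.sum() < 3:
            rows.append((q, np.nan, int(ok.sum())))
            continue
        rho = spearmanr(prof.mean[ok], truth_vals[ok]).statistic
        rows.append((q, float(rho), int(ok.sum())))
    return pd.DataFrame(rows, columns=["quantity", "spearman_rho", "n_bins"])
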