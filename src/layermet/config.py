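"""Configuration objects shared across pipeline stages.

Every literature-derived constant (Hill coefficient, LDH equilibrium
constant, pixel sizes, TCSPC binning, IRF width, gel elasticity, profile
grid/bin sizes) lives here as a named default so no stage hard-codes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class ImagingConfig:
    """Acquisition geometry and instrument parameters.

    Attributes
    ----------
    pixel_size_redox : float
        Widefield (Peredox / bead) pixel size, µm/pixel.
    pixel_size_flim : float
        Multiphoton FLIM pixel size, µm/pixel.
    frame_interval_min : float
        Time-lapse frame interval, minutes.
    n_time_bins_raw : int
        Raw TCSPC histogram length.
    tcspc_window_ns : float
        Full TCSPC temporal window, ns (80 MHz source -> 12.5 ns).
    irf_fwhm_ps : float
        Instrument response full width at half maximum, ps.
    bead_diameter_um : float
        Fiducial bead diameter, µm.
    gel_shear_modulus_pa : float
        Substrate gel shear modulus, Pa.
    gel_thickness_um : float
        Substrate gel thickness, µm (treated as a half-space).
    gel_poisson_ratio : float
        Substrate Poisson ratio (incompressible default).
    """

    pixel_size_redox: float = 0.325
    pixel_size_flim: float = 0.792
    frame_interval_min: float = 15.0
    n_time_bins_raw: int = 256
    tcspc_window_ns: float = 12.5
    irf_fwhm_ps: float = 311.0
    bead_diameter_um: float = 0.2
    gel_shear_modulus_pa: float = 9600.0
    gel_thickness_um: float = 100.0
    gel_poisson_ratio: float = 0.5

    @property
    def time_bin_width_ns(self) -> float:
        return self.tcspc_window_ns / self.n_time_bins_raw

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_redox", "pixel_size_flim", "frame_interval_min",
            "tcspc_window_ns", "irf_fwhm_ps", "bead_diameter_um",
            "gel_shear_modulus_pa", "gel_thickness_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_time_bins_raw <= 0:
            raise ValueError("n_time_bins_raw must be strictly positive")
        if not 0 <= self.gel_poisson_ratio < 0.5 + 1e-12:
            raise ValueError("gel_poisson_ratio must lie in [0, 0.5]")


@dataclass
class NoiseParams:
    """Rendering noise model: Poisson shot noise plus additive Gaussian."""

    poisson: bool = False
    gaussian_sd: float = 0.0
    background: float = 0.0


@dataclass
class SimulationParams:
    """Ground-truth monolayer geometry and gradient shapes.

    The layer occupies ``x < front_x0`` initially and expands toward +x.
    Edge/bulk values with an exponential decay length define every
    retrograde gradient (speed, aspect ratio, redox, lifetime fraction,
    traction); these are configurable emulation parameters, not claims
    about the biology.
    """

    domain_um: tuple[float, float] = (800.0, 200.0)   # (Lx, Ly)
    n_cells: int = 400
    n_frames: int = 8
    front_x0_um: float = 600.0
    edge_speed_um_h: float = 20.0
    bulk_speed_um_h: float = 1.0
    speed_decay_um: float = 150.0
    edge_redox: float = 60.0
    bulk_redox: float = 250.0
    redox_decay_um: float = 200.0
    edge_alpha1: float = 0.85
    bulk_alpha1: float = 0.70
    tau1_ns: float = 0.4
    tau2_ns: float = 2.5
    flim_background_frac: float = 0.01
    edge_traction_pa: float = 120.0
    bulk_traction_pa: float = 20.0
    traction_decay_um: float = 120.0
    edge_aspect: float = 2.0
    bulk_aspect: float = 1.1
    nucleus_sigma_px: float = 3.0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.domain_um[0] <= 0 or self.domain_um[1] <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.tau1_ns < self.tau2_ns:
            raise ValueError("tau1_ns must be smaller than tau2_ns")


@dataclass
class ProfileConfig:
    """Spatial-profile gridding and binning constants."""

    grid_spacing_px: int = 35
    x_bin_um: float = 260.0
    min_layers_for_sd: int = 3


@dataclass
class TrackingConfig:
    """Detection / linking scales (pixels, frames)."""

    nucleus_radius_px: float = 4.0
    min_separation_px: float = 5.0
    gating_radius_px: float = 15.0
    flow_window_px: int = 32
    detect_threshold_rel: float = 0.1


@dataclass
class TractionConfig:
    """Bead correlation and elastic-inversion settings.

    ``regularization`` is the dimensionless Tikhonov weight (relative to
    the softest Green's-operator mode), fixed by an L-curve sweep on
    synthetic bead pairs; ``smooth_sigma_cells`` Gaussian-smooths the
    measured displacement field (in traction grid cells) before
    inversion to suppress correlation noise at the highest wavenumbers.
    """

    grid_n: int = 64
    piv_window_px: int = 32
    regularization: float = 0.05
    smooth_sigma_cells: float = 1.0
    bead_pixel_factor: float = 2.0   # bead-channel pixel size, × pixel_size_redox


@dataclass
class FlimFitConfig:
    """Bounds and quality gates for decay fitting."""

    tau_min_ns: float = 0.02
    tau_max_ns: float = 100.0
    min_photons: int = 500
    n_restarts: int = 5
    temporal_binning: int = 4
    spatial_bin_radius_px: int = 2
    map_shape: tuple[int, int] = (6, 48)   # (ny, nx) of the fitted lifetime map


@dataclass
class PipelineConfig:
    """Top-level config aggregating all stage sections."""

    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    traction: TractionConfig = field(default_factory=TractionConfig)
    flim: FlimFitConfig = field(default_factory=FlimFitConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, section):
            d = dict(raw.get(section, {}))
            for key in ("domain_um", "map_shape"):
                if key in d:
                    d[key] = tuple(d[key])
            return klass(**d)

        return cls(
            imaging=build(ImagingConfig, "imaging"),
            simulation=build(SimulationParams, "simulation"),
            noise=build(NoiseParams, "noise"),
            profile=build(ProfileConfig, "profile"),
            tracking=build(TrackingConfig, "tracking"),
            traction=build(TractionConfig, "traction"),
            flim=build(FlimFitConfig, "flim"),
            seed=int(raw.get("seed", 0)),
        )
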