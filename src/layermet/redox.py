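"""Peredox ratiometric biosensor calibration and NAD+/NADH conversion.

The Peredox sensor couples a NADH-sensitive green (T-Sapphire) fluorophore
to an expression-normalizing red (mCherry) fluorophore; the red/green
ratio rises with cytoplasmic NADH occupancy. Calibration titrates cells
through media of known lactate:pyruvate ratio X, which clamps the
cytoplasmic NAD+/NADH through the lactate dehydrogenase equilibrium

    K = [Pyr][NADH][H+] / ([Lac][NAD+])      (K = 1.1e-11 at pH 7.4)

so X = [Lac]/[Pyr] = [H+] / (K * NAD+/NADH).  The normalized fluorescence
response follows a logistic (Hill) curve in X,

    F(X) = 1 + A / (1 + (B / X)^h),   h = 1.7 fixed,

with per-cell amplitude A and midpoint B fitted by bounded nonlinear
least squares.  Composing the two relations converts fluorescence ratio
to NAD+/NADH and back; because the transform is nonlinear and monotone
decreasing, symmetric fluorescence errors map to asymmetric redox errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

HILL_COEFFICIENT = 1.7
LDH_EQUILIBRIUM_K = 1.1e-11
PHYSIOLOGICAL_PH = 7.4


@dataclass
class CalibrationModel:
    """Fitted titration parameters plus the LDH equilibrium constants.

    Parameters
    ----------
    A : float
        Logistic amplitude (dynamic range of the normalized ratio).
    B : float
        Logistic midpoint, in lactate:pyruvate ratio units.
    hill : float
        Hill coefficient, fixed at 1.7.
    K : float
        LDH equilibrium constant.
    pH : float
        Assumed cytoplasmic pH.
    """

    A: float = 1.04
    B: float = 44.13
    hill: float = HILL_COEFFICIENT
    K: float = LDH_EQUILIBRIUM_K
    pH: float = PHYSIOLOGICAL_PH
    clip_eps_frac: float = 1e-3

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0 or self.K <= 0:
            raise ValueError("A, B and K must be strictly positive")

    @property
    def h_plus(self) -> float:
        return 10.0 ** (-self.pH)


def logistic_response(X, A, B, hill=HILL_COEFFICIENT):
    """Normalized fluorescence ratio F(X) = 1 + A / (1 + (B/X)^hill)."""
    X = np.asarray(X, dtype=float)
    return 1.0 + A / (1.0 + (B / X) ** hill)


def per_cell_ratio(
    red_image: np.ndarray,
    green_image: np.ndarray,
    label_image: np.ndarray,
    green_floor: float = 1e-6,
) -> pd.DataFrame:
    """Per-nucleus mean intensities and red/green fluorescence ratio.

    The ratio is the ratio of channel means over each labeled nucleus
    (not the mean of pixelwise ratios), which is robust to pixel-level
    zeros in the green channel.  Cells whose mean green signal does not
    clear ``green_floor`` are flagged (``qc_flag='low_green'``) and get
    NaN ratios rather than being dropped.
    """
    red_image = np.asarray(red_image, dtype=float)
    green_image = np.asarray(green_image, dtype=float)
    if red_image.shape != green_image.shape or red_image.shape != label_image.shape:
        raise ValueError("channel and label images must share a shape")
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.DataFrame(columns=["label", "mean_red", "mean_green", "F_raw", "qc_flag"])
    mean_red = ndimage.mean(red_image, labels=label_image, index=labels)
    mean_green = ndimage.mean(green_image, labels=label_image, index=labels)
    ok = mean_green > green_floor
    F_raw = np.where(ok, mean_red / np.where(ok, mean_green, 1.0), np.nan)
    return pd.DataFrame({
        "label": labels.astype(int),
        "mean_red": mean_red,
        "mean_green": mean_green,
        "F_raw": F_raw,
        "qc_flag": np.where(ok, "", "low_green"),
    })


@dataclass
class TitrationSeries:
    """One cell's fluorescence response across the lactate:pyruvate steps."""

    cell_id: int
    X: np.ndarray            # lactate:pyruvate ratio per step, ordered as acquired
    F_raw: np.ndarray        # raw red/green ratio per step
    F_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.F_raw = np.asarray(self.F_raw, dtype=float)
        if self.X.shape != self.F_raw.shape:
            raise ValueError("X and F_raw must have equal length")
        if np.any(self.X <= 0):
            raise ValueError("all lactate:pyruvate ratios must be positive")


def normalize_titration(series: TitrationSeries) -> TitrationSeries:
    """Normalize a series so its lowest-X (pyruvate-dominant) step maps to 1.

    The lowest-X step drives the sensor to its low-NADH state, the lower
    asymptote of the logistic; anchoring it at F=1 matches the model's
    F -> 1 limit as X -> 0.  Idempotent: renormalizing changes nothing.
    """
    anchor_idx = int(np.argmin(series.X))
    anchor = series.F_raw[anchor_idx]
    if not np.isfinite(anchor) or anchor <= 0:
        raise ValueError("missing or invalid low-X anchor step")
    return TitrationSeries(
        cell_id=series.cell_id,
        X=series.X,
        F_raw=series.F_raw,
        F_norm=series.F_raw / anchor,
    )


@dataclass
class CalibrationFitResult:
    """Per-cell logistic fits with aggregate statistics."""

    per_cell: pd.DataFrame            # cell_id, A, B, rss, converged
    A_mean: float = field(init=False)
    A_sd: float = field(init=False)
    B_mean: float = field(init=False)
    B_sd: float = field(init=False)
    n_failed: int = field(init=False)

    def __post_init__(self) -> None:
        ok = self.per_cell[self.per_cell["converged"]]
        self.A_mean = float(ok["A"].mean())
        self.A_sd = float(ok["A"].std(ddof=1)) if len(ok) > 1 else 0.0
        self.B_mean = float(ok["B"].mean())
        self.B_sd = float(ok["B"].std(ddof=1)) if len(ok) > 1 else 0.0
        self.n_failed = int((~self.per_cell["converged"]).sum())

    def mean_model(self) -> CalibrationModel:
        return CalibrationModel(A=self.A_mean, B=self.B_mean)


def fit_calibration(
    series_list: list[TitrationSeries],
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-3, 1e-3), (10.0, 1e4)),
) -> CalibrationFitResult:
    """Fit the logistic response per cell with the Hill coefficient fixed.

    Each series needs >= 4 steps spanning the sigmoid.  Non-converged
    cells are kept in the table with ``converged=False`` and excluded
    from the aggregate mean/SD.
    """
    rows = []
    for s in series_list:
        if s.F_norm is None:
            s = normalize_titration(s)
        if s.X.size < 4:
            raise ValueError(f"cell {s.cell_id}: need >= 4 titration steps")
        x0 = _initial_guess(s.X, s.F_norm)
        try:
            popt, _ = optimize.curve_fit(
                logistic_response, s.X, s.F_norm, p0=x0,
                bounds=bounds, maxfev=20000,
            )
            resid = s.F_norm - logistic_response(s.X, *popt)
            rows.append((s.cell_id, popt[0], popt[1], float(resid @ resid), True))
        except RuntimeError:
            rows.append((s.cell_id, np.nan, np.nan, np.nan, False))
    per_cell = pd.DataFrame(rows, columns=["cell_id", "A", "B", "rss", "converged"])
    return CalibrationFitResult(per_cell=per_cell)


def _initial_guess(X, F):
    A0 = max(float(np.max(F) - 1.0), 0.1)
    # midpoint: X where F crosses halfway up the observed range
    half = 1.0 + A0 / 2.0
    idx = int(np.argmin(np.abs(F - half)))
    B0 = float(np.clip(X[idx], 1e-2, 1e3))
    return (A0, B0)


def _clip_interior(F_norm, model: CalibrationModel):
    """Clip F into the open interval (1, 1+A) by eps = clip_eps_frac * A."""
    eps = model.clip_eps_frac * model.A
    lo, hi = 1.0 + eps, 1.0 + model.A - eps
    F = np.asarray(F_norm, dtype=float)
    clipped = (F <= lo) | (F >= hi)
    return np.clip(F, lo, hi), clipped


def fluorescence_to_redox(F_norm, model: CalibrationModel, return_flags: bool = False):
    """Convert normalized fluorescence ratio to cytoplasmic NAD+/NADH.

    Inverts the logistic for the lactate:pyruvate ratio,
    X = B / (A/(F-1) - 1)^(1/h), then applies the LDH equilibrium,
    NAD+/NADH = [H+] / (K X).  Strictly decreasing in F.  Values at or
    beyond the asymptotes are clipped into an eps-interior and flagged.
    """
    F, clipped = _clip_interior(F_norm, model)
    if np.any(clipped):
        warnings.warn(f"{int(np.sum(clipped))} fluorescence value(s) clipped to the "
                      "invertible range", stacklevel=2)
    X = model.B / (model.A / (F - 1.0) - 1.0) ** (1.0 / model.hill)
    redox = model.h_plus / (model.K * X)
    if return_flags:
        return redox, clipped
    return redox


def redox_to_fluorescence(redox, model: CalibrationModel):
    """Exact inverse of :func:`fluorescence_to_redox` for positive redox."""
    redox = np.asarray(redox, dtype=float)
    if np.any(redox <= 0):
        raise ValueError("NAD+/NADH must be strictly positive")
    X = model.h_plus / (model.K * redox)
    return logistic_response(X, model.A, model.B, model.hill)


DEFAULT_TITRATION_X = np.array([0.1, 1.0, 5.0, 20.0, 80.0, 200.0, 400.0])


def simulate_titration_experiment(
    n_cells: int = 200,
    A_mean: float = 1.04,
    A_sd: float = 0.24,
    B_mean: float = 44.13,
    B_sd: float = 26.08,
    X: np.ndarray = DEFAULT_TITRATION_X,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> tuple[list[TitrationSeries], np.ndarray, np.ndarray]:
    """Synthetic titration cohort with per-cell calibration parameters.

    Each cell draws true (A, B) from normal distributions (truncated to
    the physical range A > 0.05, B > 1 — the logistic midpoint must be
    a positive lactate:pyruvate ratio) and responds along the logistic
    curve at the titration steps ``X`` with multiplicative Gaussian
    noise of fractional SD ``noise_frac``; a per-cell expression scale
    emulates raw (un-normalized) red/green ratios.

    Returns ``(series_list, true_A, true_B)``.
    """
    rng = np.random.default_rng(seed)

    def truncated_normal(mean, sd, lo, size):
        out = rng.normal(mean, sd, size)
        while True:
            bad = out < lo
            if not bad.any():
                return out
            out[bad] = rng.normal(mean, sd, int(bad.sum()))

    true_A = truncated_normal(A_mean, A_sd, 0.05, n_cells)
    true_B = truncated_normal(B_mean, B_sd, 1.0, n_cells)
    series = []
    for i in range(n_cells):
        F = logistic_response(X, true_A[i], true_B[i])
        scale = rng.lognormal(0.0, 0.2)
        F_raw = scale * F * (1.0 + noise_frac * rng.standard_normal(X.size))
        series.append(TitrationSeries(cell_id=i, X=X, F_raw=F_raw))
    return series, true_A, true_B


def propagate_error(F_mean, F_sd, model: CalibrationModel):
    """Transform mean +/- SD fluorescence into an asymmetric redox interval.

    The SD is added to / subtracted from the mean ratio *before*
    conversion; because the transform is nonlinear the resulting interval
    is asymmetric about the point estimate.  Returns
    ``(redox_mean, lower, upper)`` with ``lower <= redox_mean <= upper``.
    """
    F_mean = np.asarray(F_mean, dtype=float)
    F_sd = np.asarray(F_sd, dtype=float)
    center = fluorescence_to_redox(F_mean, model)
    hi_F = fluorescence_to_redox(F_mean + F_sd, model)   # transform is decreasing
    lo_F = fluorescence_to_redox(F_mean - F_sd, model)
    lower = np.minimum(hi_F, lo_F)
    upper = np.maximum(hi_F, lo_F)
    return center, lower, upper
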