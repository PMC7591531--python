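"""Block cross-correlation with sub-pixel peak localization.

Shared displacement primitive for nucleus optical flow and bead
tracking.  The central region of the second window is matched against
the first with locally normalized cross-correlation
(:func:`skimage.feature.match_template`, which corrects for local mean
and variance and therefore has no windowing bias), and the correlation
peak is refined to sub-pixel precision with a separable Gaussian
(log-parabolic) three-point fit.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import match_template


def _refine(cm: float, c0: float, cp: float) -> float:
    """Three-point sub-pixel peak offset in [-0.5, 0.5].

    Gaussian (log-parabolic) interpolation — exact for Gaussian-shaped
    correlation peaks of any width — with a plain parabola fallback
    when the stencil is not positive.
    """
    if cm > 0 and c0 > 0 and cp > 0 and c0 >= cm and c0 >= cp:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm - 2 * l0 + lp
        if denom < 0:
            return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5))
    denom = cm - 2 * c0 + cp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def subpixel_shift(
    window_a: np.ndarray,
    window_b: np.ndarray,
    max_shift: int | None = None,
) -> tuple[np.ndarray, float]:
    """Displacement (dy, dx) of ``window_b`` content relative to ``window_a``.

    Returns ``(shift, quality)``; quality is the normalized correlation
    coefficient at the peak (1 = perfect match, ~0 = decorrelated).
    The search range is ``max_shift`` pixels (default a quarter of the
    window).
    """
    a = np.asarray(window_a, dtype=float)
    b = np.asarray(window_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("windows must share a shape")
    if np.array_equal(a, b):
        return np.zeros(2), 1.0 if a.std() > 0 else 0.0
    ny, nx = a.shape
    if max_shift is None:
        max_shift = max(min(ny, nx) // 4, 1)
    m = int(min(max_shift, (ny - 3) // 2, (nx - 3) // 2))
    if m < 1:
        return np.zeros(2), 0.0
    template = b[m:ny - m, m:nx - m]
    if template.std() == 0 or a.std() == 0:
        return np.zeros(2), 0.0
    cc = match_template(a, template)      # (2m+1, 2m+1) valid-mode NCC map
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    peak = float(cc[iy, ix])
    # content of b at offset m matched a at (iy, ix): shift = m - found
    dy = float(m - iy)
    dx = float(m - ix)
    if 0 < iy < cc.shape[0] - 1:
        dy -= _refine(cc[iy - 1, ix], cc[iy, ix], cc[iy + 1, ix])
    if 0 < ix < cc.shape[1] - 1:
        dx -= _refine(cc[iy, ix - 1], cc[iy, ix], cc[iy, ix + 1])
    return np.array([dy, dx]), float(np.clip(peak, -1.0, 1.0))
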