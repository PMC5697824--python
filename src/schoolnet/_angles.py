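"""Angle helpers shared across modules.

Convention: angles in radians, anticlockwise positive, wrapped to (-pi, pi].
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_angle", "moving_average"]


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a, dtype=float), 2.0 * np.pi)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated (shrinking) windows at the edges.

    NaNs propagate: a window containing a NaN averages to NaN, matching the
    explicit-missing-marker policy used throughout the package.
    """
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = x.size
    half = window // 2
    out = np.empty(n)
    if np.isnan(x).any():
        for i in range(n):
            out[i] = np.mean(x[max(0, i - half):min(n, i + half + 1)])
        return out
    c = np.concatenate(([0.0], np.cumsum(x)))
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (c[hi] - c[lo]) / (hi - lo)
    return out
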