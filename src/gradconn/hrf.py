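"""Canonical double-gamma hemodynamic response function and convolution helpers.

The kernel is the difference of two gamma densities — a response peaking at
6 s and an undershoot peaking at 16 s, with a 6:1 peak-to-undershoot ratio —
truncated at 32 s and normalised so the peak equals 1.  All regressor
construction in this package samples signals on a fine "microtime" grid,
convolves with this kernel, and then reads the result off at mid-volume
acquisition times.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["canonical_hrf", "hrf_convolve", "sample_at"]


def canonical_hrf(
    dt: float,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Double-gamma kernel sampled at t = 0, dt, 2*dt, ... < length_s.

    Gamma shapes are chosen so the densities attain their modes at ``peak_s``
    and ``undershoot_s`` (unit scale: mode = shape - 1); the undershoot is
    scaled down by ``ratio`` and the result peak-normalised to 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length_s, dt)
    h = stats.gamma.pdf(t, peak_s + 1.0) - stats.gamma.pdf(t, undershoot_s + 1.0) / ratio
    return h / h.max()


def hrf_convolve(u: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    """Causal convolution of a microtime series with an HRF kernel.

    Scaled by dt so the result approximates the continuous convolution
    integral and is insensitive to the microtime resolution.
    """
    return np.convolve(u, kernel)[: len(u)] * dt


def sample_at(series: np.ndarray, dt: float, times: np.ndarray) -> np.ndarray:
    """Linearly interpolate a microtime series (defined at t = k*dt) at
    arbitrary times, holding the last value beyond the end of the series."""
    t = np.arange(len(series)) * dt
    return np.interp(times, t, series)
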