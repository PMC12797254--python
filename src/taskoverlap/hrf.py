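"""Canonical double-gamma haemodynamic response function and convolution.

The same kernel and regressor builder are used by the synthetic forward model
and the first-level design matrices, so that a noiseless simulated run is
fitted exactly by the analysis model.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = ["double_gamma_hrf", "hrf_kernel", "convolve_events"]

#: kernel support in seconds; the undershoot has decayed to ~0 by then
HRF_DURATION_S = 32.0


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    Difference of two gamma densities: a positive lobe peaking near 6 s and
    an undershoot peaking near 16 s weighted by ``undershoot_ratio``.
    """
    t = np.asarray(t, dtype=float)
    peak = _gamma_dist.pdf(t, peak_delay_s / dispersion, scale=dispersion)
    under = _gamma_dist.pdf(t, undershoot_delay_s / dispersion, scale=dispersion)
    return peak - undershoot_ratio * under


def hrf_kernel(dt: float, duration_s: float = HRF_DURATION_S) -> np.ndarray:
    """Discrete HRF kernel sampled every ``dt`` seconds, peak-normalized."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration_s + dt, dt)
    h = double_gamma_hrf(t)
    return h / h.max()


def convolve_events(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_volumes: int,
    tr_seconds: float,
    oversampling: int = 10,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at volume acquisition times.

    The event boxcar is built on a grid of ``tr / oversampling`` seconds,
    convolved with the double-gamma kernel, and read out at ``t = i * TR``.

    Returns a length-``n_volumes`` vector.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if onsets.shape != durations.shape:
        raise ValueError("onsets and durations must have matching shapes")
    if np.any(onsets < 0) or np.any(durations <= 0):
        raise ValueError("onsets must be >= 0 and durations > 0")

    dt = tr_seconds / oversampling
    n_fine = int(round(n_volumes * tr_seconds / dt)) + 1
    boxcar = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        boxcar[i0 : max(i1, i0 + 1)] = 1.0

    kernel = hrf_kernel(dt)
    convolved = np.convolve(boxcar, kernel)[:n_fine] * dt
    sample_idx = np.round(np.arange(n_volumes) * tr_seconds / dt).astype(int)
    return convolved[sample_idx]
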