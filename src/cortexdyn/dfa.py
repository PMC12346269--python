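"""Alpha-band amplitude envelopes and detrended fluctuation analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.signal import filtfilt, firwin, hilbert

__all__ = ["DfaResult", "alpha_envelope", "dfa_hurst"]


@dataclass
class DfaResult:
    hurst: float
    window_sizes: NDArray[np.float64]  # seconds
    fluctuation: NDArray[np.float64]  # RMS detrended fluctuation
    fit_range: tuple[float, float]  # seconds

    def __post_init__(self) -> None:
        if not np.isfinite(self.hurst):
            raise ValueError("hurst must be finite")


def alpha_envelope(
    timeseries: NDArray[np.float64],
    fs: float,
    band: tuple[float, float] = (8.0, 13.0),
    fir_order: int = 100,
    trim_edges: bool = False,
) -> NDArray[np.float64]:
    """Amplitude envelope of the band-passed signal.

    Zero-phase band-pass with an order-``fir_order`` FIR filter, then the
    modulus of the analytic signal. With ``trim_edges`` the filter ring-in
    (2 x fir_order samples each side) is cut off; otherwise the output has
    the input's length.
    """
    x = np.asarray(timeseries, dtype=float).ravel()
    if fs <= 2 * band[1]:
        raise ValueError("fs must exceed twice the band's upper edge")
    if len(x) <= 3 * fir_order:
        raise ValueError(f"time series too short: need > {3 * fir_order} samples")
    taps = firwin(fir_order + 1, band, fs=fs, pass_zero=False)
    filtered = filtfilt(taps, [1.0], x)
    env = np.abs(hilbert(filtered))
    if trim_edges:
        cut = 2 * fir_order
        env = env[cut:-cut] if len(env) > 4 * fir_order else env
    return env


def dfa_hurst(
    envelope: NDArray[np.float64],
    fs: float,
    window_range: tuple[float, float] = (1.0, 120.0),
    overlap: float = 0.5,
    fit_range: tuple[float, float] = (3.0, 50.0),
    n_window_sizes: int = 20,
) -> DfaResult:
    """Hurst exponent via detrended fluctuation analysis.

    The signal profile (cumulative sum of the mean-removed envelope) is cut
    into 50%-overlapping windows at ``n_window_sizes`` log-spaced sizes
    within ``window_range``; each window is linearly detrended and the RMS
    residual averaged per size. H is the slope of log10 fluctuation versus
    log10 window size restricted to ``fit_range``.
    """
    x = np.asarray(envelope, dtype=float).ravel()
    max_fit_samples = int(round(fit_range[1] * fs))
    if len(x) < 2 * max_fit_samples:
        raise ValueError(
            f"envelope too short: need >= {2 * max_fit_samples} samples "
            f"(2 x the largest fit window of {fit_range[1]} s)"
        )
    profile = np.cumsum(x - x.mean())
    sizes_s = np.logspace(
        np.log10(window_range[0]), np.log10(window_range[1]), n_window_sizes
    )
    sizes = np.unique(np.round(sizes_s * fs).astype(int))
    sizes = sizes[(sizes >= 4) & (sizes <= len(x))]

    flucts = []
    kept = []
    t = None
    for n in sizes:
        step = max(int(round(n * (1.0 - overlap))), 1)
        n_win = (len(profile) - n) // step + 1
        if n_win < 1:
            continue
        idx = step * np.arange(n_win)[:, None] + np.arange(n)[None, :]
        segs = profile[idx]
        # vectorized linear detrend per window
        t = np.arange(n, dtype=float)
        t_mean = t.mean()
        t_center = t - t_mean
        denom = np.sum(t_center**2)
        seg_mean = segs.mean(axis=1, keepdims=True)
        slope = (segs - seg_mean) @ t_center / denom
        resid = segs - seg_mean - slope[:, None] * t_center[None, :]
        flucts.append(np.sqrt(np.mean(resid**2)))
        kept.append(n)
    sizes_sec = np.asarray(kept, dtype=float) / fs
    fl = np.asarray(flucts)
    ok = fl > 0
    sizes_sec, fl = sizes_sec[ok], fl[ok]
    in_fit = (sizes_sec >= fit_range[0] - 1e-12) & (sizes_sec <= fit_range[1] + 1e-12)
    if in_fit.sum() < 2:
        raise ValueError("fewer than 2 window sizes inside fit_range")
    slope_fit = np.polyfit(np.log10(sizes_sec[in_fit]), np.log10(fl[in_fit]), 1)
    return DfaResult(float(slope_fit[0]), sizes_sec, fl, fit_range)
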