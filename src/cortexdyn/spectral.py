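"""Per-parcel spectral parameterization.

Estimates the PSD on a 0.1 Hz grid and decomposes it, in log10-power
space, into an aperiodic component ``L(f) = b - log10(k + f**chi)`` (with
automatic fallback to a knee-free fit) plus Gaussian periodic peaks, then
extracts the alpha peak with a reference-constrained search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import curve_fit
from scipy.signal.windows import hann

__all__ = [
    "PowerSpectrum",
    "AperiodicFit",
    "PeakFit",
    "SpectralSummary",
    "welch_psd",
    "interpolate_line_noise",
    "fit_spectral_model",
    "extract_alpha",
    "summarize_spectrum",
]


@dataclass
class PowerSpectrum:
    """Power on a uniform 0.1 Hz frequency grid (arbitrary units)."""

    freqs: NDArray[np.float64]
    power: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float).ravel()
        self.power = np.asarray(self.power, dtype=float).ravel()
        if len(self.freqs) != len(self.power):
            raise ValueError("freqs and power must have equal length")
        d = np.diff(self.freqs)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, 0.1, atol=1e-9)):
            raise ValueError("freqs must be strictly increasing on a 0.1 Hz grid")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    def band(self, lo: float, hi: float) -> NDArray[np.bool_]:
        return (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)


@dataclass
class AperiodicFit:
    """Aperiodic model b - log10(k + f^chi) in log10 power."""

    offset: float
    knee: float
    exponent: float
    mode: str  # "with_knee" | "fixed"
    freq_step: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("with_knee", "fixed"):
            raise ValueError("mode must be 'with_knee' or 'fixed'")
        if self.exponent <= 0:
            raise ValueError("exponent chi must be > 0")

    @property
    def knee_frequency(self) -> float:
        """k^(1/chi) in Hz, NaN when fitted without the knee."""
        if self.mode != "with_knee":
            return float("nan")
        return float(self.knee ** (1.0 / self.exponent))

    def log_power(self, freqs: NDArray[np.float64]) -> NDArray[np.float64]:
        f = np.asarray(freqs, dtype=float)
        k = self.knee if self.mode == "with_knee" else 0.0
        return self.offset - np.log10(k + f**self.exponent)


@dataclass
class PeakFit:
    """One Gaussian periodic peak above the aperiodic component."""

    center_frequency: float
    peak_power: float  # log10-power height above the aperiodic fit
    bandwidth: float  # Hz (2 * Gaussian SD)

    def __post_init__(self) -> None:
        if self.peak_power <= 0:
            raise ValueError("peak_power must be > 0")


@dataclass
class SpectralSummary:
    """The per-parcel spectral parameters (NaN marks a missing value)."""

    exponent: float
    knee_frequency: float
    auc: float
    alpha_power: float = float("nan")
    alpha_frequency: float = float("nan")


def welch_psd(
    timeseries: NDArray[np.float64],
    fs: float,
    epoch_seconds: float = 10.0,
    overlap_fraction: float = 0.5,
    mode: str = "power",
) -> PowerSpectrum:
    """Epoch-averaged spectrum: Hann-tapered epochs with 50% overlap.

    ``mode='power'`` (default) averages squared Fourier magnitudes;
    ``mode='amplitude'`` averages absolute magnitudes, which halves the
    apparent aperiodic exponent relative to the power convention.
    A 10-s epoch yields the 0.1 Hz grid required by :class:`PowerSpectrum`.
    """
    x = np.asarray(timeseries, dtype=float).ravel()
    nper = int(round(epoch_seconds * fs))
    if len(x) < nper:
        raise ValueError(
            f"time series too short: need at least {nper} samples "
            f"({epoch_seconds} s at fs={fs})"
        )
    if mode not in ("power", "amplitude"):
        raise ValueError("mode must be 'power' or 'amplitude'")
    step = int(round(nper * (1.0 - overlap_fraction)))
    step = max(step, 1)
    n_epochs = (len(x) - nper) // step + 1
    win = hann(nper, sym=False)
    scale = 2.0 / (fs * np.sum(win**2))
    acc = None
    for e in range(n_epochs):
        seg = x[e * step : e * step + nper]
        coeffs = np.fft.rfft(seg * win)
        mag = np.abs(coeffs)
        term = mag**2 * scale if mode == "power" else mag * np.sqrt(scale)
        acc = term if acc is None else acc + term
    power = acc / n_epochs
    power[0] = power[1] if len(power) > 1 else power[0]  # drop DC singularity
    if len(power) > 1:
        power[-1] /= 2.0 if mode == "power" else np.sqrt(2.0)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return PowerSpectrum(freqs, power)


def n_welch_epochs(n_samples: int, fs: float, epoch_seconds: float = 10.0,
                   overlap_fraction: float = 0.5) -> int:
    """Number of epochs ``welch_psd`` will average for a given input length."""
    nper = int(round(epoch_seconds * fs))
    step = max(int(round(nper * (1.0 - overlap_fraction))), 1)
    return (n_samples - nper) // step + 1 if n_samples >= nper else 0


def interpolate_line_noise(
    spectrum: PowerSpectrum,
    line_freqs=(50.0, 100.0, 150.0),
    halfwidth: float = 2.0,
) -> PowerSpectrum:
    """Replace power within ``f0 +/- halfwidth`` of each line frequency by
    the straight line joining the first bins outside the band."""
    freqs, power = spectrum.freqs, spectrum.power.copy()
    for f0 in line_freqs:
        inside = np.abs(freqs - f0) <= halfwidth + 1e-9
        if not inside.any():
            continue
        i0, i1 = np.flatnonzero(inside)[[0, -1]]
        if i0 == 0 or i1 == len(freqs) - 1:
            raise ValueError(
                f"line band {f0}+/-{halfwidth} Hz exceeds spectrum support"
            )
        lo, hi = i0 - 1, i1 + 1
        power[inside] = np.interp(freqs[inside], [freqs[lo], freqs[hi]],
                                  [power[lo], power[hi]])
    return PowerSpectrum(freqs, power)


def _gaussian(f, center, height, sd):
    return height * np.exp(-0.5 * ((f - center) / sd) ** 2)


def _peaks_log_power(freqs: NDArray[np.float64], peaks: list[PeakFit]):
    out = np.zeros_like(freqs, dtype=float)
    for p in peaks:
        out += _gaussian(freqs, p.center_frequency, p.peak_power, p.bandwidth / 2.0)
    return out


def _fit_aperiodic(freqs, log_power, with_knee: bool) -> AperiodicFit:
    """Single least-squares pass; raises on optimizer failure."""
    slope_guess = -(log_power[-1] - log_power[0]) / (
        np.log10(freqs[-1]) - np.log10(freqs[0])
    )
    chi0 = float(np.clip(slope_guess, 0.2, 6.0))
    if with_knee:
        def model(f, b, k, chi):
            return b - np.log10(np.maximum(k + f**chi, 1e-300))
        p0 = [log_power[0], 1.0, chi0]
    else:
        def model(f, b, chi):
            return b - chi * np.log10(f)
        p0 = [log_power[0], chi0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(model, freqs, log_power, p0=p0, maxfev=5000)
    if with_knee:
        b, k, chi = popt
        if chi <= 0:
            raise RuntimeError("non-physical exponent from knee fit")
        return AperiodicFit(float(b), float(k), float(chi), "with_knee")
    b, chi = popt
    if chi <= 0:
        raise RuntimeError("non-physical exponent from fixed fit")
    return AperiodicFit(float(b), 0.0, float(chi), "fixed")


def _robust_aperiodic(freqs, log_power, with_knee):
    """Refit after masking bins that sit above the initial fit (peaks)."""
    fit = _fit_aperiodic(freqs, log_power, with_knee)
    resid = log_power - fit.log_power(freqs)
    resid = np.clip(resid, 0.0, None)
    thresh = np.percentile(resid, 2.5)
    mask = resid <= thresh
    if mask.sum() >= 5:
        fit = _fit_aperiodic(freqs[mask], log_power[mask], with_knee)
    return fit


def fit_spectral_model(
    spectrum: PowerSpectrum,
    fit_range: tuple[float, float] = (1.0, 65.0),
    peak_threshold_sd: float = 2.0,
    peak_width_limits: tuple[float, float] = (2.0, 16.0),
    with_knee: bool = True,
    max_n_peaks: int = 6,
    min_peak_height: float = 0.05,
) -> tuple[AperiodicFit, list[PeakFit]]:
    """Decompose a PSD into aperiodic + Gaussian peaks over ``fit_range``.

    If the knee fit fails to converge or returns a knee ``k <= 0``, the
    model is refit with the knee fixed at zero and ``mode='fixed'``.
    """
    sel = spectrum.band(*fit_range)
    freqs = spectrum.freqs[sel]
    power = spectrum.power[sel]
    if len(freqs) < 5:
        raise ValueError("spectrum too sparse over fit_range")
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive over fit_range")
    log_power = np.log10(power)

    aperiodic = None
    if with_knee:
        try:
            cand = _robust_aperiodic(freqs, log_power, with_knee=True)
            if cand.knee > 0:
                aperiodic = cand
        except (RuntimeError, ValueError):
            aperiodic = None
    if aperiodic is None:
        aperiodic = _robust_aperiodic(freqs, log_power, with_knee=False)

    # iterative peak extraction on the flattened spectrum
    lo_bw, hi_bw = peak_width_limits
    flat = log_power - aperiodic.log_power(freqs)
    guesses = []
    work = flat.copy()
    for _ in range(max_n_peaks):
        sd_thresh = peak_threshold_sd * np.std(work)
        i = int(np.argmax(work))
        height = work[i]
        if height <= max(sd_thresh, min_peak_height):
            break
        # half-height width estimate -> Gaussian SD
        half = height / 2.0
        j = i
        while j > 0 and work[j] > half:
            j -= 1
        r = i
        while r < len(work) - 1 and work[r] > half:
            r += 1
        fwhm = max(freqs[r] - freqs[j], 0.2)
        sd = float(np.clip(fwhm / 2.355, lo_bw / 2.0, hi_bw / 2.0))
        guesses.append((freqs[i], height, sd))
        work = work - _gaussian(freqs, freqs[i], height, sd)

    peaks: list[PeakFit] = []
    if guesses:
        def multi(f, *params):
            out = np.zeros_like(f)
            for c, h, s in zip(params[::3], params[1::3], params[2::3]):
                out += _gaussian(f, c, h, s)
            return out
        p0, lo, hi = [], [], []
        for c, h, s in guesses:
            p0 += [c, h, s]
            lo += [c - 2 * s, 0.0, lo_bw / 2.0]
            hi += [c + 2 * s, np.inf, hi_bw / 2.0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(multi, freqs, flat, p0=p0,
                                    bounds=(lo, hi), maxfev=5000)
            triples = list(zip(popt[::3], popt[1::3], popt[2::3]))
        except RuntimeError:
            triples = guesses
        for c, h, s in triples:
            if h > min_peak_height and fit_range[0] <= c <= fit_range[1]:
                peaks.append(PeakFit(float(c), float(h), float(2.0 * s)))

    # final aperiodic pass on the peak-removed spectrum
    peakless = log_power - _peaks_log_power(freqs, peaks)
    try:
        final = _fit_aperiodic(freqs, peakless, with_knee=aperiodic.mode == "with_knee")
        if final.mode == "with_knee" and final.knee <= 0:
            final = _fit_aperiodic(freqs, peakless, with_knee=False)
        aperiodic = final
    except (RuntimeError, ValueError):
        pass
    peaks.sort(key=lambda p: p.center_frequency)
    return aperiodic, peaks


def extract_alpha(
    peaks_per_parcel: list[list[PeakFit]],
    visual_reference_psd: PowerSpectrum | None,
    search_pad: float = 2.0,
    alpha_range: tuple[float, float] = (7.0, 13.0),
    **fit_kwargs,
) -> NDArray[np.float64]:
    """Per-parcel (alpha_frequency, alpha_power), NaN where no peak exists.

    The search window is anchored on the alpha peak of the mean PSD over a
    set of visual reference parcels: window = peak band (center +/- bw/2)
    widened by ``search_pad`` Hz on each side. If the reference PSD has no
    alpha peak the window falls back to ``alpha_range``. Among multiple
    in-window candidates the highest-power one wins.
    """
    if visual_reference_psd is not None:
        _, ref_peaks = fit_spectral_model(visual_reference_psd, **fit_kwargs)
        ref_alpha = [p for p in ref_peaks
                     if alpha_range[0] <= p.center_frequency <= alpha_range[1]]
    else:
        ref_alpha = []
    if ref_alpha:
        ref = max(ref_alpha, key=lambda p: p.peak_power)
        window = (ref.center_frequency - ref.bandwidth / 2.0 - search_pad,
                  ref.center_frequency + ref.bandwidth / 2.0 + search_pad)
    else:
        window = alpha_range

    out = np.full((len(peaks_per_parcel), 2), np.nan)
    for i, peaks in enumerate(peaks_per_parcel):
        cands = [p for p in peaks if window[0] <= p.center_frequency <= window[1]]
        if not cands:
            cands = [p for p in peaks
                     if alpha_range[0] <= p.center_frequency <= alpha_range[1]]
        if cands:
            best = max(cands, key=lambda p: p.peak_power)
            out[i] = (best.center_frequency, best.peak_power)
    return out


def mean_reference_spectrum(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Mean PSD across a (visual) reference parcel set."""
    if not spectra:
        raise ValueError("reference parcel set must be non-empty")
    freqs = spectra[0].freqs
    for s in spectra[1:]:
        if len(s.freqs) != len(freqs) or not np.allclose(s.freqs, freqs):
            raise ValueError("reference spectra must share one frequency grid")
    return PowerSpectrum(freqs, np.mean([s.power for s in spectra], axis=0))


def summarize_spectrum(
    aperiodic_fit: AperiodicFit,
    auc_range: tuple[float, float] = (1.0, 65.0),
) -> SpectralSummary:
    """AUC (summed linear aperiodic power on the 0.1 Hz grid, 1-65 Hz)
    and knee frequency (NaN in knee-free mode)."""
    step = aperiodic_fit.freq_step
    n = int(round((auc_range[1] - auc_range[0]) / step)) + 1
    freqs = auc_range[0] + step * np.arange(n)
    auc = float(np.sum(10.0 ** aperiodic_fit.log_power(freqs)))
    return SpectralSummary(
        exponent=aperiodic_fit.exponent,
        knee_frequency=aperiodic_fit.knee_frequency,
        auc=auc,
    )
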