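"""Synthetic parcellations, maps, time series and cohorts.

Everything here is a pure function of its arguments and an integer seed,
so downstream statistics can be exercised end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert
from scipy.spatial.transform import Rotation

__all__ = [
    "ParcelGeometry",
    "ParcelMap",
    "SubjectRecord",
    "TimeseriesParams",
    "SyntheticConfig",
    "PARAMETER_ORDER",
    "make_geometry",
    "make_bilateral_geometry",
    "great_circle_distances",
    "simulate_smooth_map",
    "fractional_gaussian_noise",
    "simulate_parcel_timeseries",
    "simulate_cohort",
]

#: Canonical ordering of the six dynamics parameters used throughout.
PARAMETER_ORDER = (
    "exponent",
    "knee_frequency",
    "auc",
    "hurst",
    "alpha_power",
    "alpha_frequency",
)

# Fixed affine taking unit-sphere coordinates to an anatomical (MNI-like,
# mm) frame: x = left-right, y = posterior-anterior, z = inferior-superior.
_ANAT_SCALE = np.array([70.0, 85.0, 65.0])
_ANAT_OFFSET = np.array([0.0, -18.0, 15.0])


@dataclass(frozen=True)
class ParcelGeometry:
    """Parcel centroids on the unit sphere plus anatomical-space centroids."""

    parcel_id: NDArray[np.int64]
    sphere_xyz: NDArray[np.float64]
    anat_xyz: NDArray[np.float64]
    medial_wall: NDArray[np.bool_]

    def __post_init__(self) -> None:
        pid = np.asarray(self.parcel_id)
        sph = np.asarray(self.sphere_xyz, dtype=float)
        anat = np.asarray(self.anat_xyz, dtype=float)
        mw = np.asarray(self.medial_wall, dtype=bool)
        if sph.ndim != 2 or sph.shape[1] != 3:
            raise ValueError("sphere_xyz must be (n_parcels, 3)")
        if not (len(pid) == len(sph) == len(anat) == len(mw)):
            raise ValueError("geometry fields must have equal length")
        norms = np.linalg.norm(sph, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sphere centroids must have unit norm (tol 1e-9)")
        if len(np.unique(pid)) != len(pid):
            raise ValueError("parcel ids must be unique")
        if int((~mw).sum()) < min(3, len(pid)) and len(pid) >= 3:
            raise ValueError("need at least 3 non-medial-wall parcels")
        object.__setattr__(self, "parcel_id", pid.astype(np.int64))
        object.__setattr__(self, "sphere_xyz", sph)
        object.__setattr__(self, "anat_xyz", anat)
        object.__setattr__(self, "medial_wall", mw)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_id)

    def axis_values(self, axis: str) -> NDArray[np.float64]:
        """Anatomical coordinate along ``x``, ``y``, ``z`` or ``y_plus_z``."""
        cols = {"x": 0, "y": 1, "z": 2}
        if axis in cols:
            return self.anat_xyz[:, cols[axis]].copy()
        if axis == "y_plus_z":
            return self.anat_xyz[:, 1] + self.anat_xyz[:, 2]
        raise ValueError(f"unknown axis {axis!r}; use x, y, z or y_plus_z")


@dataclass
class ParcelMap:
    """One value (or NaN for missing) per parcel of a geometry."""

    values: NDArray[np.float64]
    parameter_label: str = ""
    geometry_ref: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SubjectRecord:
    subject_id: str
    group_label: str
    maps: dict  # parameter_label -> ndarray of per-parcel values
    symptoms: tuple | None = None  # (positive_score, negative_score)


@dataclass
class TimeseriesParams:
    """Generative parameters for one parcel's resting-state trace."""

    offset: float = 0.0  # b, log10 power
    knee: float = 0.0  # k, model units (>= 0)
    exponent: float = 2.0  # chi (> 0)
    alpha_frequency: float = 10.0
    alpha_amplitude: float = 0.0
    alpha_bandwidth: float = 2.0
    envelope_hurst: float = 0.7
    fs: float = 100.0
    duration: float = 300.0

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("exponent chi must be > 0")
        if self.knee < 0:
            raise ValueError("knee k must be >= 0")
        if self.alpha_amplitude > 0 and self.fs < 4 * self.alpha_frequency:
            raise ValueError("fs must be >= 4 x alpha frequency")
        if not 0 < self.envelope_hurst < 1.5:
            raise ValueError("envelope Hurst target must lie in (0, 1.5)")


@dataclass
class SyntheticConfig:
    """Full recipe for a synthetic cohort."""

    seed: int = 0
    n_parcels: int = 180
    group_sizes: dict = field(default_factory=lambda: {"control": 20, "clinical_A": 20})
    gradient_map: NDArray[np.float64] | None = None
    signature_patterns: dict = field(default_factory=dict)  # group -> {param -> ndarray}
    signature_amplitude: float = 1.0  # beta
    noise_sd: float = 0.5
    smoothness_length_scale: float = 0.3  # radians
    symptom_coupling: tuple = (1.0, 0.0)  # scores = coupling * beta_i + noise
    symptom_noise_sd: float = 0.5
    symptom_groups: tuple = ()  # groups that receive symptom scores
    paired_with: dict = field(default_factory=dict)  # drug label -> baseline label
    timeseries_params: TimeseriesParams | None = None

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group size must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def make_geometry(
    n_parcels: int, seed: int = 0, medial_wall_fraction: float = 0.0
) -> ParcelGeometry:
    """Quasi-uniform parcel centroids on the unit sphere (Fibonacci lattice).

    The lattice is given a uniformly random rigid rotation drawn from
    ``seed`` so distinct seeds yield distinct (but equally uniform)
    geometries. Anatomical centroids follow by a fixed affine.
    """
    if n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    i = np.arange(n_parcels, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_parcels
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    rng = np.random.default_rng(seed)
    if n_parcels > 1:
        pts = pts @ Rotation.random(rng=rng).as_matrix().T
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    anat = pts * _ANAT_SCALE + _ANAT_OFFSET
    medial = np.zeros(n_parcels, dtype=bool)
    n_medial = int(round(medial_wall_fraction * n_parcels))
    n_medial = min(n_medial, max(0, n_parcels - 3))
    if n_medial > 0:
        # flag the parcels closest to the medial plane (|x| smallest)
        medial[np.argsort(np.abs(pts[:, 0]))[:n_medial]] = True
    return ParcelGeometry(np.arange(n_parcels), pts, anat, medial)


def make_bilateral_geometry(
    n_pairs: int, seed: int = 0
) -> tuple[ParcelGeometry, NDArray[np.int64]]:
    """A two-hemisphere geometry: ``n_pairs`` right parcels plus their
    left mirror images, and a homotopic pairing table of shape (n_pairs, 2)
    with columns (left_index, right_index)."""
    base = make_geometry(n_pairs, seed=seed)
    right = base.sphere_xyz.copy()
    right[:, 0] = np.abs(right[:, 0])
    right /= np.linalg.norm(right, axis=1, keepdims=True)
    left = right.copy()
    left[:, 0] *= -1.0
    sphere = np.vstack([left, right])
    anat = sphere * _ANAT_SCALE + _ANAT_OFFSET
    geom = ParcelGeometry(
        np.arange(2 * n_pairs), sphere, anat, np.zeros(2 * n_pairs, dtype=bool)
    )
    pairs = np.column_stack([np.arange(n_pairs), np.arange(n_pairs) + n_pairs])
    return geom, pairs


def great_circle_distances(sphere_xyz: NDArray[np.float64]) -> NDArray[np.float64]:
    """Pairwise great-circle (arc) distances in radians."""
    g = np.clip(sphere_xyz @ sphere_xyz.T, -1.0, 1.0)
    return np.arccos(g)


def simulate_smooth_map(
    geometry: ParcelGeometry,
    length_scale: float,
    seed: int = 0,
    sd: float = 1.0,
) -> NDArray[np.float64]:
    """Zero-mean Gaussian random field over parcels with squared-exponential
    covariance in great-circle distance (length_scale in radians)."""
    if length_scale <= 0:
        raise ValueError("length_scale must be > 0")
    d = great_circle_distances(geometry.sphere_xyz)
    if geometry.n_parcels > 1 and np.all(d[~np.eye(len(d), dtype=bool)] < 1e-12):
        raise ValueError("degenerate geometry: all centroids coincide")
    cov = sd**2 * np.exp(-0.5 * (d / length_scale) ** 2)
    # the kernel is not guaranteed PSD on the sphere: clip negative modes
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(geometry.n_parcels)
    return v @ (np.sqrt(w) * z)


def fractional_gaussian_noise(
    n: int, hurst: float, seed: int = 0, rng: np.random.Generator | None = None
) -> NDArray[np.float64]:
    """Exact fractional Gaussian noise by Davies-Harte circulant embedding.

    Unit variance, ``0 < hurst < 1``. H = 0.5 reduces to white noise.
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma[:-1], gamma[-1:], gamma[-2:0:-1]])
    lam = np.fft.rfft(row).real
    lam = np.clip(lam, 0.0, None)  # tiny negatives from roundoff
    m = len(row)
    # complex Gaussian spectrum with Hermitian symmetry handled by irfft
    nf = len(lam)
    z = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    z[0] = rng.standard_normal() * np.sqrt(2.0)
    if m % 2 == 0:
        z[-1] = rng.standard_normal() * np.sqrt(2.0)
    spec = np.sqrt(lam * m / 2.0) * z
    x = np.fft.irfft(spec, n=m)
    return x[:n]


def _long_range_series(n: int, hurst: float, rng: np.random.Generator) -> NDArray[np.float64]:
    """Unit-SD series whose DFA slope targets ``hurst`` in (0, 1.5)."""
    if hurst < 1.0:
        x = fractional_gaussian_noise(n, hurst, rng=rng)
    else:
        # DFA slope of cumulated fGn(H') is H' + 1
        h = min(max(hurst - 1.0, 1e-3), 0.999)
        x = np.cumsum(fractional_gaussian_noise(n, h, rng=rng))
    s = x.std()
    return x / s if s > 0 else x


def simulate_parcel_timeseries(
    params: TimeseriesParams, seed: int = 0
) -> NDArray[np.float64]:
    """One parcel's trace: aperiodic 10^b / (k + f^chi) background plus an
    alpha-band oscillation amplitude-modulated by a long-range-correlated
    envelope.

    The broadband part is Gaussian noise spectrally shaped so the expected
    one-sided PSD equals ``10**offset / (knee + f**exponent)``. The alpha
    part is a narrowband unit-amplitude carrier (band-passed noise with its
    own envelope divided out) multiplied by
    ``alpha_amplitude * |1 + 0.25 * g(t)|`` where ``g`` has unit SD and DFA
    exponent ``envelope_hurst``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration * params.fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / params.fs)
    psd = np.zeros_like(freqs)
    nz = freqs > 0
    psd[nz] = 10.0**params.offset / (params.knee + freqs[nz] ** params.exponent)
    # E[2 |rfft(ts)|^2 / (fs n)] = psd  (one-sided periodogram convention)
    amp = np.sqrt(psd * n * params.fs / 4.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    ts = np.fft.irfft(spec, n=n)

    if params.alpha_amplitude > 0:
        # narrowband carrier: Gaussian spectral window, envelope-normalized
        sig_f = max(params.alpha_bandwidth / 2.0, 1e-6)
        win = np.exp(-0.5 * ((freqs - params.alpha_frequency) / sig_f) ** 2)
        cspec = win * (
            rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
        )
        cspec[0] = 0.0
        carrier = np.fft.irfft(cspec, n=n)
        analytic = hilbert(carrier)
        mag = np.abs(analytic)
        mag[mag < 1e-12] = 1e-12
        carrier = np.real(analytic) / mag  # unit instantaneous amplitude
        g = _long_range_series(n, params.envelope_hurst, rng)
        # drop modulation content above ~1.6 Hz so the band-pass used at
        # extraction time does not truncate the envelope's sidebands
        g = gaussian_filter1d(g, 0.1 * params.fs)
        s = g.std()
        if s > 0:
            g = g / s
        env = np.abs(1.0 + 0.25 * g)
        ts = ts + params.alpha_amplitude * env * carrier
    return ts


def _truncated_normal(mean: float, sd: float, size: int, rng: np.random.Generator):
    """Normal(mean, sd) truncated at 0 from below (resampling)."""
    if sd <= 0:
        return np.full(size, max(mean, 0.0))
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out < 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, 0.0, None)


def simulate_cohort(config: SyntheticConfig) -> tuple[list[SubjectRecord], ParcelGeometry]:
    """Generate a full cohort of per-subject multiparameter maps.

    Control-like groups get ``gradient + smooth noise`` per parameter;
    groups with a signature pattern additionally add a subject-specific
    expression ``beta_i * pattern`` with ``beta_i ~ N(beta, beta/2)``
    truncated at zero. Groups listed in ``paired_with`` reuse the subjects
    (and per-subject baseline maps) of their baseline group, so paired
    drug-placebo designs are representable. Symptom scores, when enabled
    for a group, are ``coupling * beta_i + noise``.
    """
    rng = np.random.default_rng(config.seed)
    geom = make_geometry(config.n_parcels, seed=config.seed)
    if config.gradient_map is not None:
        gradient = np.asarray(config.gradient_map, dtype=float)
        if len(gradient) != geom.n_parcels:
            raise ValueError("gradient_map length must match n_parcels")
    else:
        # hierarchy surrogate: smooth map with a posterior-anterior trend
        gradient = simulate_smooth_map(geom, 0.8, seed=config.seed + 101)
        gradient = gradient + geom.anat_xyz[:, 1] / _ANAT_SCALE[1]

    beta = config.signature_amplitude
    for grp, pats in config.signature_patterns.items():
        for p, vals in pats.items():
            if len(np.asarray(vals)) != geom.n_parcels:
                raise ValueError(f"signature pattern {grp}/{p} has wrong length")
    patterned = {g for g in config.group_sizes if g in config.signature_patterns}
    if beta != 0 and not patterned and any(
        g not in ("control", "placebo") and g not in config.paired_with
        for g in config.group_sizes
    ):
        # non-baseline groups exist but no pattern was supplied
        raise ValueError("signature_patterns required when signature_amplitude != 0")

    records: list[SubjectRecord] = []
    baseline_maps: dict[str, dict[str, NDArray[np.float64]]] = {}

    def fresh_maps(sub_seed: int) -> dict[str, NDArray[np.float64]]:
        out = {}
        for j, p in enumerate(PARAMETER_ORDER):
            noise = simulate_smooth_map(
                geom, config.smoothness_length_scale, seed=sub_seed + j, sd=config.noise_sd
            )
            out[p] = gradient + noise
        return out

    counter = 0
    # baseline groups first so paired groups can reuse their subjects
    ordered = sorted(
        config.group_sizes, key=lambda g: (g in config.paired_with, g)
    )
    for grp in ordered:
        n = config.group_sizes[grp]
        pats = config.signature_patterns.get(grp, {})
        has_pattern = bool(pats) and beta != 0
        betas = _truncated_normal(beta, abs(beta) / 2.0, n, rng) if has_pattern else np.zeros(n)
        base_grp = config.paired_with.get(grp)
        for i in range(n):
            counter += 1
            if base_grp is not None:
                sid = f"{base_grp}_{i:03d}"
                base = baseline_maps.get(sid)
                if base is None:
                    raise ValueError(
                        f"paired group {grp!r} has no subject {sid!r} in {base_grp!r}"
                    )
                maps = {
                    p: base[p]
                    + simulate_smooth_map(
                        geom,
                        config.smoothness_length_scale,
                        seed=int(rng.integers(2**31)),
                        sd=config.noise_sd / 2.0,
                    )
                    for p in PARAMETER_ORDER
                }
            else:
                sid = f"{grp}_{i:03d}"
                maps = fresh_maps(int(rng.integers(2**31)))
                baseline_maps[sid] = {p: v.copy() for p, v in maps.items()}
            if has_pattern:
                for p, pat in pats.items():
                    maps[p] = maps[p] + betas[i] * np.asarray(pat, dtype=float)
            symptoms = None
            if grp in config.symptom_groups:
                c_pos, c_neg = config.symptom_coupling
                symptoms = (
                    float(c_pos * betas[i] + rng.normal(0, config.symptom_noise_sd)),
                    float(c_neg * betas[i] + rng.normal(0, config.symptom_noise_sd)),
                )
            records.append(SubjectRecord(sid, grp, maps, symptoms))
    return records, geom
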