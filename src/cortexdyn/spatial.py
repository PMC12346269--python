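"""Spatial statistics on parcellated maps.

Spearman map correlations with spin-rotation (spatial autocorrelation
preserving) permutation nulls, anatomical-axis polynomial fits with nested
F-tests, Moran's I, and percentile bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import stats
from scipy.spatial.transform import Rotation

from .synthetic import ParcelGeometry, great_circle_distances

__all__ = [
    "SpatialStatResult",
    "AxisFitResult",
    "spearman_map_corr",
    "spin_rotations",
    "apply_rotation",
    "spin_pvalue",
    "axis_projection_fit",
    "morans_i",
    "bootstrap_ci",
]


@dataclass
class SpatialStatResult:
    statistic_name: str
    value: float
    p_value: float = float("nan")
    ci: tuple[float, float] | None = None
    null_values: NDArray[np.float64] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


@dataclass
class AxisFitResult:
    axis: str
    order: int
    coefficients: NDArray[np.float64]  # highest degree first (np.polyfit order)
    r_squared: float
    p_value: float

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")


def _joint_ok(a: NDArray[np.float64], b: NDArray[np.float64]) -> NDArray[np.bool_]:
    return np.isfinite(a) & np.isfinite(b)


def spearman_map_corr(map_a, map_b) -> float:
    """Spearman rank correlation over jointly non-missing parcels."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("maps must have equal length")
    ok = _joint_ok(a, b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 jointly non-missing parcels")
    rho = stats.spearmanr(a[ok], b[ok]).statistic
    return float(rho)


def spin_rotations(
    geometry: ParcelGeometry, n_rotations: int, seed: int = 0
) -> NDArray[np.int64]:
    """Parcel reassignment indices for uniformly random sphere rotations.

    Returns an (n_rotations, n_parcels) integer array: entry [r, i] is the
    source parcel whose rotated centroid lies closest to original parcel i.
    Medial-wall parcels are never used as sources (the next closest parcel
    is taken instead), and medial-wall targets keep the identity index.
    """
    rng = np.random.default_rng(seed)
    pts = geometry.sphere_xyz
    mw = geometry.medial_wall
    usable = np.flatnonzero(~mw)
    out = np.empty((n_rotations, geometry.n_parcels), dtype=np.int64)
    for r in range(n_rotations):
        rot = Rotation.random(rng=rng).as_matrix()
        rotated = pts[usable] @ rot.T
        # cosine similarity == negative great-circle distance ordering
        sim = pts @ rotated.T
        nearest = usable[np.argmax(sim, axis=1)]
        nearest[mw] = np.flatnonzero(mw)  # medial-wall targets left in place
        out[r] = nearest
    return out


def apply_rotation(values, reassignment: NDArray[np.int64]):
    """Permute a map (or the rows of a parcels x k stack) by one spin."""
    v = np.asarray(values, dtype=float)
    return v[reassignment]


def spin_pvalue(
    statistic_fn,
    map_a,
    map_b,
    rotation_log: NDArray[np.int64],
    alternative: str = "two-sided",
    statistic_name: str = "spearman_rho",
) -> SpatialStatResult:
    """Spin-permutation p-value for ``statistic_fn(map_a, map_b)``.

    ``map_a`` may be 1-D (one map) or 2-D (parcels x parameters); all of
    its columns are rotated with the same spin within a permutation. The
    p-value uses the add-one correction
    ``(1 + #{null at least as extreme}) / (1 + n_rotations)``.
    """
    a = np.asarray(map_a, dtype=float)
    observed = float(statistic_fn(a, map_b))
    null = []
    skipped = 0
    for reassign in rotation_log:
        try:
            null.append(float(statistic_fn(apply_rotation(a, reassign), map_b)))
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} rotation(s) skipped (undefined statistic)",
                      stacklevel=2)
    null_arr = np.asarray(null)
    if alternative == "two-sided":
        exceed = np.sum(np.abs(null_arr) >= abs(observed))
    elif alternative == "greater":
        exceed = np.sum(null_arr >= observed)
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    p = (1.0 + exceed) / (1.0 + len(null_arr))
    return SpatialStatResult(statistic_name, observed, float(p), null_values=null_arr)


def axis_projection_fit(
    map_values,
    geometry: ParcelGeometry,
    axis: str,
    alpha: float = 0.05,
    max_order: int = 5,
) -> AxisFitResult:
    """Increasing-order polynomial fit of a map against an anatomical axis.

    Orders n = 1, 2, ... are fit by least squares; fitting stops when order
    n+1 fails to improve on order n by the nested-model F test at ``alpha``
    (or ``max_order`` is reached). The returned p-value is the F-test of
    the selected model against the next-simpler one (a constant for n=1).
    """
    y = np.asarray(map_values, dtype=float).ravel()
    x = geometry.axis_values(axis)
    ok = _joint_ok(y, x)
    if np.ptp(x[ok]) == 0:
        raise ValueError("degenerate axis: no variation in coordinates")
    x, y = x[ok], y[ok]
    n_obs = len(y)

    def rss_for(order: int):
        if n_obs < order + 2:
            return None, None
        coeffs = np.polyfit(x, y, order)
        resid = y - np.polyval(coeffs, x)
        return float(np.sum(resid**2)), coeffs

    def f_test(rss_small, df_small, rss_big, df_big):
        # df = number of fitted parameters
        num = (rss_small - rss_big) / (df_big - df_small)
        den = rss_big / max(n_obs - df_big, 1)
        if den <= 0:
            return 0.0
        f = max(num / den, 0.0)
        return float(stats.f.sf(f, df_big - df_small, n_obs - df_big))

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("degenerate map: zero variance")
    rss_prev = tss  # order-0 (constant) model
    df_prev = 1
    rss1, coeffs1 = rss_for(1)
    if rss1 is None:
        raise ValueError("too few non-missing parcels for a linear fit")
    selected = (1, coeffs1, rss1, f_test(rss_prev, df_prev, rss1, 2))
    rss_prev, df_prev, coeffs_prev = rss1, 2, coeffs1
    order = 1
    while order < max_order:
        rss_next, coeffs_next = rss_for(order + 1)
        if rss_next is None:
            break
        p_improve = f_test(rss_prev, df_prev, rss_next, df_prev + 1)
        if p_improve >= alpha:
            break
        order += 1
        selected = (order, coeffs_next, rss_next, p_improve)
        rss_prev, df_prev = rss_next, df_prev + 1
    order, coeffs, rss, p = selected
    r2 = 1.0 - rss / tss
    return AxisFitResult(axis, order, np.asarray(coeffs), float(np.clip(r2, 0, 1)), p)


def knn_weights(
    geometry: ParcelGeometry, k: int = 6, indices: NDArray[np.int64] | None = None
) -> NDArray[np.float64]:
    """Row-normalized k-nearest-neighbour weights on sphere centroids."""
    pts = geometry.sphere_xyz if indices is None else geometry.sphere_xyz[indices]
    d = great_circle_distances(pts)
    n = len(d)
    if n <= k:
        k = max(n - 1, 1)
    w = np.zeros((n, n))
    order = np.argsort(d, axis=1)
    for i in range(n):
        w[i, order[i, 1 : k + 1]] = 1.0
    return w / w.sum(axis=1, keepdims=True)


def morans_i(
    map_values,
    geometry: ParcelGeometry | None = None,
    weights: NDArray[np.float64] | None = None,
    k: int = 6,
    statistic_name: str = "morans_I",
) -> SpatialStatResult:
    """Moran's I spatial autocorrelation with row-normalized weights.

    Weights default to k-nearest-neighbour adjacency on the sphere
    centroids of the non-missing parcels; a custom (already masked) weight
    matrix may be supplied instead.
    """
    v = np.asarray(map_values, dtype=float).ravel()
    ok = np.isfinite(v)
    if ok.sum() < 3:
        raise ValueError("need >= 3 non-missing parcels")
    z = v[ok] - v[ok].mean()
    if np.all(z == 0):
        raise ValueError("degenerate input: zero variance")
    if weights is None:
        if geometry is None:
            raise ValueError("provide a geometry or an explicit weight matrix")
        w = knn_weights(geometry, k=k, indices=np.flatnonzero(ok))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (ok.sum(), ok.sum()):
            raise ValueError("weight matrix shape must match non-missing parcels")
    s0 = w.sum()
    i_val = (len(z) / s0) * float(z @ w @ z) / float(z @ z)
    return SpatialStatResult(statistic_name, i_val)


def bootstrap_ci(
    statistic_fn,
    sample,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval of ``statistic_fn`` over resamples.

    ``sample`` is an array (or tuple of arrays resampled jointly along the
    first axis). Resamples on which the statistic is undefined are redrawn.
    """
    if isinstance(sample, tuple):
        arrs = [np.asarray(s) for s in sample]
    else:
        arrs = [np.asarray(sample)]
    n = len(arrs[0])
    if n < 2:
        raise ValueError("sample size must be >= 2")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            try:
                picked = [a[idx] for a in arrs]
                vals[b] = statistic_fn(*picked) if isinstance(sample, tuple) \
                    else statistic_fn(picked[0])
                if np.isfinite(vals[b]):
                    break
            except ValueError:
                pass
            redraws += 1
        else:
            raise RuntimeError("statistic undefined on 100 consecutive resamples")
    if redraws:
        warnings.warn(f"{redraws} resample(s) redrawn", stacklevel=2)
    lo_q = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * lo_q, 100 * (1 - lo_q)])
    return float(lo), float(hi)
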