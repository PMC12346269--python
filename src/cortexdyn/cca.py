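"""Canonical correlation analysis between two parcels-x-parameters map sets.

The fit follows the QR + SVD construction: with column-centered X = QxRx
and Y = QyRy, the SVD Qx'Qy = USV' yields weights Wx = Rx^-1 U,
Wy = Ry^-1 V, canonical variables Zx = XWx, Zy = YWy, and canonical
correlations diag(S), reported in descending order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import stats

from .spatial import SpatialStatResult, apply_rotation, spearman_map_corr

__all__ = [
    "CCAResult",
    "fit_cca",
    "explained_covariance",
    "cca_loadings",
    "cca_significance",
    "cca_reproducibility",
]


@dataclass
class CCAResult:
    weights_x: NDArray[np.float64]  # (k, k)
    weights_y: NDArray[np.float64]
    zx: NDArray[np.float64]  # (n_complete_rows, k)
    zy: NDArray[np.float64]
    correlations: NDArray[np.float64]  # descending
    row_mask: NDArray[np.bool_]  # complete rows used in the fit
    qx: NDArray[np.float64] = field(repr=False, default=None)
    rx: NDArray[np.float64] = field(repr=False, default=None)
    qy: NDArray[np.float64] = field(repr=False, default=None)
    ry: NDArray[np.float64] = field(repr=False, default=None)
    svd_u: NDArray[np.float64] = field(repr=False, default=None)
    svd_s: NDArray[np.float64] = field(repr=False, default=None)
    svd_vt: NDArray[np.float64] = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return len(self.correlations)


def _complete_rows(X: NDArray[np.float64], Y: NDArray[np.float64]):
    ok = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    return ok


def fit_cca(X, Y) -> CCAResult:
    """Fit CCA via thin QR of the centered blocks and SVD of Qx'Qy.

    Rows with any missing entry in either block are dropped listwise (the
    count is logged via a warning when nonzero). Raises a degenerate-input
    error naming the offending columns if either triangular factor is
    rank-deficient.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    ok = _complete_rows(X, Y)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} incomplete row(s) before CCA", stacklevel=2)
    Xc = X[ok] - X[ok].mean(axis=0)
    Yc = Y[ok] - Y[ok].mean(axis=0)
    n, kx = Xc.shape
    ky = Yc.shape[1]
    if n <= max(kx, ky):
        raise ValueError("need more complete rows than columns")
    qx, rx = np.linalg.qr(Xc)
    qy, ry = np.linalg.qr(Yc)
    for name, r, mat in (("X", rx, Xc), ("Y", ry, Yc)):
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1e-300))
        if len(bad):
            raise ValueError(
                f"rank-deficient {name} block: columns {bad.tolist()} are "
                "linearly dependent"
            )
    u, s, vt = np.linalg.svd(qx.T @ qy)
    # numpy returns singular values descending already; keep that order
    wx = np.linalg.solve(rx, u)
    wy = np.linalg.solve(ry, vt.T)
    zx = Xc @ wx
    zy = Yc @ wy
    return CCAResult(wx, wy, zx, zy, s.copy(), ok, qx, rx, qy, ry, u, s, vt)


def explained_covariance(result: CCAResult) -> NDArray[np.float64]:
    """Fraction of explained covariance per canonical pair: R_i^2 / sum R^2."""
    r2 = result.correlations**2
    total = r2.sum()
    if total <= 0:
        raise ValueError("all canonical correlations are zero")
    return r2 / total


def cca_loadings(
    result: CCAResult, X, Y, component: int = 0
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Pearson correlations of each original column with its own block's
    canonical variable (default: the first pair).

    Both canonical variables are sign-oriented so the largest-magnitude
    X-side loading is positive; the same flip is applied to the Y side so
    the pair's correlation is preserved.
    """
    X = np.asarray(X, dtype=float)[result.row_mask]
    Y = np.asarray(Y, dtype=float)[result.row_mask]
    zx = result.zx[:, component]
    zy = result.zy[:, component]

    def block_loadings(mat, z):
        out = np.full(mat.shape[1], np.nan)
        for j in range(mat.shape[1]):
            col = mat[:, j]
            if np.std(col) == 0 or np.std(z) == 0:
                warnings.warn(f"zero-variance column {j}: loading undefined",
                              stacklevel=3)
                continue
            out[j] = np.corrcoef(col, z)[0, 1]
        return out

    lx = block_loadings(X, zx)
    ly = block_loadings(Y, zy)
    imax = int(np.nanargmax(np.abs(lx)))
    if lx[imax] < 0:
        lx, ly = -lx, -ly
    return lx, ly


def cca_significance(
    X, Y, rotation_log: NDArray[np.int64], component: int = 0
) -> SpatialStatResult:
    """Spin-permutation p-value for a canonical correlation.

    Every column of X is rotated with the same spin within a permutation,
    the CCA refit, and the chosen canonical correlation recorded. One-sided
    (canonical correlations are nonnegative), add-one corrected.
    """
    X = np.asarray(X, dtype=float)
    observed = float(fit_cca(X, Y).correlations[component])
    null = []
    for reassign in rotation_log:
        try:
            null.append(float(fit_cca(apply_rotation(X, reassign), Y)
                              .correlations[component]))
        except ValueError:
            continue
    null_arr = np.asarray(null)
    p = (1.0 + np.sum(null_arr >= observed)) / (1.0 + len(null_arr))
    return SpatialStatResult("canonical_r", observed, float(p), null_values=null_arr)


def cca_reproducibility(
    result_list: list[CCAResult],
    X_list,
    Y_list,
    rotation_log: NDArray[np.int64] | None = None,
) -> dict:
    """Cross-fit similarity of first canonical variables and loadings.

    For every pair of fits: Spearman correlations between the X-side first
    canonical variables, between the Y-side ones, and between each block's
    loading vectors (absolute values, since canonical signs are arbitrary).
    Optionally spin p-values for the map-level correlations.
    """
    m = len(result_list)
    if m < 2:
        raise ValueError("need at least two fitted CCAs")
    n_parcels = {len(r.row_mask) for r in result_list}
    if len(n_parcels) != 1:
        raise ValueError("all fits must share one geometry (parcel count)")
    n = n_parcels.pop()

    def full_variable(res: CCAResult, side: str):
        z = np.full(n, np.nan)
        z[res.row_mask] = (res.zx if side == "x" else res.zy)[:, 0]
        return z

    loadings = [cca_loadings(r, x, y) for r, x, y in zip(result_list, X_list, Y_list)]
    out = {
        "zx_corr": np.full((m, m), np.nan),
        "zy_corr": np.full((m, m), np.nan),
        "loadings_x_corr": np.full((m, m), np.nan),
        "loadings_y_corr": np.full((m, m), np.nan),
    }
    if rotation_log is not None:
        out["zx_p"] = np.full((m, m), np.nan)
        out["zy_p"] = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(m):
            if i == j:
                for key in out:
                    out[key][i, j] = 1.0 if not key.endswith("_p") else np.nan
                continue
            zxi, zxj = full_variable(result_list[i], "x"), full_variable(result_list[j], "x")
            zyi, zyj = full_variable(result_list[i], "y"), full_variable(result_list[j], "y")
            out["zx_corr"][i, j] = abs(spearman_map_corr(zxi, zxj))
            out["zy_corr"][i, j] = abs(spearman_map_corr(zyi, zyj))
            out["loadings_x_corr"][i, j] = abs(
                stats.spearmanr(loadings[i][0], loadings[j][0]).statistic)
            out["loadings_y_corr"][i, j] = abs(
                stats.spearmanr(loadings[i][1], loadings[j][1]).statistic)
            if rotation_log is not None:
                from .spatial import spin_pvalue
                out["zx_p"][i, j] = spin_pvalue(
                    lambda a, b: abs(spearman_map_corr(a, b)), zxi, zxj,
                    rotation_log, alternative="greater").p_value
                out["zy_p"][i, j] = spin_pvalue(
                    lambda a, b: abs(spearman_map_corr(a, b)), zyi, zyj,
                    rotation_log, alternative="greater").p_value
    return out
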