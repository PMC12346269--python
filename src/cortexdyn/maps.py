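"""Map-level derived quantities: hemisphere averaging, z-scoring, and
group difference ("signature" / "drug effect") maps.

All functions treat NaN as an explicit missing value and propagate it
parcel-wise rather than dropping subjects listwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "GroupDifferenceMap",
    "average_hemispheres",
    "zscore_map",
    "group_difference_map",
    "drug_effect_map",
]


@dataclass
class GroupDifferenceMap:
    values: NDArray[np.float64]
    mode: str  # "t_score" | "mean_diff"
    group_labels: tuple[str, str] = ("A", "B")
    parameter_label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("t_score", "mean_diff"):
            raise ValueError("mode must be 't_score' or 'mean_diff'")
        self.values = np.asarray(self.values, dtype=float).ravel()


def average_hemispheres(
    map_2h: NDArray[np.float64], homotopic_pairs: NDArray[np.int64]
) -> NDArray[np.float64]:
    """Mean of homotopic (left, right) parcel pairs; one-sided values pass
    through, double-missing stays missing. Output has half the length."""
    v = np.asarray(map_2h, dtype=float).ravel()
    pairs = np.asarray(homotopic_pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("homotopic_pairs must have shape (n_pairs, 2)")
    flat = pairs.ravel()
    if len(flat) != len(v) or len(np.unique(flat)) != len(v) or flat.min() < 0 or flat.max() >= len(v):
        raise ValueError("pairing table must cover every parcel exactly once")
    left, right = v[pairs[:, 0]], v[pairs[:, 1]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.column_stack([left, right]), axis=1)


def zscore_map(values: NDArray[np.float64]) -> NDArray[np.float64]:
    """(x - mean) / SD over non-missing parcels, NaN preserved."""
    v = np.asarray(values, dtype=float).ravel()
    ok = np.isfinite(v)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing values to z-score")
    sd = v[ok].std(ddof=0)
    # ptp guard: identical values can still give sd != 0 via mean roundoff
    if sd == 0 or np.ptp(v[ok]) == 0:
        raise ValueError("degenerate input: zero variance across parcels")
    out = np.full_like(v, np.nan)
    out[ok] = (v[ok] - v[ok].mean()) / sd
    return out


def _stack(maps) -> NDArray[np.float64]:
    arr = np.asarray([np.asarray(m, dtype=float).ravel() for m in maps])
    if arr.ndim != 2:
        raise ValueError("expected a collection of equal-length parcel maps")
    return arr


def group_difference_map(
    groupA_maps,
    groupB_maps,
    mode: str = "mean_diff",
    group_labels: tuple[str, str] = ("A", "B"),
    parameter_label: str = "",
) -> GroupDifferenceMap:
    """Per-parcel group contrast.

    ``mean_diff``: mean(A) - mean(B) over non-missing subjects per parcel
    (at least one subject per side). ``t_score``: pooled-variance two-sample
    t statistic with per-parcel ns (at least two per side). Parcels failing
    the count requirement come back NaN; if every parcel fails, an error is
    raised.
    """
    A, B = _stack(groupA_maps), _stack(groupB_maps)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the parcel grid")
    nA = np.isfinite(A).sum(axis=0)
    nB = np.isfinite(B).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mA, mB = np.nanmean(A, axis=0), np.nanmean(B, axis=0)
        if mode == "mean_diff":
            out = np.where((nA >= 1) & (nB >= 1), mA - mB, np.nan)
        elif mode == "t_score":
            vA, vB = np.nanvar(A, axis=0, ddof=1), np.nanvar(B, axis=0, ddof=1)
            ok = (nA >= 2) & (nB >= 2)
            sp2 = ((nA - 1) * vA + (nB - 1) * vB) / np.maximum(nA + nB - 2, 1)
            se = np.sqrt(sp2 * (1.0 / np.maximum(nA, 1) + 1.0 / np.maximum(nB, 1)))
            out = np.where(ok & (se > 0), (mA - mB) / np.where(se > 0, se, 1.0), np.nan)
            out[ok & (se == 0) & (mA == mB)] = 0.0
        else:
            raise ValueError("mode must be 'mean_diff' or 't_score'")
    if not np.isfinite(out).any():
        raise ValueError("no parcel satisfies the per-group subject minimum")
    return GroupDifferenceMap(out, mode, group_labels, parameter_label)


def drug_effect_map(
    drug_subject_maps: dict,
    placebo_subject_maps: dict,
    paired_ids=None,
    zscore: bool = True,
    parameter_label: str = "",
) -> GroupDifferenceMap:
    """Within-subject drug-minus-placebo contrast, averaged over subjects.

    Both inputs map subject_id -> parcel values; each subject's maps are
    z-scored before differencing (the analysis path). Unpaired subjects are
    excluded with a warning; if nobody pairs up, an error is raised.
    """
    if paired_ids is None:
        paired_ids = sorted(set(drug_subject_maps) & set(placebo_subject_maps))
    unpaired = (set(drug_subject_maps) | set(placebo_subject_maps)) - set(paired_ids)
    if unpaired:
        warnings.warn(f"excluding {len(unpaired)} unpaired subject(s)", stacklevel=2)
    diffs = []
    for sid in paired_ids:
        if sid not in drug_subject_maps or sid not in placebo_subject_maps:
            warnings.warn(f"excluding unpaired subject {sid!r}", stacklevel=2)
            continue
        d = np.asarray(drug_subject_maps[sid], dtype=float)
        p = np.asarray(placebo_subject_maps[sid], dtype=float)
        if zscore:
            d, p = zscore_map(d), zscore_map(p)
        diffs.append(d - p)
    if not diffs:
        raise ValueError("no paired subjects available")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.asarray(diffs), axis=0)
    return GroupDifferenceMap(mean, "mean_diff", ("drug", "placebo"), parameter_label)
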