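"""Per-subject pattern similarity and symptom coupling.

Individual signature vectors (six parameter maps stacked vertically) are
correlated with reference drug-effect vectors; the resulting similarities
are related to symptom scores, including a permutation test for the
drug-by-symptom-dimension double dissociation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import stats

from .spatial import SpatialStatResult
from .synthetic import PARAMETER_ORDER

__all__ = [
    "SimilarityProfile",
    "concat_parameters_vertical",
    "individual_similarity",
    "symptom_correlation",
    "double_dissociation_test",
]


@dataclass
class SimilarityProfile:
    subject_id: str
    u: NDArray[np.float64]
    r_per_drug: dict
    p_per_drug: dict


def concat_parameters_vertical(
    subject_maps: dict, parameter_order=PARAMETER_ORDER
) -> NDArray[np.float64]:
    """Stack one subject's parameter maps into a single column vector.

    Blocks follow ``parameter_order`` regardless of dict insertion order;
    parcels keep geometry order within each block. Length is
    n_parameters x n_parcels. Missing entries stay NaN.
    """
    unknown = set(subject_maps) - set(parameter_order)
    if unknown:
        raise ValueError(f"unknown parameter label(s): {sorted(unknown)}")
    missing = set(parameter_order) - set(subject_maps)
    if missing:
        raise ValueError(f"missing parameter map(s): {sorted(missing)}")
    blocks = [np.asarray(subject_maps[p], dtype=float).ravel()
              for p in parameter_order]
    lengths = {len(b) for b in blocks}
    if len(lengths) != 1:
        raise ValueError("all parameter maps must share the parcel grid")
    return np.concatenate(blocks)


def _rank_corr(a, b, method: str = "spearman") -> float:
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError("method must be 'spearman' or 'pearson'")


def individual_similarity(
    u_i,
    v_ref,
    rotation_log: NDArray[np.int64] | None = None,
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlation of one subject's concatenated signature with a reference
    drug-effect vector, plus a spin p-value.

    Both vectors hold n_parameters blocks of n_parcels entries; within a
    permutation one shared parcel reassignment is applied to every block of
    ``u_i``. Returns ``(r, p)``; p is NaN without a rotation log.
    """
    u = np.asarray(u_i, dtype=float).ravel()
    v = np.asarray(v_ref, dtype=float).ravel()
    if len(u) != len(v):
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(u) & np.isfinite(v)
    if ok.sum() < 30:
        raise ValueError("need >= 30 jointly non-missing entries")
    r = _rank_corr(u[ok], v[ok], method)
    if rotation_log is None:
        return r, float("nan")
    n_parcels = rotation_log.shape[1]
    if len(u) % n_parcels:
        raise ValueError("vector length must be a multiple of the parcel count")
    n_blocks = len(u) // n_parcels
    ub = u.reshape(n_blocks, n_parcels)
    null = np.empty(len(rotation_log))
    for t, reassign in enumerate(rotation_log):
        up = ub[:, reassign].ravel()
        okp = np.isfinite(up) & np.isfinite(v)
        null[t] = _rank_corr(up[okp], v[okp], method)
    p = (1.0 + np.sum(np.abs(null) >= abs(r))) / (1.0 + len(null))
    return r, float(p)


def symptom_correlation(
    similarities,
    symptom_scores,
    n_perm: int = 10000,
    seed: int = 0,
    method: str = "spearman",
) -> SpatialStatResult:
    """Rank correlation between per-subject similarities and symptom scores
    with a subject-level permutation p-value (two-sided, add-one)."""
    r_vec = np.asarray(similarities, dtype=float).ravel()
    s_vec = np.asarray(symptom_scores, dtype=float).ravel()
    if len(r_vec) != len(s_vec) or len(r_vec) < 5:
        raise ValueError("need >= 5 paired (similarity, score) observations")
    if np.ptp(s_vec) == 0:
        raise ValueError("degenerate input: constant symptom scores")
    observed = _rank_corr(r_vec, s_vec, method)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        null[t] = _rank_corr(r_vec, rng.permutation(s_vec), method)
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return SpatialStatResult("symptom_corr", observed, float(p), null_values=null)


def double_dissociation_test(
    sim_drug_a,
    sim_drug_b,
    positive_scores,
    negative_scores,
    n_perm: int = 10000,
    seed: int = 0,
    method: str = "spearman",
) -> tuple[float, float]:
    """Permutation test of the drug x symptom-dimension interaction.

    Statistic: ``[r(simA, pos) - r(simA, neg)] - [r(simB, pos) - r(simB, neg)]``.
    The null jointly permutes each subject's (pos, neg) score pair across
    subjects, preserving the dependence between the two dimensions.
    Returns ``(delta, p)``, two-sided with the add-one correction.
    """
    a = np.asarray(sim_drug_a, dtype=float).ravel()
    b = np.asarray(sim_drug_b, dtype=float).ravel()
    pos = np.asarray(positive_scores, dtype=float).ravel()
    neg = np.asarray(negative_scores, dtype=float).ravel()
    n = len(a)
    if not (len(b) == len(pos) == len(neg) == n):
        raise ValueError("all four vectors must be paired over the same subjects")
    if n < 8:
        raise ValueError("n < 8: the double-dissociation test is uninformative")

    def standardize(x):
        r = stats.rankdata(x) if method == "spearman" else np.asarray(x, float)
        r = r - r.mean()
        nrm = np.linalg.norm(r)
        if nrm == 0:
            raise ValueError("degenerate input: constant vector")
        return r / nrm

    # with unit-norm centered (rank) vectors, every correlation is a dot
    # product and permuting a score pair permutes its rank vector, so
    # delta = (u_a - u_b) . (u_pos - u_neg)[perm]
    d_sim = standardize(a) - standardize(b)
    d_score = standardize(pos) - standardize(neg)
    observed = float(d_sim @ d_score)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        null[t] = d_sim @ d_score[rng.permutation(n)]
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return float(observed), float(p)
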