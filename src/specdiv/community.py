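"""Correspondence analysis of cell x species abundance tables, supplementary
projection of predicted tables, Ward assemblage typing with bootstrap
uncertainty, and between-type species-set similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)


@dataclass
class CAResult:
    """SVD-based correspondence analysis of a nonnegative table."""

    row_scores: pd.DataFrame  # principal coordinates, axes as columns
    col_scores: pd.DataFrame  # principal coordinates
    col_standard: pd.DataFrame  # standard coordinates (for projection)
    singular_values: np.ndarray
    axis_inertia: np.ndarray  # squared singular values
    total_inertia: float  # chi-squared statistic / grand total
    row_mass: pd.Series = field(repr=False, default=None)
    col_mass: pd.Series = field(repr=False, default=None)


def correspondence_analysis(N: pd.DataFrame, max_axes: int | None = None) -> CAResult:
    """Correspondence analysis of a cells x species count table.

    All-zero rows/columns are dropped with a warning.  The standardized
    residual matrix ``S = D_r^{-1/2} (P - r c') D_c^{-1/2}`` (with
    ``P = N / n``) is decomposed by SVD; axis inertias are the squared
    singular values and sum to the table's chi-squared statistic over its
    grand total.
    """
    if not isinstance(N, pd.DataFrame):
        N = pd.DataFrame(np.asarray(N, dtype=float))
    M = N.to_numpy(dtype=float)
    if np.any(M < 0):
        raise ValueError("table must be nonnegative")
    rz, cz = M.sum(axis=1) == 0, M.sum(axis=0) == 0
    if rz.any() or cz.any():
        logger.warning("dropping %d all-zero rows and %d all-zero columns",
                       int(rz.sum()), int(cz.sum()))
        N = N.loc[~rz, ~cz]
        M = N.to_numpy(dtype=float)
    if M.size == 0 or M.sum() == 0:
        raise ValueError("table has rank 0")

    n = M.sum()
    P = M / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # drop the numerically-zero trivial dimensions
    keep = sv > 1e-12 * max(sv[0], 1.0) if sv.size else np.array([], bool)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    if max_axes is not None:
        U, sv, Vt = U[:, :max_axes], sv[:max_axes], Vt[:max_axes]

    axes = [f"CA{i + 1}" for i in range(len(sv))]
    row_scores = (U * sv) / np.sqrt(r)[:, None]
    col_standard = Vt.T / np.sqrt(c)[:, None]
    col_scores = col_standard * sv

    return CAResult(
        row_scores=pd.DataFrame(row_scores, index=N.index, columns=axes),
        col_scores=pd.DataFrame(col_scores, index=N.columns, columns=axes),
        col_standard=pd.DataFrame(col_standard, index=N.columns, columns=axes),
        singular_values=sv,
        axis_inertia=sv**2,
        total_inertia=float(np.sum(sv**2)),
        row_mass=pd.Series(r, index=N.index),
        col_mass=pd.Series(c, index=N.columns),
    )


def project_rows(ca: CAResult, N_new: pd.DataFrame) -> pd.DataFrame:
    """Project new rows as supplementary points onto the fitted axes.

    Row profiles times the fitted column standard coordinates; on the
    training table this reproduces the fitted row scores.
    """
    if not isinstance(N_new, pd.DataFrame):
        N_new = pd.DataFrame(np.asarray(N_new, dtype=float), columns=ca.col_standard.index)
    try:
        M = N_new[ca.col_standard.index].to_numpy(dtype=float)
    except KeyError as e:
        raise ValueError("species set does not match the fitted CA") from e
    tot = M.sum(axis=1, keepdims=True)
    if np.any(tot == 0):
        logger.warning("%d all-zero rows project to the origin", int((tot == 0).sum()))
    profiles = np.divide(M, tot, out=np.zeros_like(M), where=tot > 0)
    scores = profiles @ ca.col_standard.to_numpy()
    return pd.DataFrame(scores, index=N_new.index, columns=ca.col_standard.columns)


@dataclass
class AssemblageTyping:
    labels: pd.Series  # per-cell type in 1..k
    uncertainty: pd.Series  # per-cell bootstrap label-instability in [0, 1]
    type_uncertainty: pd.Series  # mean per type
    linkage_matrix: np.ndarray = field(repr=False, default=None)


def _match_labels(ref: np.ndarray, new: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``new`` to maximize overlap with ``ref`` (Hungarian)."""
    cont = np.zeros((k, k))
    for a, b in zip(ref, new):
        cont[a - 1, b - 1] += 1
    rows, cols = linear_sum_assignment(-cont)
    mapping = {c + 1: r + 1 for r, c in zip(rows, cols)}
    return np.array([mapping[v] for v in new])


def assemblage_types(
    row_scores: pd.DataFrame,
    k: int = 4,
    n_axes: int = 5,
    n_boot: int = 100,
    seed: int = 0,
) -> AssemblageTyping:
    """Ward clustering of CA row scores into ``k`` assemblage types.

    Uses the first ``n_axes`` axes (or all available).  Per-cell uncertainty
    is the fraction of bootstrap re-clusterings (cells resampled with
    replacement, re-clustered, types matched to the reference by maximum
    overlap) in which the cell lands in a different type.
    """
    scores = row_scores.iloc[:, : min(n_axes, row_scores.shape[1])].to_numpy(dtype=float)
    n = scores.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of cells")
    if k == 1:
        labels = np.ones(n, dtype=int)
        link = None
    else:
        link = linkage(scores, method="ward")
        labels = fcluster(link, t=k, criterion="maxclust")

    rng = np.random.default_rng(seed)
    changed = np.zeros(n)
    appeared = np.zeros(n)
    if k > 1 and n_boot > 0:
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            uniq = np.unique(idx)
            if len(uniq) <= k:
                continue
            bl = fcluster(linkage(scores[uniq], method="ward"), t=k, criterion="maxclust")
            matched = _match_labels(labels[uniq], bl, k)
            appeared[uniq] += 1
            changed[uniq] += matched != labels[uniq]
    with np.errstate(invalid="ignore", divide="ignore"):
        unc = np.where(appeared > 0, changed / appeared, 0.0)

    labels_s = pd.Series(labels, index=row_scores.index, name="type")
    unc_s = pd.Series(unc, index=row_scores.index, name="uncertainty")
    return AssemblageTyping(
        labels=labels_s,
        uncertainty=unc_s,
        type_uncertainty=unc_s.groupby(labels_s).mean(),
        linkage_matrix=link,
    )


def type_species_set(
    counts: pd.DataFrame, cells: pd.Index, min_occupancy: float = 0.05
) -> set[str]:
    """Species present (abundance > 0) in at least ``min_occupancy`` of the
    type's cells."""
    sub = counts.loc[cells]
    occ = (sub > 0).mean(axis=0)
    return set(occ.index[occ >= min_occupancy])


def type_similarity(
    typing_a: pd.Index,
    typing_b: pd.Index,
    counts: pd.DataFrame,
    min_occupancy: float = 0.05,
) -> float:
    """Sørensen similarity (percent) of the species sets of two cell groups."""
    sa = type_species_set(counts, typing_a, min_occupancy)
    sb = type_species_set(counts, typing_b, min_occupancy)
    if not sa and not sb:
        return float("nan")
    return 200.0 * len(sa & sb) / (len(sa) + len(sb))


def sorensen(a: set, b: set) -> float:
    """Sørensen similarity 2|A∩B|/(|A|+|B|) as a percentage."""
    if not a and not b:
        return float("nan")
    return 200.0 * len(a & b) / (len(a) + len(b))
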