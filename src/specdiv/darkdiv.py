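"""Dark diversity from Beals-smoothing co-occurrence probabilities.

``beals_matrix`` computes, for every plot i and species j, the expected
probability of j in i given the plot's other species and the pairwise
co-occurrence frequencies; species-specific 5%-quantile thresholds over
occupied plots then decide whether an absent-but-probable species belongs to
the plot's dark diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_RICHNESS = 5  # plots must be richer than this to enter the analysis
DD_LISTING_SHARE = 0.15  # species in DD of > 15% of plots are listed


def beals_matrix(X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Beals smoothing: b_ij = (1/S_i^(-j)) * sum_{k != j, X_ik = 1} M_jk/N_k.

    ``M_jk`` counts plots containing both j and k, ``N_k`` plots containing
    k; the target species is excluded from the plot richness ``S_i^(-j)``
    and from the sum.  Plots whose richness (excluding j) is zero get
    ``b_ij = 0``; species never observed contribute nothing.
    """
    names = X.columns if isinstance(X, pd.DataFrame) else None
    index = X.index if isinstance(X, pd.DataFrame) else None
    A = (np.asarray(X) > 0).astype(float)
    n_plots, n_species = A.shape
    if n_plots < 2 or n_species < 2:
        raise ValueError("need at least 2 plots and 2 species")
    M = A.T @ A  # co-occurrence counts; diagonal = N
    N = np.diag(M).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        Q = np.where(N[None, :] > 0, M / N[None, :], 0.0)  # Q[j, k] = M_jk / N_k
    num = A @ Q.T - A * np.diag(Q)[None, :]  # exclude k = j
    S = A.sum(axis=1, keepdims=True)
    denom = S - A  # richness excluding the target species
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(denom > 0, num / denom, 0.0)
    return pd.DataFrame(b, index=index, columns=names)


def species_thresholds(
    b: pd.DataFrame, X: pd.DataFrame, q: float = 0.05
) -> pd.Series:
    """Per-species q-quantile (linear interpolation) of the Beals values over
    the plots where the species occurs.  Species with zero occurrences are
    skipped with a warning (NaN threshold)."""
    A = (X.to_numpy() > 0)
    bm = b.to_numpy()
    out = {}
    for j, sp in enumerate(X.columns):
        occ = A[:, j]
        if not occ.any():
            logger.warning("species %s has no occurrences; threshold undefined", sp)
            out[sp] = np.nan
            continue
        out[sp] = float(np.quantile(bm[occ, j], q))
    return pd.Series(out)


@dataclass
class DDReport:
    membership: pd.DataFrame  # plots x species boolean
    eligible: pd.Series  # per-plot eligibility (richness > min)
    per_plot_count: pd.Series
    mean_dd_per_plot: float
    species_share: pd.Series  # share of eligible plots with the species in DD
    frequent_species: list[str]  # in DD of > 15% of eligible plots
    per_region_counts: pd.Series | None = None


def dark_diversity(
    X: pd.DataFrame,
    b: pd.DataFrame,
    thresholds: pd.Series,
    min_richness: int = MIN_RICHNESS,
) -> pd.DataFrame:
    """Membership matrix: species j is in the dark diversity of plot i iff
    the plot is eligible (richness > ``min_richness``), the species is
    absent, and ``b_ij >= threshold_j``."""
    A = X.to_numpy() > 0
    richness = A.sum(axis=1)
    eligible = richness > min_richness
    th = thresholds.reindex(X.columns).to_numpy()
    with np.errstate(invalid="ignore"):
        member = (~A) & (b.to_numpy() >= th[None, :]) & ~np.isnan(th)[None, :]
    member &= eligible[:, None]
    return pd.DataFrame(member, index=X.index, columns=X.columns)


def dd_summaries(
    membership: pd.DataFrame,
    X: pd.DataFrame,
    min_richness: int = MIN_RICHNESS,
    regions: pd.Series | None = None,
    listing_share: float = DD_LISTING_SHARE,
) -> DDReport:
    """Aggregate a membership matrix into the dark-diversity report."""
    richness = (X.to_numpy() > 0).sum(axis=1)
    eligible = pd.Series(richness > min_richness, index=X.index)
    per_plot = membership.sum(axis=1)
    n_eligible = int(eligible.sum())
    mean_dd = float(per_plot[eligible].mean()) if n_eligible else 0.0
    share = membership.loc[eligible].mean(axis=0) if n_eligible else membership.mean(axis=0) * 0.0
    frequent = list(share.index[share > listing_share])
    per_region = None
    if regions is not None:
        has_dd = per_plot > 0
        per_region = has_dd[eligible].groupby(regions[eligible]).sum()
    return DDReport(
        membership=membership,
        eligible=eligible,
        per_plot_count=per_plot,
        mean_dd_per_plot=mean_dd,
        species_share=share,
        frequent_species=frequent,
        per_region_counts=per_region,
    )


def presence_matrix_from_plots(
    plot_abundances: list[dict[int, int]], legend: dict[int, str], plot_ids: list[str]
) -> pd.DataFrame:
    """Binary plots x species table from per-plot abundance dicts."""
    codes = sorted({c for ab in plot_abundances for c, n in ab.items() if n > 0})
    data = [[1 if ab.get(c, 0) > 0 else 0 for c in codes] for ab in plot_abundances]
    return pd.DataFrame(data, index=plot_ids, columns=[legend.get(c, str(c)) for c in codes])
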