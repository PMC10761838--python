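"""Species trait tables, community-weighted means, and convex-hull
functional richness / divergence.

Trait aggregation rules: per species per PA, crown-pixel index values are
trimmed to the central 95% and averaged; species occurring in several PAs
take the mean of per-PA means; maximum DBH is the mean of the two largest
recorded individuals; wood density and phenology are constant across PAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .classify import crown_footprint_pixels
from .spectral import IndexRaster
from .synthgen import FieldSurvey, SpeciesPool, SyntheticScene

logger = logging.getLogger(__name__)

BIOPHYSICAL_TRAITS = ("wood_density", "phenology", "max_dbh")
BIOCHEMICAL_TRAITS = ("CCI", "NIRvP", "NDWI")
INDEX_TRAITS = BIOCHEMICAL_TRAITS


def central_trim(values: np.ndarray, keep: float = 0.95) -> np.ndarray:
    """Keep the central ``keep`` fraction of values (percentile trimming)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return v
    lo, hi = np.percentile(v, [(1 - keep) / 2 * 100, (1 + keep) / 2 * 100])
    return v[(v >= lo) & (v <= hi)]


def max_dbh_from_records(dbh_values: np.ndarray) -> float:
    """Mean of the two largest recorded individuals (the single value if
    only one record exists)."""
    v = np.sort(np.asarray(dbh_values, dtype=float))
    if v.size == 0:
        return float("nan")
    return float(v[-2:].mean())


def species_index_means(
    scene: SyntheticScene,
    indices: dict[str, IndexRaster],
    trait_names: tuple[str, ...] = INDEX_TRAITS,
    keep: float = 0.95,
) -> pd.DataFrame:
    """Per-species mean index values from crown pixels in one scene,
    after central-95% trimming."""
    shape = scene.shape
    pixels: dict[str, dict[str, list[np.ndarray]]] = {}
    for crown in scene.crowns:
        rr, cc = crown_footprint_pixels(crown, shape)
        if rr.size == 0:
            continue
        own = scene.truth_map[rr, cc] == crown.species  # visible-canopy pixels only
        rr, cc = rr[own], cc[own]
        if rr.size == 0:
            continue
        bucket = pixels.setdefault(crown.species_id, {t: [] for t in trait_names})
        for t in trait_names:
            bucket[t].append(indices[t].values[rr, cc])
    rows = {}
    for sp, bucket in pixels.items():
        rows[sp] = {
            t: float(np.mean(central_trim(np.concatenate(bucket[t]), keep)))
            if bucket[t] else float("nan")
            for t in trait_names
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def build_trait_table(
    pool: SpeciesPool,
    per_pa_surveys: dict[str, FieldSurvey],
    per_pa_index_means: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Assemble the species x trait table.

    ``per_pa_index_means`` holds per-PA species means of the index traits
    (already trimmed, e.g. from :func:`species_index_means`).  DBH comes from
    the survey records per PA (mean of the two largest); species with fewer
    than two records in a PA fall back to the available records with a logged
    note, and to the pool's distribution median when a species was never
    recorded.  Per-PA values of a shared species are averaged.
    """
    dbh_records: dict[str, dict[str, list[float]]] = {}
    for pa, survey in per_pa_surveys.items():
        for q in survey.quadrats:
            for rec in q.records:
                dbh_records.setdefault(rec.species_id, {}).setdefault(pa, []).append(rec.dbh_m)

    rows = []
    for i, sp in enumerate(pool.species_ids):
        pa_list = [pool_pa for p, pool_pa in enumerate(per_pa_surveys) if pool.membership[i, p]] \
            if len(per_pa_surveys) == pool.n_pas else list(per_pa_surveys)

        per_pa_dbh = []
        for pa in pa_list:
            vals = dbh_records.get(sp, {}).get(pa, [])
            if len(vals) >= 2:
                per_pa_dbh.append(max_dbh_from_records(np.array(vals)))
            elif len(vals) == 1:
                logger.info("species %s at %s: single DBH record used", sp, pa)
                per_pa_dbh.append(vals[0])
        if per_pa_dbh:
            max_dbh = float(np.mean(per_pa_dbh))
        else:
            max_dbh = float(np.exp(pool.dbh_lognorm_mu[i]))
            logger.info("species %s: no DBH records; distribution median used", sp)

        idx_means = {}
        for t in INDEX_TRAITS:
            vals = [
                per_pa_index_means[pa].loc[sp, t]
                for pa in pa_list
                if pa in per_pa_index_means and sp in per_pa_index_means[pa].index
                and np.isfinite(per_pa_index_means[pa].loc[sp, t])
            ]
            idx_means[t] = float(np.mean(vals)) if vals else float("nan")

        rows.append(
            {
                "species": sp,
                "wood_density": float(pool.wood_density[i]),
                "phenology": int(pool.phenology[i]),
                "max_dbh": max_dbh,
                **idx_means,
            }
        )
    table = pd.DataFrame(rows).set_index("species")
    return table


def cwm(abundance: pd.Series | np.ndarray, traits: pd.Series | np.ndarray) -> float:
    """Community-weighted mean: sum p_i t_i with relative abundances p_i.

    Undefined (NaN) for a zero-total community.
    """
    a = np.asarray(abundance, dtype=float)
    t = np.asarray(traits, dtype=float)
    tot = a.sum()
    if tot == 0:
        return float("nan")
    return float(a @ t / tot)


def cwm_table(counts: pd.DataFrame, trait_table: pd.DataFrame,
              traits: tuple[str, ...] | None = None) -> pd.DataFrame:
    """CWM of every trait for every cell of an abundance table."""
    if traits is None:
        traits = tuple(trait_table.columns)
    common = [s for s in counts.columns if s in trait_table.index]
    missing = set(counts.columns) - set(common)
    if missing:
        logger.warning("species without traits ignored in CWM: %s", sorted(missing))
    sub = counts[common].to_numpy(dtype=float)
    tot = sub.sum(axis=1, keepdims=True)
    rel = np.divide(sub, tot, out=np.full_like(sub, np.nan), where=tot > 0)
    tmat = trait_table.loc[common, list(traits)].to_numpy(dtype=float)
    return pd.DataFrame(rel @ tmat, index=counts.index, columns=list(traits))


@dataclass
class FDResult:
    fric: float
    fdiv: float
    degenerate: bool


def standardize_traits(trait_table: pd.DataFrame, traits: tuple[str, ...]) -> pd.DataFrame:
    """Zero-mean/unit-variance scaling over the full species pool."""
    t = trait_table[list(traits)].astype(float)
    sd = t.std(ddof=0).replace(0, 1.0)
    return (t - t.mean()) / sd


def fric(points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull volume of the community's trait points.

    Returns ``(volume, degenerate)``; fewer than d+1 affinely independent
    points give volume 0 with the degenerate flag set.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    d = pts.shape[1]
    if pts.shape[0] < d + 1:
        return 0.0, True
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False


def fdiv(points: np.ndarray, abundances: np.ndarray) -> tuple[float, bool]:
    """Functional divergence: abundance spread relative to the hull's
    gravity center.

    G = centroid of hull vertices; d_i = distance of species i to G;
    dbar = unweighted mean of d_i; Delta d = sum p_i (d_i - dbar);
    Delta |d| = sum p_i |d_i - dbar|; FDiv = (Delta d + dbar) /
    (Delta |d| + dbar).
    """
    pts = np.asarray(points, dtype=float)
    a = np.asarray(abundances, dtype=float)
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < pts.shape[1] + 1:
        return float("nan"), True
    try:
        hull = ConvexHull(uniq)
    except QhullError:
        return float("nan"), True
    G = uniq[hull.vertices].mean(axis=0)
    d = np.linalg.norm(pts - G, axis=1)
    dbar = d.mean()
    p = a / a.sum()
    delta_d = float(p @ (d - dbar))
    delta_abs = float(p @ np.abs(d - dbar))
    return (delta_d + dbar) / (delta_abs + dbar), False


def fd_table(
    counts: pd.DataFrame,
    trait_table: pd.DataFrame,
    traits: tuple[str, ...],
    standardize: bool = True,
) -> pd.DataFrame:
    """FRic and FDiv per cell on a three-trait set.

    Traits are standardized over the species pool before hull computation.
    """
    t = standardize_traits(trait_table, traits) if standardize else trait_table[list(traits)]
    common = [s for s in counts.columns if s in t.index]
    tmat = t.loc[common].to_numpy(dtype=float)
    sub = counts[common].to_numpy(dtype=float)
    rows = []
    for i in range(sub.shape[0]):
        present = sub[i] > 0
        if present.sum() == 0:
            rows.append((np.nan, np.nan, True))
            continue
        vol, deg_r = fric(tmat[present])
        div, deg_d = fdiv(tmat[present], sub[i][present])
        rows.append((vol, div, deg_r or deg_d))
    return pd.DataFrame(rows, index=counts.index, columns=["FRic", "FDiv", "degenerate"])


def summarize_fd(fd: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Group means of FRic/FDiv over non-degenerate cells, with the count of
    degenerate cells per group."""
    g = grouping.reindex(fd.index)
    ok = ~fd["degenerate"].astype(bool)
    means = fd.loc[ok, ["FRic", "FDiv"]].groupby(g[ok]).mean()
    n_deg = fd.loc[~ok].groupby(g[~ok]).size() if (~ok).any() else pd.Series(dtype=int)
    means["n_degenerate"] = n_deg.reindex(means.index).fillna(0).astype(int)
    empty = set(g.dropna().unique()) - set(means.index)
    if empty:
        logger.warning("groups with no defined FD value: %s", sorted(empty))
    return means
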