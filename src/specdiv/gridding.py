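"""Grid-cell abundance extraction: overlay 0.005-degree cells on a
classification map, sample 0.5 ha plots, extrapolate pixel counts to stem
abundances via canopy spread, and attach climate covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassificationMap
from .synthgen import (
    CELL_SIZE_M,
    CLIMATE_COVARIATES,
    NONFOREST,
    PIXEL_SIZE_M,
    PIXELS_PER_CELL,
    ClimateGrids,
)

logger = logging.getLogger(__name__)

# 18 x 18 px at 4 m = 72 x 72 m = 0.5184 ha, the smallest square window
# of at least 0.5 ha
PLOT_WINDOW_PX = 18


@dataclass
class PlotSample:
    """One ~0.5 ha plot window with per-species pixel counts."""

    row0: int
    col0: int
    window_px: int
    pixel_counts: dict[int, int]  # class code -> pixel count
    forest_fraction: float
    abundance: dict[int, int] = field(default_factory=dict)


@dataclass
class GridCell:
    cell_id: str
    row: int  # cell index within the map grid
    col: int
    px_bounds: tuple[int, int, int, int]  # r0, r1, c0, c1 (half-open)
    plots: list[PlotSample] = field(default_factory=list)
    abundance: dict[int, int] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass
class AbundanceMatrix:
    """Cells x species counts with coordinates and covariates attached."""

    counts: pd.DataFrame  # index = cell_id, columns = species names
    covariates: pd.DataFrame  # index = cell_id; CC1..CC6, elevation, soil
    coords: pd.DataFrame  # index = cell_id; x, y (projected m), lon, lat
    pa_id: pd.Series | None = None

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def relative(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        return self.counts.div(tot, axis=0)

    def to_frame(self) -> pd.DataFrame:
        parts = [self.coords, self.covariates, self.counts]
        if self.pa_id is not None:
            parts.insert(0, self.pa_id.rename("pa_id").to_frame())
        return pd.concat(parts, axis=1)


def overlay_grid(
    cmap: ClassificationMap, cell_size_m: float = CELL_SIZE_M, pa_id: str = "PA"
) -> list[GridCell]:
    """Tile the map extent with half-open square cells (default 0.5 km).

    Edge cells clipped by the map boundary are kept; the cells partition the
    extent with no overlap or gap.
    """
    rows, cols = cmap.labels.shape
    cell_px = int(round(cell_size_m / cmap.pixel_size_m))
    n_cr = max(int(np.ceil(rows / cell_px)), 1)
    n_cc = max(int(np.ceil(cols / cell_px)), 1)
    cells = []
    for cr in range(n_cr):
        for cc in range(n_cc):
            r0, c0 = cr * cell_px, cc * cell_px
            r1, c1 = min(r0 + cell_px, rows), min(c0 + cell_px, cols)
            if r0 >= rows or c0 >= cols:
                continue
            cells.append(
                GridCell(
                    cell_id=f"{pa_id}_r{cr:03d}c{cc:03d}",
                    row=cr,
                    col=cc,
                    px_bounds=(r0, r1, c0, c1),
                )
            )
    return cells


def extract_plots(
    cell: GridCell,
    cmap: ClassificationMap,
    n_plots: int = 3,
    min_forest_fraction: float = 0.70,
    window_px: int = PLOT_WINDOW_PX,
    seed: int = 0,
    max_attempts: int = 200,
) -> list[PlotSample]:
    """Place up to ``n_plots`` non-overlapping plot windows in a cell.

    Windows are ``window_px`` squared (18 px = 0.52 ha at 4 m), at seeded
    random positions fully inside the cell, and accepted only when the
    labelled (forest) pixel fraction is at least ``min_forest_fraction``.
    Cells yielding no qualifying plot are excluded upstream with a logged
    reason.
    """
    r0, r1, c0, c1 = cell.px_bounds
    if r1 - r0 < window_px or c1 - c0 < window_px:
        logger.info("cell %s smaller than a plot window", cell.cell_id)
        return []
    rng = np.random.default_rng(seed)
    accepted: list[PlotSample] = []
    for _ in range(max_attempts):
        if len(accepted) == n_plots:
            break
        pr = int(rng.integers(r0, r1 - window_px + 1))
        pc = int(rng.integers(c0, c1 - window_px + 1))
        if any(
            abs(pr - p.row0) < window_px and abs(pc - p.col0) < window_px for p in accepted
        ):
            continue
        patch = cmap.labels[pr : pr + window_px, pc : pc + window_px]
        forest = patch != NONFOREST
        frac = float(forest.mean())
        if frac < min_forest_fraction:
            continue
        vals, counts = np.unique(patch[forest], return_counts=True)
        accepted.append(
            PlotSample(
                row0=pr,
                col0=pc,
                window_px=window_px,
                pixel_counts={int(v): int(n) for v, n in zip(vals, counts)},
                forest_fraction=frac,
            )
        )
    return accepted


def pixels_to_abundance(
    plot: PlotSample,
    canopy_spread_m: dict[int, float],
    pixel_size_m: float = PIXEL_SIZE_M,
) -> dict[int, int]:
    """Extrapolate pixel counts to stem counts via mean crown area.

    ``abundance = round(pixels * pixel_area / (pi (spread/2)^2))`` with a
    floor of one individual for any species that occupies at least one pixel.
    """
    out: dict[int, int] = {}
    for code, n_px in plot.pixel_counts.items():
        if n_px == 0:
            out[code] = 0
            continue
        if code not in canopy_spread_m:
            raise KeyError(f"no canopy spread for species code {code}")
        spread = canopy_spread_m[code]
        if spread <= 0:
            raise ValueError(f"non-positive canopy spread for species code {code}")
        crown_area = np.pi * (spread / 2.0) ** 2
        out[code] = max(int(round(n_px * pixel_size_m**2 / crown_area)), 1)
    plot.abundance = out
    return out


def aggregate_cell_abundance(plots: list[PlotSample]) -> dict[int, int]:
    """Element-wise sum of plot abundances."""
    if not plots:
        raise ValueError("need at least one accepted plot")
    out: dict[int, int] = {}
    for p in plots:
        for code, n in p.abundance.items():
            out[code] = out.get(code, 0) + n
    return out


def attach_covariates(
    cells: list[GridCell],
    grids: ClimateGrids,
    cell_origin: tuple[int, int],
) -> list[GridCell]:
    """Copy nearest-neighbor covariate values onto each cell.

    ``cell_origin`` is the (row, col) of the map's first grid cell within the
    climate raster; map cells map 1:1 onto climate cells and are clipped to
    the raster edge (nearest neighbor).
    """
    cov = grids.covariate_array()
    rows, cols = grids.shape
    missing = []
    for cell in cells:
        gr = cell_origin[0] + cell.row
        gc = cell_origin[1] + cell.col
        if not (0 <= gr < rows and 0 <= gc < cols):
            missing.append(cell.cell_id)
            gr, gc = min(max(gr, 0), rows - 1), min(max(gc, 0), cols - 1)
        cell.covariates = {
            name: float(cov[gr, gc, i]) for i, name in enumerate(CLIMATE_COVARIATES)
        }
        cell.covariates["elevation"] = float(grids.elevation[gr, gc])
        cell.covariates["soil"] = float(grids.soil[gr, gc])
    if missing:
        logger.warning("%d cells outside the covariate extent were clipped: %s",
                       len(missing), missing[:5])
    return cells


def build_abundance_matrix(
    cmap: ClassificationMap,
    grids: ClimateGrids,
    cell_origin: tuple[int, int],
    canopy_spread_m: dict[int, float],
    pa_id: str = "PA",
    n_plots: int = 3,
    min_forest_fraction: float = 0.70,
    seed: int = 0,
) -> tuple[AbundanceMatrix, list[GridCell], list[str]]:
    """Full grid pipeline for one map: overlay, plots, abundance, covariates.

    Returns the abundance matrix of retained cells, the cell objects, and
    the ids of cells excluded for lack of a qualifying plot.
    """
    cells = overlay_grid(cmap, pa_id=pa_id)
    rng = np.random.default_rng(seed)
    retained, excluded = [], []
    for cell in cells:
        plots = extract_plots(
            cell,
            cmap,
            n_plots=n_plots,
            min_forest_fraction=min_forest_fraction,
            seed=int(rng.integers(2**31)),
        )
        if not plots:
            excluded.append(cell.cell_id)
            continue
        for p in plots:
            pixels_to_abundance(p, canopy_spread_m)
        cell.plots = plots
        cell.abundance = aggregate_cell_abundance(plots)
        retained.append(cell)
    if excluded:
        logger.info("excluded %d/%d cells with no qualifying plot", len(excluded), len(cells))
    if not retained:
        raise ValueError("no cell yielded a qualifying plot")

    attach_covariates(retained, grids, cell_origin)

    codes = sorted({c for cell in retained for c in cell.abundance})
    names = [cmap.legend.get(c, str(c)) for c in codes]
    counts = pd.DataFrame(
        [[cell.abundance.get(c, 0) for c in codes] for cell in retained],
        index=[c.cell_id for c in retained],
        columns=names,
        dtype=int,
    )
    covariates = pd.DataFrame(
        [cell.covariates for cell in retained], index=counts.index
    )
    xs = [(cell.col + 0.5) * CELL_SIZE_M for cell in retained]
    ys = [(cell.row + 0.5) * CELL_SIZE_M for cell in retained]
    lon, lat = grids.cell_center_deg(
        np.array([cell_origin[0] + c.row for c in retained]),
        np.array([cell_origin[1] + c.col for c in retained]),
    )
    coords = pd.DataFrame({"x": xs, "y": ys, "lon": lon, "lat": lat}, index=counts.index)
    am = AbundanceMatrix(
        counts=counts,
        covariates=covariates,
        coords=coords,
        pa_id=pd.Series(pa_id, index=counts.index),
    )
    return am, retained, excluded


def concat_abundance(matrices: list[AbundanceMatrix]) -> AbundanceMatrix:
    """Stack per-PA abundance matrices on the union of species columns."""
    counts = pd.concat([m.counts for m in matrices]).fillna(0).astype(int)
    covs = pd.concat([m.covariates for m in matrices])
    coords = pd.concat([m.coords for m in matrices])
    pa = pd.concat([m.pa_id for m in matrices])
    # offset projected coords per PA so cells never collide spatially
    offset = 0.0
    for m in matrices:
        coords.loc[m.counts.index, "x"] = m.coords["x"] + offset
        offset += m.coords["x"].max() + 10 * CELL_SIZE_M
    return AbundanceMatrix(counts=counts, covariates=covs, coords=coords, pa_id=pa)
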