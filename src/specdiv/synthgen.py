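"""Seeded synthetic landscapes: species pools, climate grids, hyperspectral
scenes with crown-level ground truth, and field surveys.

Everything downstream (classification, gridded abundance, abundance-climate
modelling, traits, dark diversity) is exercised on the output of this module,
so the generators encode the statistical structure the analysis assumes:

* species carry spectral signatures separable in the four classification
  regions, niche coefficients linking log-abundance to climate (evergreen
  species increase with rainfall), canopy-spread and DBH distributions;
* climate grids carry a monotone west-to-east rainfall gradient across
  protected areas (PAs) plus seeded within-PA noise;
* scenes place crowns by a log-linear niche model on the local climate cell,
  rasterize them taller-tree-wins at 4 m pixels, and render reflectance as
  signature x smooth multiplicative brightness field + sensor noise;
* field surveys record crowns inside randomly placed 8 m x 8 m quadrats,
  dropping stems at or below the 0.04 m DBH recording limit.

All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .spectral import CLASSIFICATION_REGIONS_NM, SpectralCube

logger = logging.getLogger(__name__)

PIXEL_SIZE_M = 4.0
CELL_SIZE_M = 500.0
CELL_SIZE_DEG = 0.005
PIXELS_PER_CELL = int(round(CELL_SIZE_M / PIXEL_SIZE_M))  # 125

DBH_MIN_M = 0.04  # recording limit: stems at or below this are not recorded
DBH_MAX_M = 1.43

QUADRAT_SIZE_M = 8.0

NONFOREST = -1

CLIMATE_COVARIATES = ("CC1", "CC2", "CC3", "CC4", "CC5", "CC6")

#: default per-PA mean ranges (first PA -> last PA) for the six climate
#: covariates: decadal mean annual rainfall, wet-season rainfall, rainfall
#: seasonality, decadal mean temperature, max monthly temperature,
#: temperature seasonality.
DEFAULT_GRADIENT_SPEC = {
    "CC1": (1140.13, 2757.60),
    "CC2": (700.0, 2100.0),
    "CC3": (85.0, 45.0),
    "CC4": (28.08, 24.93),
    "CC5": (33.5, 29.5),
    "CC6": (5.5, 2.5),
}


def default_wavelength_grid() -> np.ndarray:
    """425-band, 5 nm grid starting at 380 nm (visible through SWIR)."""
    return 380.0 + 5.0 * np.arange(425)


def _base_vegetation_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth, plausible green-canopy reflectance curve."""
    control_wl = np.array(
        [380, 450, 500, 550, 600, 660, 690, 720, 760, 900, 1100,
         1280, 1400, 1500, 1660, 1800, 1940, 2050, 2200, 2400, 2510],
        dtype=float,
    )
    control_r = np.array(
        [0.03, 0.035, 0.04, 0.09, 0.06, 0.04, 0.05, 0.20, 0.42, 0.46, 0.44,
         0.40, 0.12, 0.28, 0.26, 0.10, 0.05, 0.16, 0.18, 0.08, 0.05]
    )
    return np.interp(wavelengths, control_wl, control_r)


def _soil_background_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Flat, slowly brightening soil curve: low NIR/red contrast so NDVI
    masking removes the background."""
    return 0.18 + 0.10 * (wavelengths - wavelengths[0]) / (
        wavelengths[-1] - wavelengths[0]
    )


@dataclass
class SpeciesPool:
    """Regional species pool shared by all PAs of a synthetic landscape."""

    species_ids: list[str]
    membership: np.ndarray  # (n_species, n_pas) bool
    phenology: np.ndarray  # (n_species,) 1 = evergreen, 0 = deciduous
    wood_density: np.ndarray  # g/cm^3
    mean_canopy_spread: np.ndarray  # m
    dbh_lognorm_mu: np.ndarray
    dbh_lognorm_sigma: np.ndarray
    signatures: np.ndarray  # (n_species, n_bands) in [0, 1]
    wavelengths: np.ndarray  # (n_bands,)
    niche_coefficients: np.ndarray  # (n_species, 6) on standardized covariates

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_pas(self) -> int:
        return self.membership.shape[1]

    def pa_species(self, pa: int) -> np.ndarray:
        """Indices of the species occurring in PA ``pa``."""
        return np.flatnonzero(self.membership[:, pa])

    def n_pa_specific(self) -> int:
        """Species restricted to a single PA (0 when there is only one PA)."""
        if self.n_pas == 1:
            return 0
        return int(np.sum(self.membership.sum(axis=1) == 1))

    def sample_dbh(self, species: int, size: int, rng: np.random.Generator) -> np.ndarray:
        """Log-normal DBH draws truncated to the simulated stem-size range."""
        d = rng.lognormal(self.dbh_lognorm_mu[species], self.dbh_lognorm_sigma[species], size)
        return np.clip(d, 0.02, DBH_MAX_M)


@dataclass
class ClimateGrids:
    """Aligned climate/elevation/soil rasters with a PA-index raster."""

    covariates: dict[str, np.ndarray]  # name -> (rows, cols)
    elevation: np.ndarray
    soil: np.ndarray  # binary: 1 = Nitisols, 0 = other
    pa_index: np.ndarray  # (rows, cols) int
    pa_ids: list[str]
    cell_size_deg: float = CELL_SIZE_DEG
    origin_deg: tuple[float, float] = (76.0, 10.0)  # (lon, lat) of cell (0, 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def n_pas(self) -> int:
        return len(self.pa_ids)

    def covariate_array(self) -> np.ndarray:
        """(rows, cols, 6) stack in CC1..CC6 order."""
        return np.stack([self.covariates[c] for c in CLIMATE_COVARIATES], axis=-1)

    def standardization(self) -> tuple[np.ndarray, np.ndarray]:
        """Means and SDs of the six covariates over all cells."""
        arr = self.covariate_array().reshape(-1, len(CLIMATE_COVARIATES))
        sd = arr.std(axis=0)
        sd[sd == 0] = 1.0
        return arr.mean(axis=0), sd

    def standardized_array(self) -> np.ndarray:
        mean, sd = self.standardization()
        return (self.covariate_array() - mean) / sd

    def pa_block(self, pa: int) -> tuple[slice, slice]:
        """Row/col slices of the (rectangular) block belonging to PA ``pa``."""
        rows, cols = np.nonzero(self.pa_index == pa)
        if rows.size == 0:
            raise ValueError(f"PA index {pa} has no cells")
        return (
            slice(int(rows.min()), int(rows.max()) + 1),
            slice(int(cols.min()), int(cols.max()) + 1),
        )

    def pa_rainfall_means(self) -> np.ndarray:
        cc1 = self.covariates["CC1"]
        return np.array([cc1[self.pa_index == p].mean() for p in range(self.n_pas)])

    def cell_center_deg(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.origin_deg[0] + (np.asarray(col) + 0.5) * self.cell_size_deg
        lat = self.origin_deg[1] + (np.asarray(row) + 0.5) * self.cell_size_deg
        return lon, lat


@dataclass
class Crown:
    species: int
    species_id: str
    x_m: float
    y_m: float
    diameter_m: float
    height_m: float
    dbh_m: float


@dataclass
class SyntheticScene:
    """A rendered hyperspectral scene for one PA with full ground truth."""

    cube: SpectralCube
    truth_map: np.ndarray  # (rows, cols) species index, NONFOREST outside crowns
    crowns: list[Crown]
    pa: int
    pa_id: str
    species_indices: np.ndarray  # pool indices of the species present in this PA
    cell_origin: tuple[int, int]  # (row, col) of the scene origin in the climate raster
    cell_species_probs: np.ndarray = field(repr=False, default=None)
    # (cell_rows, cell_cols, n_local_species): sampling probabilities used

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth_map.shape

    def climate_cell_of(self, x_m: np.ndarray, y_m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Local climate-cell indices (within the scene block) of scene
        coordinates in meters."""
        ccr = np.minimum(
            (np.asarray(y_m) / CELL_SIZE_M).astype(int), self.cell_species_probs.shape[0] - 1
        )
        ccc = np.minimum(
            (np.asarray(x_m) / CELL_SIZE_M).astype(int), self.cell_species_probs.shape[1] - 1
        )
        return ccr, ccc

    def expected_species_frequencies(self) -> np.ndarray:
        """Niche-model expected sampling frequency of each local species,
        averaging cell probabilities weighted by covered pixel area."""
        rows, cols = self.shape
        ncr, ncc = self.cell_species_probs.shape[:2]
        # pixel counts per covered cell (edge cells may be partial)
        r_px = np.minimum(np.arange(ncr) * PIXELS_PER_CELL + PIXELS_PER_CELL, rows) - np.minimum(
            np.arange(ncr) * PIXELS_PER_CELL, rows
        )
        c_px = np.minimum(np.arange(ncc) * PIXELS_PER_CELL + PIXELS_PER_CELL, cols) - np.minimum(
            np.arange(ncc) * PIXELS_PER_CELL, cols
        )
        w = np.outer(r_px, c_px).astype(float)
        w /= w.sum()
        return np.einsum("rc,rcs->s", w, self.cell_species_probs)


@dataclass
class QuadratRecord:
    species_id: str
    dbh_m: float
    height_m: float
    canopy_spread_m: float


@dataclass
class Quadrat:
    center_x_m: float
    center_y_m: float
    size_m: float
    records: list[QuadratRecord]


@dataclass
class FieldSurvey:
    quadrats: list[Quadrat]
    pa_id: str


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_species_pool(
    n_species: int,
    n_pas: int,
    pa_specific_fraction: float,
    seed: int,
    wavelengths: np.ndarray | None = None,
    min_separation_deg: float = 1.5,
    signature_bump_amplitude: float = 0.06,
) -> SpeciesPool:
    """Create a species pool with PA memberships, traits, spectral
    signatures and niche coefficients.

    ``round(pa_specific_fraction * n_species)`` species are restricted to a
    single PA; the rest occur in at least two PAs (all PAs when there is only
    one).  Signatures are a shared smooth vegetation spectrum plus
    species-specific Gaussian bumps inside the four classification regions,
    resampled until all pairwise spectral angles on those regions exceed
    ``min_separation_deg``.
    """
    if n_species <= 0 or n_pas <= 0:
        raise ValueError("n_species and n_pas must be positive")
    if n_species < n_pas:
        raise ValueError("need at least one species per PA")
    if not 0.0 <= pa_specific_fraction <= 1.0:
        raise ValueError("pa_specific_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    wl = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths, float)

    species_ids = [f"SP{i + 1:03d}" for i in range(n_species)]

    membership = np.zeros((n_species, n_pas), dtype=bool)
    n_specific = int(round(pa_specific_fraction * n_species)) if n_pas > 1 else 0
    specific = rng.choice(n_species, size=n_specific, replace=False) if n_specific else np.array([], int)
    is_specific = np.zeros(n_species, dtype=bool)
    is_specific[specific] = True
    for i in range(n_species):
        if n_pas == 1:
            membership[i, 0] = True
        elif is_specific[i]:
            membership[i, rng.integers(n_pas)] = True
        else:
            k = int(rng.integers(2, n_pas + 1))
            membership[i, rng.choice(n_pas, size=k, replace=False)] = True
    # every PA needs at least one species
    for p in range(n_pas):
        if not membership[:, p].any():
            membership[int(rng.integers(n_species)), p] = True

    phenology = (rng.random(n_species) < 0.5).astype(int)
    wood_density = rng.uniform(0.35, 0.95, n_species)
    mean_canopy_spread = rng.uniform(5.0, 12.0, n_species)
    # log-normal DBH centered well inside [0.04, 1.43] m
    dbh_mu = rng.uniform(np.log(0.12), np.log(0.45), n_species)
    dbh_sigma = rng.uniform(0.35, 0.6, n_species)

    # niche: evergreen species increase with rainfall (CC1), deciduous decrease
    niche = rng.normal(0.0, 0.3, size=(n_species, len(CLIMATE_COVARIATES)))
    rain_slope = rng.uniform(0.8, 1.5, n_species)
    niche[:, 0] = np.where(phenology == 1, rain_slope, -rain_slope)

    signatures = _separable_signatures(
        n_species, wl, rng, min_separation_deg, signature_bump_amplitude
    )
    # phenology-linked canopy-water signal: evergreen canopies absorb more
    # near 1240 nm (raises their NDWI), tying the biochemical index traits to
    # the rainfall niche the way the deciduous/evergreen gradient does
    water_dip = np.exp(-0.5 * ((wl - 1240.0) / 35.0) ** 2)
    dip_strength = 0.04 + rng.uniform(0.0, 0.02, n_species)
    signatures = np.clip(
        signatures - (phenology * dip_strength)[:, None] * water_dip, 0.01, 0.95
    )

    return SpeciesPool(
        species_ids=species_ids,
        membership=membership,
        phenology=phenology,
        wood_density=wood_density,
        mean_canopy_spread=mean_canopy_spread,
        dbh_lognorm_mu=dbh_mu,
        dbh_lognorm_sigma=dbh_sigma,
        signatures=signatures,
        wavelengths=wl,
        niche_coefficients=niche,
    )


def _random_signature(
    base: np.ndarray, wl: np.ndarray, rng: np.random.Generator, amplitude: float
) -> np.ndarray:
    sig = base.copy()
    for lo, hi in CLASSIFICATION_REGIONS_NM:
        for _ in range(int(rng.integers(2, 4))):
            center = rng.uniform(lo, hi)
            width = rng.uniform(20.0, 60.0)
            amp = rng.uniform(0.3, 1.0) * amplitude * rng.choice([-1.0, 1.0])
            sig += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return np.clip(sig, 0.01, 0.95)


def _separable_signatures(
    n_species: int,
    wl: np.ndarray,
    rng: np.random.Generator,
    min_separation_deg: float,
    amplitude: float,
    max_retries: int = 200,
) -> np.ndarray:
    base = _base_vegetation_spectrum(wl)
    region = np.zeros(len(wl), dtype=bool)
    for lo, hi in CLASSIFICATION_REGIONS_NM:
        region |= (wl >= lo) & (wl <= hi)

    def _angles(sigs: np.ndarray) -> np.ndarray:
        v = sigs[:, region]
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        cos = np.clip(v @ v.T, -1.0, 1.0)
        return np.degrees(np.arccos(cos))

    sigs = np.stack([_random_signature(base, wl, rng, amplitude) for _ in range(n_species)])
    for _ in range(max_retries):
        ang = _angles(sigs)
        np.fill_diagonal(ang, np.inf)
        worst = np.unravel_index(np.argmin(ang), ang.shape)
        if ang[worst] >= min_separation_deg:
            return sigs
        sigs[worst[1]] = _random_signature(base, wl, rng, amplitude)
    logger.warning(
        "signature separability target %.2f deg not reached after %d retries",
        min_separation_deg,
        max_retries,
    )
    return sigs


def generate_climate_grids(
    pa_ids: list[str] | int,
    cells_per_pa: tuple[int, int] = (4, 4),
    gradient_spec: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    cell_size_deg: float = CELL_SIZE_DEG,
) -> ClimateGrids:
    """Gridded climate covariates for PAs laid out west to east.

    Each covariate's per-PA mean interpolates linearly between the end points
    of ``gradient_spec`` (default: rainfall increasing, temperature
    decreasing eastward); cell values add seeded Gaussian noise with SD
    ``noise_sd * |range|``.  With ``noise_sd = 0`` every cell equals its
    PA-level mean exactly.
    """
    if isinstance(pa_ids, int):
        pa_ids = [f"PA{i + 1}" for i in range(pa_ids)]
    n_pas = len(pa_ids)
    ny, nx = cells_per_pa
    if n_pas < 1 or ny < 1 or nx < 1:
        raise ValueError("degenerate extent: need at least one cell per PA")
    spec = dict(DEFAULT_GRADIENT_SPEC)
    if gradient_spec:
        spec.update(gradient_spec)

    rng = np.random.default_rng(seed)
    rows, cols = ny, nx * n_pas
    pa_index = np.repeat(np.arange(n_pas), nx)[None, :].repeat(rows, axis=0)

    frac = np.arange(n_pas) / max(n_pas - 1, 1)
    covariates: dict[str, np.ndarray] = {}
    for name in CLIMATE_COVARIATES:
        lo, hi = spec[name]
        pa_means = lo + frac * (hi - lo)
        grid = pa_means[pa_index].astype(float)
        grid += rng.normal(0.0, noise_sd * abs(hi - lo), size=grid.shape)
        covariates[name] = grid

    elevation = 500.0 + 150.0 * rng.random((rows, cols))
    # wetter (eastern) half of the gradient sits on Nitisols
    soil = (pa_index >= n_pas / 2.0).astype(int) if n_pas > 1 else np.zeros((rows, cols), int)

    return ClimateGrids(
        covariates=covariates,
        elevation=elevation,
        soil=soil,
        pa_index=pa_index,
        pa_ids=list(pa_ids),
        cell_size_deg=cell_size_deg,
    )


def _brightness_field(
    shape: tuple[int, int], brightness_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    lo, hi = brightness_range
    if hi < lo:
        raise ValueError("brightness_range must be (low, high) with low <= high")
    if hi == lo:
        return np.full(shape, lo)
    coarse = rng.random((max(shape[0] // 32, 2), max(shape[1] // 32, 2)))
    fine = ndimage.zoom(coarse, (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1]), order=1)
    fine = fine[: shape[0], : shape[1]]
    if fine.shape != shape:  # zoom can undershoot by a pixel
        fine = np.pad(fine, ((0, shape[0] - fine.shape[0]), (0, shape[1] - fine.shape[1])), mode="edge")
    fmin, fmax = fine.min(), fine.max()
    return lo + (fine - fmin) * (hi - lo) / max(fmax - fmin, 1e-12)


def generate_scene(
    pool: SpeciesPool,
    grids: ClimateGrids,
    pa: int | str,
    size: tuple[int, int] = (256, 256),
    noise_sd: float = 0.002,
    brightness_range: tuple[float, float] = (0.85, 1.15),
    forest_fraction: float = 0.78,
    seed: int = 0,
) -> SyntheticScene:
    """Render a hyperspectral scene for one PA with crown-level truth.

    Crowns are placed at uniform random centers; the species of each crown is
    drawn with probability proportional to ``exp(niche . z)`` where ``z`` is
    the standardized covariate vector of the climate cell under the crown
    center.  Crowns rasterize as discs, taller tree wins on overlap.  Pixel
    spectra are the species signature times a smooth multiplicative
    brightness field plus Gaussian sensor noise, clipped to [0, 1];
    background pixels carry a low-contrast soil spectrum.
    """
    if isinstance(pa, str):
        pa = grids.pa_ids.index(pa)
    local_species = pool.pa_species(pa)
    if local_species.size == 0:
        raise ValueError(f"no species assigned to PA {grids.pa_ids[pa]}")
    rows, cols = size
    min_diam_px = pool.mean_canopy_spread[local_species].min() / PIXEL_SIZE_M
    if min(rows, cols) < min_diam_px:
        raise ValueError("scene smaller than one crown")

    rng = np.random.default_rng(seed)

    # climate cells covered by the scene (clipped to the PA block)
    rsl, csl = grids.pa_block(pa)
    pa_cells_z = grids.standardized_array()[rsl, csl]  # (pr, pc, 6)
    ncr = min(int(np.ceil(rows / PIXELS_PER_CELL)), pa_cells_z.shape[0])
    ncc = min(int(np.ceil(cols / PIXELS_PER_CELL)), pa_cells_z.shape[1])
    z = pa_cells_z[:ncr, :ncc]  # (ncr, ncc, 6)

    logits = np.einsum("rck,sk->rcs", z, pool.niche_coefficients[local_species])
    logits -= logits.max(axis=-1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=-1, keepdims=True)  # (ncr, ncc, n_local)

    # number of crowns for the requested coverage under a Boolean disc model:
    # cover = 1 - exp(-n A_mean / A_scene)  =>  n = -ln(1 - f) A_scene / A_mean
    if not 0.0 < forest_fraction < 1.0:
        raise ValueError("forest_fraction must be in (0, 1)")
    mean_area = np.pi * (pool.mean_canopy_spread[local_species].mean() / 2.0) ** 2
    scene_area = rows * cols * PIXEL_SIZE_M**2
    n_crowns = max(int(-np.log(1.0 - forest_fraction) * scene_area / mean_area), 1)

    x = rng.uniform(0, cols * PIXEL_SIZE_M, n_crowns)
    y = rng.uniform(0, rows * PIXEL_SIZE_M, n_crowns)
    ccr = np.minimum((y / CELL_SIZE_M).astype(int), ncr - 1)
    ccc = np.minimum((x / CELL_SIZE_M).astype(int), ncc - 1)

    # vectorized categorical draw per crown from its cell's distribution
    cdf = np.cumsum(probs[ccr, ccc], axis=1)
    u = rng.random(n_crowns)[:, None]
    local_idx = (u > cdf).sum(axis=1)
    species = local_species[local_idx]

    spread = rng.normal(pool.mean_canopy_spread[species], 0.15 * pool.mean_canopy_spread[species])
    spread = np.maximum(spread, PIXEL_SIZE_M)
    dbh = np.clip(
        rng.lognormal(pool.dbh_lognorm_mu[species], pool.dbh_lognorm_sigma[species]),
        0.02,
        DBH_MAX_M,
    )
    height = 4.0 + 1.6 * spread + 8.0 * dbh + rng.normal(0, 1.0, n_crowns)

    crowns = [
        Crown(
            species=int(species[i]),
            species_id=pool.species_ids[species[i]],
            x_m=float(x[i]),
            y_m=float(y[i]),
            diameter_m=float(spread[i]),
            height_m=float(height[i]),
            dbh_m=float(dbh[i]),
        )
        for i in range(n_crowns)
    ]

    truth = np.full((rows, cols), NONFOREST, dtype=np.int32)
    for i in np.argsort(height):  # paint shortest first so taller wins
        _paint_disc(truth, x[i], y[i], spread[i] / 2.0, np.int32(species[i]))

    # render reflectance
    n_bands = len(pool.wavelengths)
    soil = _soil_background_spectrum(pool.wavelengths).astype(np.float32)
    # signature lookup: row per species index, last row = background
    lut = np.vstack([pool.signatures.astype(np.float32), soil[None, :]])
    refl = lut[np.where(truth == NONFOREST, pool.n_species, truth)]  # (rows, cols, bands)
    refl *= _brightness_field((rows, cols), brightness_range, rng)[..., None].astype(np.float32)
    if noise_sd > 0:
        refl += rng.normal(0.0, noise_sd, size=refl.shape).astype(np.float32)
    np.clip(refl, 0.0, 1.0, out=refl)

    cube = SpectralCube(
        reflectance=np.ascontiguousarray(np.moveaxis(refl, -1, 0)),
        wavelengths=pool.wavelengths,
    )
    return SyntheticScene(
        cube=cube,
        truth_map=truth,
        crowns=crowns,
        pa=pa,
        pa_id=grids.pa_ids[pa],
        species_indices=local_species,
        cell_origin=(rsl.start, csl.start),
        cell_species_probs=probs,
    )


def _paint_disc(arr: np.ndarray, x_m: float, y_m: float, radius_m: float, value) -> int:
    """Rasterize a disc (meters) into a 4 m pixel grid; returns painted count."""
    r_px = radius_m / PIXEL_SIZE_M
    cx, cy = x_m / PIXEL_SIZE_M, y_m / PIXEL_SIZE_M
    r0 = max(int(np.floor(cy - r_px)), 0)
    r1 = min(int(np.ceil(cy + r_px)) + 1, arr.shape[0])
    c0 = max(int(np.floor(cx - r_px)), 0)
    c1 = min(int(np.ceil(cx + r_px)) + 1, arr.shape[1])
    if r0 >= r1 or c0 >= c1:
        return 0
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr + 0.5 - cy) ** 2 + (cc + 0.5 - cx) ** 2 <= r_px**2
    arr[r0:r1, c0:c1][inside] = value
    return int(inside.sum())


def generate_field_survey(
    scene: SyntheticScene,
    n_quadrats: int,
    seed: int = 0,
    quadrat_size_m: float = QUADRAT_SIZE_M,
) -> FieldSurvey:
    """Place square quadrats at random and record the crowns whose centers
    fall inside, excluding stems with DBH <= 0.04 m (the recording limit)."""
    if n_quadrats < 1:
        raise ValueError("n_quadrats must be >= 1")
    rows, cols = scene.shape
    w_m, h_m = cols * PIXEL_SIZE_M, rows * PIXEL_SIZE_M
    if quadrat_size_m > min(w_m, h_m):
        raise ValueError("quadrat larger than scene")
    rng = np.random.default_rng(seed)
    half = quadrat_size_m / 2.0

    cx = rng.uniform(half, w_m - half, n_quadrats)
    cy = rng.uniform(half, h_m - half, n_quadrats)

    crown_x = np.array([c.x_m for c in scene.crowns])
    crown_y = np.array([c.y_m for c in scene.crowns])

    quadrats = []
    for q in range(n_quadrats):
        inside = (
            (crown_x >= cx[q] - half)
            & (crown_x < cx[q] + half)
            & (crown_y >= cy[q] - half)
            & (crown_y < cy[q] + half)
        )
        records = [
            QuadratRecord(
                species_id=scene.crowns[i].species_id,
                dbh_m=scene.crowns[i].dbh_m,
                height_m=scene.crowns[i].height_m,
                canopy_spread_m=scene.crowns[i].diameter_m,
            )
            for i in np.flatnonzero(inside)
            if scene.crowns[i].dbh_m > DBH_MIN_M
        ]
        quadrats.append(Quadrat(float(cx[q]), float(cy[q]), quadrat_size_m, records))
    return FieldSurvey(quadrats=quadrats, pa_id=scene.pa_id)
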