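"""Spectral preprocessing: band selection, brightness normalization, MNF,
NDVI masking and canopy index computation.

A :class:`SpectralCube` stores reflectance as a ``(bands, rows, cols)`` array
with per-band wavelengths (nm) and a per-pixel validity mask.  Band selection
is purely interval driven; the retained counts are emergent, never asserted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# Spectral windows (nm).  Bands below the noisy-band cutoff and inside the
# water-absorption windows are discarded; classification restricts to four
# discriminative regions.
NOISY_BAND_CUTOFF_NM = 411.0
WATER_ABSORPTION_WINDOWS_NM = ((1348.0, 1428.0), (1778.0, 1949.0))
CLASSIFICATION_REGIONS_NM = (
    (550.0, 650.0),
    (750.0, 1250.0),
    (1500.0, 1750.0),
    (2000.0, 2250.0),
)

# Nominal index wavelengths (nm); the nearest band center is used and logged.
RED_NM = 650.0
NIR_NM = 860.0
GREEN531_NM = 531.0
RED645_NM = 645.0
SWIR1240_NM = 1240.0


@dataclass
class SpectralCube:
    """Band-indexed reflectance raster with wavelength metadata."""

    reflectance: np.ndarray  # (bands, rows, cols), values in [0, 1]
    wavelengths: np.ndarray  # (bands,), nm, strictly increasing
    validity_mask: np.ndarray | None = None  # (rows, cols) bool

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be (bands, rows, cols)")
        if self.reflectance.shape[0] != self.wavelengths.shape[0]:
            raise ValueError("band count must equal wavelength count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.reflectance.shape[1:], dtype=bool)
        else:
            self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
            if self.validity_mask.shape != self.reflectance.shape[1:]:
                raise ValueError("validity_mask shape mismatch")

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape[1:]

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band whose center is closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def band_image(self, wavelength_nm: float) -> np.ndarray:
        return self.reflectance[self.nearest_band(wavelength_nm)]


@dataclass
class BandSet:
    """Ordered, unique band indices into a parent cube."""

    indices: np.ndarray
    label: str = "usable"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("indices must be unique")
        self.indices = np.sort(idx)

    def __len__(self) -> int:
        return len(self.indices)

    def wavelengths(self, cube: SpectralCube) -> np.ndarray:
        return cube.wavelengths[self.indices]


@dataclass
class IndexRaster:
    """A named spectral index with the wavelengths that produced it."""

    name: str
    values: np.ndarray
    wavelengths_nm: tuple[float, ...]


@dataclass
class MNFModel:
    """Minimum noise fraction transform fitted from spatial shift differences.

    ``eigenvalues`` order components by decreasing signal-to-noise ratio of the
    noise-whitened signal covariance.
    """

    mean: np.ndarray  # (bands,)
    forward: np.ndarray  # (bands, bands): scores = (x - mean) @ forward
    backward: np.ndarray  # (bands, bands): x = scores @ backward + mean
    eigenvalues: np.ndarray  # (bands,), non-increasing
    noise_cov: np.ndarray = field(repr=False, default=None)

    @property
    def n_bands(self) -> int:
        return self.mean.shape[0]

    def n_components_above(self, snr_threshold: float) -> int:
        """Number of leading components with eigenvalue > threshold (min 1)."""
        return max(1, int(np.sum(self.eigenvalues > snr_threshold)))

    def transform(self, x: np.ndarray, n_components: int | None = None) -> np.ndarray:
        fwd = self.forward if n_components is None else self.forward[:, :n_components]
        return (np.asarray(x, dtype=float) - self.mean) @ fwd

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        k = scores.shape[-1]
        return scores @ self.backward[:k] + self.mean


def select_usable_bands(cube: SpectralCube) -> BandSet:
    """Drop noisy short-wavelength bands and water-absorption windows.

    Retains bands with center >= 411 nm that fall outside the closed windows
    [1348, 1428] and [1778, 1949] nm.
    """
    wl = cube.wavelengths
    keep = wl >= NOISY_BAND_CUTOFF_NM
    for lo, hi in WATER_ABSORPTION_WINDOWS_NM:
        keep &= ~((wl >= lo) & (wl <= hi))
    if not keep.any():
        raise ValueError("no usable bands after filtering")
    return BandSet(np.flatnonzero(keep), label="usable")


def select_classification_bands(bands: BandSet, cube: SpectralCube) -> BandSet:
    """Restrict a usable-band set to the four discriminative regions
    (closed intervals, nm): 550-650, 750-1250, 1500-1750, 2000-2250."""
    wl = cube.wavelengths[bands.indices]
    keep = np.zeros(len(wl), dtype=bool)
    for lo, hi in CLASSIFICATION_REGIONS_NM:
        keep |= (wl >= lo) & (wl <= hi)
    return BandSet(bands.indices[keep], label="classification")


def brightness_normalize(spectra: np.ndarray) -> np.ndarray:
    """Scale each spectrum (last axis) to unit Euclidean norm.

    Removes multiplicative brightness gradients while preserving spectral
    shape.  All-zero spectra cannot be normalized; they are returned as NaN
    rows with a warning.
    """
    x = np.asarray(spectra, dtype=float)
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    zero = norms[..., 0] == 0
    if np.any(zero):
        warnings.warn(
            f"{int(np.sum(zero))} all-zero spectra could not be normalized",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = x / norms
    out[zero] = np.nan
    return out


def fit_mnf(
    stack: np.ndarray,
    mask: np.ndarray | None = None,
    ridge: float = 1e-12,
    dual_direction: bool = False,
) -> MNFModel:
    """Fit a minimum noise fraction transform from a spatial image stack.

    Parameters
    ----------
    stack
        ``(rows, cols, bands)`` array of pixel spectra.
    mask
        Optional per-pixel validity; noise differences use only pairs of
        valid neighboring pixels.
    ridge
        Added to the noise-covariance diagonal if it is ill conditioned.
    dual_direction
        Average horizontal and vertical shift differences for the noise
        estimate (default: horizontal only).

    The noise covariance is estimated from shift differences
    ``d = x[r, c] - x[r, c+1]`` as ``cov(d) / 2``; the transform is the
    eigendecomposition of the noise-whitened signal covariance, ordered by
    decreasing SNR eigenvalue.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (rows, cols, bands)")
    rows, cols, bands = stack.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)

    samples = stack[mask]
    if samples.shape[0] < bands + 1:
        raise ValueError("need more than band-count valid samples")

    def _shift_diffs(axis: int) -> np.ndarray:
        if axis == 1:
            d = stack[:, :-1, :] - stack[:, 1:, :]
            pair_ok = mask[:, :-1] & mask[:, 1:]
        else:
            d = stack[:-1, :, :] - stack[1:, :, :]
            pair_ok = mask[:-1, :] & mask[1:, :]
        return d[pair_ok]

    diffs = _shift_diffs(axis=1)
    if dual_direction:
        diffs = np.vstack([diffs, _shift_diffs(axis=0)])
    if diffs.shape[0] < bands + 1:
        raise ValueError("not enough neighbor pairs for noise estimation")

    noise_cov = np.cov(diffs / np.sqrt(2.0), rowvar=False)
    noise_cov = np.atleast_2d(noise_cov)
    # regularize if near singular
    try:
        evals = np.linalg.eigvalsh(noise_cov)
        if evals[0] <= ridge * max(evals[-1], 1.0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        bump = max(ridge, 1e-10 * float(np.trace(noise_cov)) / bands)
        logger.warning("singular noise covariance; adding ridge %.3g", bump)
        noise_cov = noise_cov + bump * np.eye(bands)

    mean = samples.mean(axis=0)
    signal_cov = np.cov(samples - mean, rowvar=False)
    signal_cov = np.atleast_2d(signal_cov)

    nvals, nvecs = np.linalg.eigh(noise_cov)
    nvals = np.maximum(nvals, ridge * max(float(nvals[-1]), 1.0))
    whiten = nvecs @ np.diag(1.0 / np.sqrt(nvals))  # (bands, bands)
    white_signal = whiten.T @ signal_cov @ whiten
    evals, evecs = np.linalg.eigh(white_signal)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    forward = whiten @ evecs
    backward = np.linalg.pinv(forward)
    return MNFModel(
        mean=mean,
        forward=forward,
        backward=backward,
        eigenvalues=evals,
        noise_cov=noise_cov,
    )


def compute_ndvi(cube: SpectralCube) -> np.ndarray:
    """NDVI = (R_NIR - R_red)/(R_NIR + R_red) with nearest bands to
    860 / 650 nm; zero-denominator pixels come out NaN."""
    nir = cube.band_image(NIR_NM).astype(float)
    red = cube.band_image(RED_NM).astype(float)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = (nir - red) / denom
    ndvi[denom == 0] = np.nan
    return ndvi


def compute_ndvi_mask(cube: SpectralCube, threshold: float) -> np.ndarray:
    """Validity mask keeping pixels with NDVI >= threshold.

    Pixels with NDVI below the threshold (or an undefined NDVI) are masked,
    removing non-forest background.  The cube's own validity mask is
    inherited.
    """
    ndvi = compute_ndvi(cube)
    with np.errstate(invalid="ignore"):
        keep = ndvi >= threshold
    keep &= ~np.isnan(ndvi)
    return keep & cube.validity_mask


def compute_indices(
    cube: SpectralCube, par: float | np.ndarray = 1.0
) -> dict[str, IndexRaster]:
    """Compute NDVI, CCI, NIRv, NIRvP and NDWI rasters.

    CCI = (R531 - R645)/(R531 + R645); NIRv = NDVI * R_NIR;
    NIRvP = NIRv * PAR; NDWI = (R860 - R1240)/(R860 + R1240).
    Nearest-band matching is used and the chosen wavelengths recorded on each
    raster.  Pixels outside the cube's validity mask (and zero-denominator
    pixels) are NaN.
    """

    def _norm_diff(wl_a: float, wl_b: float) -> tuple[np.ndarray, tuple[float, float]]:
        ia, ib = cube.nearest_band(wl_a), cube.nearest_band(wl_b)
        a = cube.reflectance[ia].astype(float)
        b = cube.reflectance[ib].astype(float)
        denom = a + b
        with np.errstate(invalid="ignore", divide="ignore"):
            v = (a - b) / denom
        v[denom == 0] = np.nan
        return v, (float(cube.wavelengths[ia]), float(cube.wavelengths[ib]))

    invalid = ~cube.validity_mask

    ndvi, ndvi_wl = _norm_diff(NIR_NM, RED_NM)
    cci, cci_wl = _norm_diff(GREEN531_NM, RED645_NM)
    ndwi, ndwi_wl = _norm_diff(NIR_NM, SWIR1240_NM)

    nir_idx = cube.nearest_band(NIR_NM)
    nirv = ndvi * cube.reflectance[nir_idx].astype(float)
    nirvp = nirv * par

    out = {
        "NDVI": IndexRaster("NDVI", ndvi, ndvi_wl),
        "CCI": IndexRaster("CCI", cci, cci_wl),
        "NIRv": IndexRaster("NIRv", nirv, ndvi_wl),
        "NIRvP": IndexRaster("NIRvP", nirvp, ndvi_wl),
        "NDWI": IndexRaster("NDWI", ndwi, ndwi_wl),
    }
    for r in out.values():
        r.values[invalid] = np.nan
        logger.debug("index %s used wavelengths %s", r.name, r.wavelengths_nm)
    return out
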