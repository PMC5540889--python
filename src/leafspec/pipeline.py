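"""From a plant scan and its blank reference to one mean reflectance spectrum.

The processing chain mirrors the imaging protocol: every plant scan is
paired with a blank-chamber reference scan taken immediately after it.
Dividing plant digital numbers by reference digital numbers band by band
cancels the lamp spectrum and the chamber's non-uniform illumination,
yielding apparent reflectance in [0, 1]. An NDVI image built from the
bands nearest 705 and 750 nm separates vegetation (high NDVI, across the
red edge) from background; thresholding it gives a plant mask, and the
masked reflectance is averaged per band into a single spectrum per plant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envi import ROLE_REFERENCE, RawCube
from .grids import CubeGeometry, WavelengthGrid, nearest_band

#: Universal NDVI segmentation threshold.
DEFAULT_NDVI_THRESHOLD = 0.20
NDVI_RED_EDGE_NM = 705.0
NDVI_NIR_NM = 750.0


class IncompatibleCubesError(ValueError):
    """Plant and reference cubes disagree in shape or wavelength grid."""


class EmptyPlantError(ValueError):
    """Segmentation produced no plant pixels."""


@dataclass
class ReflectanceCube:
    """Apparent reflectance (plant DN / reference DN), clipped to [0, 1].

    ``valid`` flags entries whose reference intensity was nonzero;
    invalid entries are excluded from every downstream average.
    """

    values: np.ndarray
    valid: np.ndarray
    grid: WavelengthGrid
    geometry: CubeGeometry


@dataclass
class NDVIImage:
    """Per-pixel (I750 - I705) / (I750 + I705) with eligibility flags."""

    values: np.ndarray
    eligible: np.ndarray
    i705_band: int
    i750_band: int


@dataclass
class PlantMask:
    """Boolean vegetation mask over (line, sample)."""

    member: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.member))


@dataclass
class ReflectanceSpectrum:
    """Mean apparent reflectance per band over the plant mask.

    ``n_pixels`` records, per band, how many masked pixels had valid
    reflectance; ``band_valid`` is False where no pixel contributed.
    """

    reflectance: np.ndarray
    grid: WavelengthGrid
    n_pixels: np.ndarray
    band_valid: np.ndarray


def normalize_by_reference(plant: RawCube, reference: RawCube) -> ReflectanceCube:
    """Divide a plant cube by its blank reference cube, band by band.

    Values are clipped to [0, 1]; voxels with zero reference intensity
    are marked invalid rather than produced as infinities.
    """
    if plant.values.shape != reference.values.shape:
        raise IncompatibleCubesError(
            f"shape mismatch {plant.values.shape} vs {reference.values.shape}"
        )
    if plant.grid != reference.grid:
        raise IncompatibleCubesError("wavelength grids differ")
    if reference.role != ROLE_REFERENCE:
        raise IncompatibleCubesError(
            f"reference cube has role {reference.role!r}, expected {ROLE_REFERENCE!r}"
        )
    ref = reference.values.astype(float)
    valid = ref > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = plant.values.astype(float) / ref
    values = np.clip(np.where(valid, ratio, 0.0), 0.0, 1.0)
    return ReflectanceCube(values, valid, plant.grid, plant.geometry)


def compute_ndvi(cube: ReflectanceCube) -> NDVIImage:
    """NDVI image from the bands nearest 705 and 750 nm.

    Pixels with an invalid input band or a zero band sum are flagged
    ineligible (they can never be classified as plant).
    """
    b705 = nearest_band(cube.grid, NDVI_RED_EDGE_NM)
    b750 = nearest_band(cube.grid, NDVI_NIR_NM)
    i705 = cube.values[:, :, b705]
    i750 = cube.values[:, :, b750]
    denom = i750 + i705
    eligible = cube.valid[:, :, b705] & cube.valid[:, :, b750] & (denom > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (i750 - i705) / denom
    values = np.where(eligible, ndvi, 0.0)
    return NDVIImage(values, eligible, b705, b750)


def segment_plant(
    ndvi: NDVIImage, threshold: float = DEFAULT_NDVI_THRESHOLD
) -> PlantMask:
    """Threshold the NDVI image: plant iff NDVI strictly above ``threshold``."""
    member = ndvi.eligible & (ndvi.values > threshold)
    return PlantMask(member)


def extract_mean_spectrum(cube: ReflectanceCube, mask: PlantMask) -> ReflectanceSpectrum:
    """Average masked, valid reflectance per band into one spectrum.

    Raises :class:`EmptyPlantError` for an empty mask. A band in which no
    masked pixel is valid is flagged (``band_valid`` False) rather than
    imputed.
    """
    if mask.member.shape != cube.values.shape[:2]:
        raise IncompatibleCubesError("mask shape does not match cube")
    if mask.n_pixels == 0:
        raise EmptyPlantError("segmentation produced an empty plant mask")
    contributing = mask.member[:, :, None] & cube.valid
    counts = contributing.sum(axis=(0, 1))
    sums = np.where(contributing, cube.values, 0.0).sum(axis=(0, 1))
    band_valid = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(band_valid, sums / np.maximum(counts, 1), np.nan)
    return ReflectanceSpectrum(means, cube.grid, counts, band_valid)


def process_scan(
    plant: RawCube,
    reference: RawCube,
    threshold: float = DEFAULT_NDVI_THRESHOLD,
    plant_id: str | None = None,
) -> ReflectanceSpectrum:
    """Full chain: normalize -> NDVI -> segment -> mean spectrum."""
    refl = normalize_by_reference(plant, reference)
    ndvi = compute_ndvi(refl)
    mask = segment_plant(ndvi, threshold)
    if mask.n_pixels == 0:
        label = f" for plant {plant_id!r}" if plant_id else ""
        raise EmptyPlantError(f"no pixels above NDVI {threshold}{label}")
    return extract_mean_spectrum(refl, mask)
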