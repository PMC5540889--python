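"""Spectral and spatial sampling grids of the push-broom imaging system.

The instrument scans one spatial line at a time; each line holds 320
detector pixels and every pixel records a full spectrum. The spectral
axis is a uniform grid of band centers. The instrument configuration of
interest spans 550-1700 nm in 243 bands, which with inclusive endpoints
gives a spacing of 1150/242 ~ 4.752 nm; the camera's nominal 4.77 nm
interval is carried as metadata only, since 243 such steps from 550 nm
would overshoot the stated 1700 nm endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Instrument constants: 550-1700 nm in 243 bands, 500 lines x 320 samples,
#: 5 mm square pixels.
INSTRUMENT_START_NM = 550.0
INSTRUMENT_END_NM = 1700.0
INSTRUMENT_N_BANDS = 243
INSTRUMENT_N_LINES = 500
INSTRUMENT_N_SAMPLES = 320
INSTRUMENT_PIXEL_MM = 5.0
NOMINAL_BAND_INTERVAL_NM = 4.77  # metadata only; not used to build the axis


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniformly spaced, strictly increasing band centers in nm."""

    band_centers_nm: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.band_centers_nm, dtype=float)
        object.__setattr__(self, "band_centers_nm", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("grid needs at least 2 band centers")
        diffs = np.diff(centers)
        if np.any(diffs <= 0):
            raise ValueError("band centers must be strictly increasing")
        # uniform spacing within 1e-9 relative tolerance
        if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=0.0):
            raise ValueError("band centers must be uniformly spaced")

    @property
    def n_bands(self) -> int:
        return self.band_centers_nm.size

    @property
    def spacing_nm(self) -> float:
        return float(
            (self.band_centers_nm[-1] - self.band_centers_nm[0]) / (self.n_bands - 1)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.band_centers_nm, other.band_centers_nm)

    def __hash__(self):
        return hash(self.band_centers_nm.tobytes())


@dataclass(frozen=True)
class CubeGeometry:
    """Spatial layout of a scan: lines x samples with square pixels (mm)."""

    n_lines: int
    n_samples: int
    pixel_size_mm: float

    def __post_init__(self):
        if self.n_lines < 1 or self.n_samples < 1:
            raise ValueError("geometry dimensions must be positive")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def vertical_coverage_mm(self) -> float:
        """Chamber height covered by the scan (n_lines x pixel size)."""
        return self.n_lines * self.pixel_size_mm

    @property
    def horizontal_coverage_mm(self) -> float:
        return self.n_samples * self.pixel_size_mm


def build_wavelength_grid(
    start_nm: float, end_nm: float, n_bands: int
) -> WavelengthGrid:
    """Build a uniform band-center grid with inclusive endpoints.

    Parameters
    ----------
    start_nm, end_nm
        First and last band center (nm); ``start_nm < end_nm``.
    n_bands
        Number of bands (>= 2).
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if not start_nm < end_nm:
        raise ValueError("start_nm must be strictly less than end_nm")
    return WavelengthGrid(np.linspace(start_nm, end_nm, n_bands))


def instrument_grid() -> WavelengthGrid:
    """The imaging spectrometer's 243-band 550-1700 nm grid."""
    return build_wavelength_grid(
        INSTRUMENT_START_NM, INSTRUMENT_END_NM, INSTRUMENT_N_BANDS
    )


def instrument_geometry() -> CubeGeometry:
    """The full imaging-chamber scan geometry (500 x 320, 5 mm pixels)."""
    return CubeGeometry(INSTRUMENT_N_LINES, INSTRUMENT_N_SAMPLES, INSTRUMENT_PIXEL_MM)


def nearest_band(grid: WavelengthGrid, target_nm: float) -> int:
    """Index of the band center closest to ``target_nm``.

    Ties (target exactly midway between two centers) break toward the
    lower index. Targets more than one band spacing outside the grid
    raise ``ValueError``.
    """
    centers = grid.band_centers_nm
    spacing = grid.spacing_nm
    if target_nm < centers[0] - spacing or target_nm > centers[-1] + spacing:
        raise ValueError(
            f"target {target_nm} nm is outside the grid "
            f"[{centers[0]}, {centers[-1]}] nm (+/- one band)"
        )
    dist = np.abs(centers - target_nm)
    return int(np.argmin(dist))  # argmin returns the first (lower) index on ties
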