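"""Reading and writing ENVI-style BIL hyperspectral cubes.

A cube is stored as a raw binary payload (``.bil``) plus a plain-text
key/value sidecar header (``.hdr``). Only the configuration the imaging
system produces is supported: 16-bit unsigned integers, band-interleaved
-by-line (BIL) layout. In BIL order the payload iterates lines slowest,
then bands, then samples within a line.

The in-memory convention everywhere in this package is a 3-D array
indexed ``(line, sample, band)``, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import CubeGeometry, WavelengthGrid

#: Scan roles: a plant scan or the paired blank-chamber reference scan.
ROLE_PLANT = "plant-scan"
ROLE_REFERENCE = "reference-scan"

_ENVI_DTYPE_U16 = 12  # ENVI data type code for uint16
_BYTE_ORDER_CODE = {"little": 0, "big": 1}


class CorruptFileError(IOError):
    """Payload size does not match the header's declared dimensions."""


class UnsupportedFormatError(IOError):
    """Header declares an interleave or data type this reader does not handle."""


@dataclass
class RawCube:
    """A raw digital-number image cube with its grids and scan role.

    ``values`` is ``uint16``, indexed ``(line, sample, band)``.
    """

    values: np.ndarray
    grid: WavelengthGrid
    geometry: CubeGeometry
    role: str = ROLE_PLANT
    extra_header: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError("cube values must be 3-D (line, sample, band)")
        if values.dtype != np.uint16:
            if np.issubdtype(values.dtype, np.integer) or np.issubdtype(
                values.dtype, np.floating
            ):
                if values.size and (values.min() < 0 or values.max() > 0xFFFF):
                    raise ValueError("intensities must fit in 16 bits")
                values = values.astype(np.uint16)
            else:
                raise ValueError("cube values must be numeric")
        self.values = values
        expected = (self.geometry.n_lines, self.geometry.n_samples, self.grid.n_bands)
        if values.shape != expected:
            raise ValueError(
                f"cube shape {values.shape} inconsistent with geometry/grid {expected}"
            )
        if self.role not in (ROLE_PLANT, ROLE_REFERENCE):
            raise ValueError(f"unknown scan role {self.role!r}")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def _header_path(data_path: Path) -> Path:
    return data_path.with_suffix(data_path.suffix + ".hdr")


def _format_header(cube: RawCube, byte_order: str) -> str:
    g = cube.geometry
    # full float precision so the grid round-trips bit-exactly
    wl = ", ".join(repr(float(w)) for w in cube.grid.band_centers_nm)
    lines = [
        "ENVI",
        f"samples = {g.n_samples}",
        f"lines = {g.n_lines}",
        f"bands = {cube.grid.n_bands}",
        "interleave = bil",
        f"data type = {_ENVI_DTYPE_U16}",
        f"byte order = {_BYTE_ORDER_CODE[byte_order]}",
        f"pixel size mm = {g.pixel_size_mm}",
        f"scan role = {cube.role}",
        "wavelength units = nm",
        "wavelength = { " + wl + " }",
    ]
    for key, value in cube.extra_header.items():
        lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def parse_envi_header(text: str) -> dict:
    """Parse a minimal ENVI key/value header into a dict of strings.

    Multi-line ``{ ... }`` values are joined; unknown keys are preserved
    verbatim so they survive a read/write round trip.
    """
    header: dict[str, str] = {}
    body = text.strip()
    if body.startswith("ENVI"):
        body = body[4:]
    # join brace-delimited blocks onto single lines
    merged: list[str] = []
    buffer = ""
    depth = 0
    for raw in body.splitlines():
        line = raw.strip()
        if not line:
            continue
        buffer = f"{buffer} {line}".strip() if buffer else line
        depth += line.count("{") - line.count("}")
        if depth == 0:
            merged.append(buffer)
            buffer = ""
    if buffer:
        raise CorruptFileError("unterminated '{' block in header")
    for line in merged:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        header[key.strip().lower()] = value.strip()
    return header


def write_bil(cube: RawCube, data_path) -> tuple[Path, Path]:
    """Write a cube as a ``.bil`` payload plus ``.hdr`` sidecar.

    Returns the (payload, header) paths. The payload is little-endian
    uint16 in BIL order; ``read_bil`` inverts it bit-exactly.
    """
    data_path = Path(data_path)
    byte_order = "little"
    # (line, sample, band) -> BIL on disk is (line, band, sample)
    bil = np.ascontiguousarray(np.transpose(cube.values, (0, 2, 1)))
    data_path.write_bytes(bil.astype("<u2").tobytes())
    header_file = _header_path(data_path)
    header_file.write_text(_format_header(cube, byte_order))
    return data_path, header_file


def read_bil(data_path, header: dict | None = None) -> RawCube:
    """Read a ``.bil``/``.hdr`` pair into a :class:`RawCube`.

    ``header`` may be passed pre-parsed; otherwise the ``.hdr`` sidecar
    next to ``data_path`` is read. Raises :class:`CorruptFileError` on a
    size mismatch and :class:`UnsupportedFormatError` for anything other
    than 16-bit BIL.
    """
    data_path = Path(data_path)
    if header is None:
        header_file = _header_path(data_path)
        if not header_file.exists():
            raise FileNotFoundError(f"missing header sidecar {header_file}")
        header = parse_envi_header(header_file.read_text())

    interleave = header.get("interleave", "bil").lower()
    if interleave != "bil":
        raise UnsupportedFormatError(f"unsupported interleave {interleave!r}")
    dtype_code = int(header.get("data type", _ENVI_DTYPE_U16))
    if dtype_code != _ENVI_DTYPE_U16:
        raise UnsupportedFormatError(f"unsupported ENVI data type {dtype_code}")
    n_samples = int(header["samples"])
    n_lines = int(header["lines"])
    n_bands = int(header["bands"])
    byte_order = int(header.get("byte order", 0))
    dtype = "<u2" if byte_order == 0 else ">u2"

    payload = data_path.read_bytes()
    expected_bytes = n_lines * n_samples * n_bands * 2
    if len(payload) != expected_bytes:
        raise CorruptFileError(
            f"payload is {len(payload)} bytes, header implies {expected_bytes}"
        )
    bil = np.frombuffer(payload, dtype=dtype).reshape(n_lines, n_bands, n_samples)
    values = np.ascontiguousarray(np.transpose(bil, (0, 2, 1))).astype(np.uint16)

    wl_text = header.get("wavelength", "").strip().strip("{}").strip()
    if wl_text:
        centers = np.array([float(v) for v in wl_text.split(",")])
    else:
        centers = np.arange(n_bands, dtype=float)
    grid = WavelengthGrid(centers)

    pixel_mm = float(header.get("pixel size mm", 1.0))
    geometry = CubeGeometry(n_lines, n_samples, pixel_mm)
    role = header.get("scan role", ROLE_PLANT)

    known = {
        "samples", "lines", "bands", "interleave", "data type", "byte order",
        "pixel size mm", "scan role", "wavelength units", "wavelength",
    }
    extra = {k: v for k, v in header.items() if k not in known}
    return RawCube(values, grid, geometry, role=role, extra_header=extra)
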