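"""Coordinate conversion and MODIS sinusoidal grid arithmetic.

The MODIS land grid lives on a sphere of radius 6371007.181 m under the
sinusoidal projection x = R*lon*cos(lat), y = R*lat (angles in radians).
Tiles delivered by the subset service are odd-dimensioned rectangles of
pixels centred on the focal pixel (the pixel containing the requested
coordinate); the tile half-width is requested in whole kilometres and
translated to pixel counts using the *nominal* resolution class (250, 500
or 1000 m), while corner coordinates and cell sizes use the exact
sinusoidal cell size (231.656358 m for the 250 m class).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "EARTH_RADIUS_M",
    "MAX_SIZE_KM",
    "SizeKm",
    "TileGeometry",
    "convert_to_dd",
    "sinusoidal_forward",
    "sinusoidal_inverse",
    "modis_tile_hv",
    "snap_to_grid",
    "tile_dims",
    "tile_geometry_for",
    "extract_tile",
]

#: Radius of the MODIS sinusoidal sphere, metres.
EARTH_RADIUS_M = 6371007.181

#: Half the global east-west extent of the sinusoidal plane, metres (pi*R).
_GLOBAL_XMAX = math.pi * EARTH_RADIUS_M
_GLOBAL_YMAX = _GLOBAL_XMAX / 2.0

#: Largest north/south or east/west half-width accepted by the subset
#: service, kilometres.
MAX_SIZE_KM = 100


@dataclass(frozen=True)
class SizeKm:
    """Area of interest around the focal pixel, km north/south and east/west."""

    km_ns: int
    km_ew: int

    def __post_init__(self) -> None:
        for name, km in (("km_ns", self.km_ns), ("km_ew", self.km_ew)):
            if km != int(km) or km < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {km}")
            if km > MAX_SIZE_KM:
                raise ValueError(
                    f"{name}={km} exceeds maximum area of interest "
                    f"({MAX_SIZE_KM},{MAX_SIZE_KM})"
                )


@dataclass(frozen=True)
class TileGeometry:
    """Pixel-grid shape and placement of one subset tile."""

    nrows: int
    ncols: int
    cell_size_m: float
    xll_m: float
    yll_m: float

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("tile dimensions must be >= 1")
        if self.nrows % 2 == 0 or self.ncols % 2 == 0:
            raise ValueError("tile dimensions must be odd (focal pixel centred)")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def n_pixels(self) -> int:
        return self.nrows * self.ncols


_DMS_RE = re.compile(
    r"""^\s*([+-]?)(\d+(?:\.\d+)?)
        (?:[°d\s]\s*(\d+(?:\.\d+)?)
        (?:['m\s]\s*(\d+(?:\.\d+)?))?)?
        \s*["s]?\s*([NSEWnsew]?)\s*$""",
    re.VERBOSE,
)


def convert_to_dd(coord: str | Sequence[float]) -> float:
    """Convert degrees-minutes-seconds or degrees-decimal-minutes to decimal degrees.

    Accepts a string such as ``"51 28 38 N"``, ``"147° 32.90412' E"`` or
    ``"-33.5"``, or a sequence ``(deg, min[, sec][, hemisphere])``.  Sign may
    be given on the degrees or as a hemisphere letter (N/S/E/W); giving both
    with conflicting meaning is an error rather than a silent preference.
    """
    if isinstance(coord, str):
        m = _DMS_RE.match(coord)
        if m is None:
            raise ValueError(f"unparseable coordinate: {coord!r}")
        sign_str, deg_s, min_s, sec_s, hemi = m.groups()
        deg = float(deg_s)
        minutes = float(min_s) if min_s is not None else 0.0
        seconds = float(sec_s) if sec_s is not None else 0.0
    else:
        parts = list(coord)
        hemi = ""
        sign_str = ""
        if parts and isinstance(parts[-1], str):
            hemi = parts.pop(-1)
        if not parts:
            raise ValueError("empty coordinate")
        deg = float(parts[0])
        if deg < 0:
            sign_str = "-"
            deg = -deg
        minutes = float(parts[1]) if len(parts) > 1 else 0.0
        seconds = float(parts[2]) if len(parts) > 2 else 0.0

    if not 0 <= minutes < 60:
        raise ValueError(f"minutes out of range [0, 60): {minutes}")
    if not 0 <= seconds < 60:
        raise ValueError(f"seconds out of range [0, 60): {seconds}")

    hemi = hemi.upper()
    sign = -1.0 if sign_str == "-" else 1.0
    if hemi:
        hemi_sign = -1.0 if hemi in "SW" else 1.0
        if sign_str == "-" and hemi_sign > 0:
            raise ValueError(
                f"explicit negative sign conflicts with hemisphere {hemi!r}"
            )
        sign = hemi_sign

    dd = sign * (deg + minutes / 60.0 + seconds / 3600.0)
    limit = 90.0 if hemi in ("N", "S") else 180.0
    if abs(dd) > limit:
        raise ValueError(f"coordinate {dd} outside ±{limit}")
    return dd


def _check_latlon(lat: float, lon: float) -> None:
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside ±90")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} outside ±180")


def sinusoidal_forward(lat: float, lon: float) -> tuple[float, float]:
    """Project (lat, lon) in decimal degrees onto the MODIS sinusoidal plane."""
    _check_latlon(lat, lon)
    phi = math.radians(lat)
    lam = math.radians(lon)
    return EARTH_RADIUS_M * lam * math.cos(phi), EARTH_RADIUS_M * phi


def sinusoidal_inverse(x_m: float, y_m: float) -> tuple[float, float]:
    """Invert :func:`sinusoidal_forward`; undefined at the poles (cos(lat)=0)."""
    phi = y_m / EARTH_RADIUS_M
    cos_phi = math.cos(phi)
    if abs(cos_phi) < 1e-12:
        raise ValueError("inverse projection undefined at the poles")
    lam = x_m / (EARTH_RADIUS_M * cos_phi)
    return math.degrees(phi), math.degrees(lam)


def modis_tile_hv(lat: float, lon: float) -> tuple[int, int]:
    """MODIS land-grid tile indices (h: 0-35 west to east, v: 0-17 north to south)."""
    x, y = sinusoidal_forward(lat, lon)
    tile_w = 2.0 * _GLOBAL_XMAX / 36.0
    h = int((x + _GLOBAL_XMAX) // tile_w)
    v = int((_GLOBAL_YMAX - y) // tile_w)
    return min(max(h, 0), 35), min(max(v, 0), 17)


def snap_to_grid(x_m: float, y_m: float, cell_size_m: float) -> tuple[float, float]:
    """Lower-left corner of the grid cell containing (x, y).

    The global pixel grid is anchored at the south-west corner of the
    sinusoidal plane, (-pi*R, -pi*R/2).
    """
    fx = -_GLOBAL_XMAX + math.floor((x_m + _GLOBAL_XMAX) / cell_size_m) * cell_size_m
    fy = -_GLOBAL_YMAX + math.floor((y_m + _GLOBAL_YMAX) / cell_size_m) * cell_size_m
    return fx, fy


def tile_dims(size: SizeKm, nominal_resolution_m: int) -> tuple[int, int]:
    """Pixel counts (nrows, ncols) of the tile a :class:`SizeKm` requests.

    Pixels per dimension = 2*(km*1000 // nominal_resolution) + 1, using the
    nominal resolution class with integer division: (1,1) at 250 m gives a
    9x9 (81-pixel) tile, (3,3) a 25x25 tile (a 6.25 km edge in nominal
    arithmetic), (0,0) the focal pixel only.
    """
    size = size if isinstance(size, SizeKm) else SizeKm(*size)
    nrows = 2 * (size.km_ns * 1000 // nominal_resolution_m) + 1
    ncols = 2 * (size.km_ew * 1000 // nominal_resolution_m) + 1
    return nrows, ncols


def tile_geometry_for(
    lat: float, lon: float, size: SizeKm, nominal_resolution_m: int, cell_size_m: float
) -> TileGeometry:
    """Full tile geometry centred on the focal pixel containing (lat, lon).

    The focal pixel is snapped to the global sinusoidal grid; the tile's
    lower-left corner sits (nrows-1)/2 pixels south and (ncols-1)/2 pixels
    west of the focal pixel's lower-left corner.
    """
    nrows, ncols = tile_dims(size, nominal_resolution_m)
    x, y = sinusoidal_forward(lat, lon)
    fx, fy = snap_to_grid(x, y, cell_size_m)
    return TileGeometry(
        nrows=nrows,
        ncols=ncols,
        cell_size_m=cell_size_m,
        xll_m=fx - (ncols - 1) // 2 * cell_size_m,
        yll_m=fy - (nrows - 1) // 2 * cell_size_m,
    )


def extract_tile(
    values: Sequence,
    geom: TileGeometry | tuple[int, int],
    inner: SizeKm,
    nominal_resolution_m: int,
) -> list:
    """Centred sub-tile of a row-major flattened tile.

    ``values`` runs row-major from the north-west corner.  ``inner`` is
    translated to pixel counts with :func:`tile_dims`; extracting with the
    outer tile's own size is the identity.
    """
    if isinstance(geom, TileGeometry):
        nrows, ncols = geom.nrows, geom.ncols
    else:
        nrows, ncols = geom
    if len(values) != nrows * ncols:
        raise ValueError(
            f"tile has {len(values)} values but dimensions {nrows}x{ncols} "
            f"require {nrows * ncols}"
        )
    in_rows, in_cols = tile_dims(inner, nominal_resolution_m)
    if in_rows > nrows or in_cols > ncols:
        raise ValueError(
            f"inner tile {in_rows}x{in_cols} exceeds outer {nrows}x{ncols}"
        )
    r0 = (nrows - in_rows) // 2
    c0 = (ncols - in_cols) // 2
    out = []
    for r in range(r0, r0 + in_rows):
        out.extend(values[r * ncols + c0 : r * ncols + c0 + in_cols])
    return out
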