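"""Export subset records as ESRI ASCII raster grids with a PRJ sidecar.

Each composite date of each band becomes one ``.asc`` grid: the standard
six-line header (NCOLS, NROWS, XLLCORNER, YLLCORNER, CELLSIZE,
NODATA_VALUE) followed by rows of stored-unit integers, top row
northernmost.  The sidecar ``.prj`` carries well-known text for the MODIS
sinusoidal projection on the sphere of radius 6371007.181 m, so standard
GIS software imports the grids in the correct datum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .catalog import BandSpec
from .geometry import EARTH_RADIUS_M
from .subset_io import SubsetRecord

__all__ = [
    "AsciiGrid",
    "SINUSOIDAL_WKT",
    "record_to_grid",
    "write_grid",
    "read_grid",
    "export_records",
    "grid_filename",
]

SINUSOIDAL_WKT = (
    'PROJCS["MODIS Sinusoidal",'
    'GEOGCS["GCS_Sphere",'
    f'DATUM["D_Sphere",SPHEROID["Sphere",{EARTH_RADIUS_M},0.0]],'
    'PRIMEM["Greenwich",0.0],UNIT["Degree",0.0174532925199433]],'
    'PROJECTION["Sinusoidal"],'
    'PARAMETER["False_Easting",0.0],'
    'PARAMETER["False_Northing",0.0],'
    'PARAMETER["Central_Meridian",0.0],'
    'UNIT["Meter",1.0]]'
)


@dataclass(frozen=True)
class AsciiGrid:
    """One raster: header metadata plus rows of values, north row first."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: int
    rows: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.rows) != self.nrows:
            raise ValueError(f"{len(self.rows)} rows but nrows={self.nrows}")
        if any(len(r) != self.ncols for r in self.rows):
            raise ValueError("ragged rows: every row must have ncols values")


def record_to_grid(
    r: SubsetRecord, band: BandSpec, scaled: bool = False
) -> AsciiGrid:
    """Lay a record's row-major values out as a grid.

    By default cells hold stored-unit integers with the band fill as
    NODATA; with ``scaled`` the valid cells are multiplied by the band's
    scale factor (fill cells still carry the integer fill sentinel).
    """
    if len(r.values) != r.nrows * r.ncols:
        raise ValueError("record values do not fill its tile dimensions")
    rows = []
    for i in range(r.nrows):
        row = r.values[i * r.ncols : (i + 1) * r.ncols]
        if scaled:
            row = tuple(
                v * band.scale_factor if v != band.no_data_fill else v
                for v in row
            )
        rows.append(tuple(row))
    return AsciiGrid(
        ncols=r.ncols,
        nrows=r.nrows,
        xllcorner=r.xll_m,
        yllcorner=r.yll_m,
        cellsize=r.cell_size_m,
        nodata_value=band.no_data_fill,
        rows=tuple(rows),
    )


def _fmt_cell(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6f}"


def write_grid(g: AsciiGrid, path: str | Path) -> None:
    """Write the grid plus its ``.prj`` sidecar."""
    path = Path(path)
    header = [
        f"NCOLS {g.ncols}",
        f"NROWS {g.nrows}",
        f"XLLCORNER {_fmt_cell(g.xllcorner)}",
        f"YLLCORNER {_fmt_cell(g.yllcorner)}",
        f"CELLSIZE {g.cellsize:.4f}",
        f"NODATA_VALUE {g.nodata_value}",
    ]
    body = [" ".join(_fmt_cell(v) for v in row) for row in g.rows]
    path.write_text("\n".join(header + body) + "\n", encoding="ascii")
    path.with_suffix(path.suffix + ".prj").write_text(
        SINUSOIDAL_WKT + "\n", encoding="ascii"
    )


def read_grid(path: str | Path) -> AsciiGrid:
    """Parse a written grid back (round trip is lossless for integer grids)."""
    lines = Path(path).read_text(encoding="ascii").splitlines()
    header: dict[str, float] = {}
    for line in lines[:6]:
        key, value = line.split(maxsplit=1)
        header[key.upper()] = float(value)
    rows = tuple(
        tuple(float(v) for v in line.split()) for line in lines[6:] if line.strip()
    )
    return AsciiGrid(
        ncols=int(header["NCOLS"]),
        nrows=int(header["NROWS"]),
        xllcorner=header["XLLCORNER"],
        yllcorner=header["YLLCORNER"],
        cellsize=header["CELLSIZE"],
        nodata_value=int(header["NODATA_VALUE"]),
        rows=rows,
    )


def grid_filename(site_id: str, band: str, date_code: str) -> str:
    return f"{site_id}__{band}__{date_code}.asc"


def export_records(
    records: Sequence[SubsetRecord],
    site_id: str,
    band: BandSpec,
    out_dir: str | Path,
    scaled: bool = False,
) -> list[Path]:
    """One grid file per composite date for one site/band."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for r in records:
        if r.band != band.band_name:
            continue
        path = out_dir / grid_filename(site_id, band.band_name, r.date_code)
        write_grid(record_to_grid(r, band, scaled=scaled), path)
        written.append(path)
    return written
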