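"""Read/write the ORNL ASCII subset dialect, site tables and date codes.

A subset file is comma-separated with no header; each row is one composite
date of one band for one site.  The first ten fields describe the tile
(rows, columns, lower-left x and y in sinusoidal metres, pixel size, the
full granule identifier, product code, A[YYYYDDD] date code, a
``Lat...Lon...Samp...Line...`` location tag, and the product processing
stamp); every following field is one pixel value in stored integer units,
ordered by row from the north-west corner.
"""

from __future__ import annotations

import datetime as dt
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SubsetFormatError",
    "DuplicateConflictError",
    "CompositeDate",
    "SubsetRecord",
    "SiteRequest",
    "parse_date_code",
    "format_date_code",
    "parse_subset_file",
    "write_subset_file",
    "subset_filename",
    "site_id_from_filename",
    "read_site_table",
    "collate_time_series",
]

N_HEADER_FIELDS = 10


class SubsetFormatError(ValueError):
    """A subset file/row that violates the ASCII dialect."""


class DuplicateConflictError(ValueError):
    """Two records for the same (site, band, date) disagree on values."""


@dataclass(frozen=True, order=True)
class CompositeDate:
    """A composite date expressed as year plus day-of-year."""

    year: int
    doy: int

    def __post_init__(self) -> None:
        if not 2000 <= self.year <= 2099:
            raise SubsetFormatError(f"date code year {self.year} outside 2000-2099")
        days = 366 if _is_leap(self.year) else 365
        if not 1 <= self.doy <= days:
            raise SubsetFormatError(
                f"day-of-year {self.doy} invalid for year {self.year}"
            )

    @property
    def calendar_date(self) -> dt.date:
        return dt.date(self.year, 1, 1) + dt.timedelta(days=self.doy - 1)

    @classmethod
    def from_date(cls, d: dt.date) -> "CompositeDate":
        return cls(d.year, d.timetuple().tm_yday)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


_DATE_CODE_RE = re.compile(r"^A(\d{4})(\d{3})$")


def parse_date_code(code: str) -> CompositeDate:
    """Parse an ``A[YYYYDDD]`` date code such as ``A2009001`` (2009 Jan 1)."""
    m = _DATE_CODE_RE.match(code)
    if m is None:
        raise SubsetFormatError(f"malformed date code: {code!r}")
    return CompositeDate(int(m.group(1)), int(m.group(2)))


def format_date_code(d: CompositeDate | dt.date) -> str:
    if isinstance(d, dt.date):
        d = CompositeDate.from_date(d)
    return f"A{d.year:04d}{d.doy:03d}"


_LOCATION_RE = re.compile(
    r"^Lat(-?\d+(?:\.\d+)?)Lon(-?\d+(?:\.\d+)?)Samp(\d+)Line(\d+)$"
)


def _fmt_num(v: float, max_decimals: int = 10) -> str:
    """Fixed-notation decimal with trailing zeros trimmed (never scientific)."""
    s = f"{v:.{max_decimals}f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


@dataclass(frozen=True)
class SubsetRecord:
    """One dated tile of one band for one site (one subset-file row)."""

    nrows: int
    ncols: int
    xll_m: float
    yll_m: float
    cell_size_m: float
    unique_id: str
    product: str
    date_code: str
    lat: float
    lon: float
    processed_stamp: str
    values: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.values) != self.nrows * self.ncols:
            raise SubsetFormatError(
                f"{len(self.values)} values but Samp x Line = "
                f"{self.ncols} x {self.nrows}"
            )
        parse_date_code(self.date_code)  # validates
        if self.product not in self.unique_id:
            raise SubsetFormatError(
                f"unique_id {self.unique_id!r} does not embed product "
                f"{self.product!r}"
            )
        if self.date_code not in self.unique_id:
            raise SubsetFormatError(
                f"unique_id {self.unique_id!r} does not embed date code "
                f"{self.date_code!r}"
            )

    @property
    def band(self) -> str:
        """Band (Science Data Set) name, the final dotted unique_id component."""
        return self.unique_id.split(".", 5)[-1]

    @property
    def composite_date(self) -> CompositeDate:
        return parse_date_code(self.date_code)

    @property
    def location_tag(self) -> str:
        return (
            f"Lat{_fmt_num(self.lat)}Lon{_fmt_num(self.lon)}"
            f"Samp{self.ncols}Line{self.nrows}"
        )

    def to_row(self) -> str:
        fields = [
            str(self.nrows),
            str(self.ncols),
            _fmt_num(self.xll_m, 6),
            _fmt_num(self.yll_m, 6),
            f"{self.cell_size_m:.4f}",
            self.unique_id,
            self.product,
            self.date_code,
            self.location_tag,
            self.processed_stamp,
        ]
        fields.extend(str(v) for v in self.values)
        return ",".join(fields)


def _parse_row(row: str, lineno: int) -> SubsetRecord:
    fields = row.strip().split(",")
    if len(fields) < N_HEADER_FIELDS + 1:
        raise SubsetFormatError(
            f"row {lineno}: expected at least {N_HEADER_FIELDS + 1} fields, "
            f"got {len(fields)}"
        )
    try:
        nrows, ncols = int(fields[0]), int(fields[1])
        xll, yll = float(fields[2]), float(fields[3])
        cell = float(fields[4])
    except ValueError as exc:
        raise SubsetFormatError(f"row {lineno}: non-numeric header field: {exc}")
    unique_id, product, date_code, tag, stamp = fields[5:10]
    m = _LOCATION_RE.match(tag)
    if m is None:
        raise SubsetFormatError(f"row {lineno}: malformed location tag {tag!r}")
    lat, lon = float(m.group(1)), float(m.group(2))
    samp, line = int(m.group(3)), int(m.group(4))
    if samp != ncols or line != nrows:
        raise SubsetFormatError(
            f"row {lineno}: Samp/Line ({samp},{line}) disagree with tile "
            f"columns/rows ({ncols},{nrows})"
        )
    raw_values = fields[10:]
    if len(raw_values) != samp * line:
        raise SubsetFormatError(
            f"row {lineno}: {len(raw_values)} data values but Samp x Line = "
            f"{samp * line}"
        )
    try:
        values = tuple(int(v) for v in raw_values)
    except ValueError:
        raise SubsetFormatError(f"row {lineno}: non-numeric data value")
    try:
        return SubsetRecord(
            nrows=nrows,
            ncols=ncols,
            xll_m=xll,
            yll_m=yll,
            cell_size_m=cell,
            unique_id=unique_id,
            product=product,
            date_code=date_code,
            lat=lat,
            lon=lon,
            processed_stamp=stamp,
            values=values,
        )
    except SubsetFormatError as exc:
        raise SubsetFormatError(f"row {lineno}: {exc}")


def parse_subset_file(source: str | Path | io.TextIOBase) -> list[SubsetRecord]:
    """Parse a comma-separated, header-less subset file into records.

    Records are returned ordered by (band, composite date) ascending.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="ascii")
    else:
        text = source.read()
    records = []
    for lineno, row in enumerate(text.splitlines(), start=1):
        if row.strip():
            records.append(_parse_row(row, lineno))
    records.sort(key=lambda r: (r.band, r.composite_date))
    return records


def write_subset_file(records: Sequence[SubsetRecord], path: str | Path) -> None:
    """Write records as comma-separated header-less rows (Table-dialect order).

    ``parse_subset_file`` of the written file recovers the records exactly.
    """
    path = Path(path)
    ordered = sorted(records, key=lambda r: (r.band, r.composite_date))
    try:
        path.write_text(
            "".join(r.to_row() + "\n" for r in ordered), encoding="ascii"
        )
    except OSError as exc:
        raise OSError(f"cannot write subset file {path}: {exc}") from exc


def subset_filename(site_id: str, product: str) -> str:
    return f"{site_id}__{product}.asc"


def site_id_from_filename(path: str | Path) -> str:
    stem = Path(path).name
    if stem.endswith(".asc"):
        stem = stem[: -len(".asc")]
    return stem.rsplit("__", 1)[0]


@dataclass(frozen=True)
class SiteRequest:
    """One row of the user's site table: where and when to subset."""

    site_id: str
    lat: float
    lon: float
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if abs(self.lat) > 90:
            raise ValueError(f"latitude {self.lat} outside ±90")
        if abs(self.lon) > 180:
            raise ValueError(f"longitude {self.lon} outside ±180")
        if self.start_date > self.end_date:
            raise ValueError(
                f"start date {self.start_date} after end date {self.end_date} "
                f"for site {self.site_id}"
            )


def _parse_table_date(value, row: int, column: str, year_end: bool) -> dt.date:
    """Dates may be years (YYYY) or POSIX-style YYYY-MM-DD strings."""
    if pd.isna(value):
        raise SubsetFormatError(f"row {row}: missing {column}")
    s = str(value).strip()
    if re.fullmatch(r"\d{4}(\.0)?", s):
        year = int(float(s))
        return dt.date(year, 12, 31) if year_end else dt.date(year, 1, 1)
    try:
        return dt.date.fromisoformat(s)
    except ValueError:
        raise SubsetFormatError(
            f"row {row}: unparseable {column} value {value!r}"
        )


def read_site_table(
    path: str | Path | io.TextIOBase,
    time_series_length: int = 0,
) -> list[SiteRequest]:
    """Read a delimited site table into :class:`SiteRequest` objects.

    The table must carry columns ``lat``, ``long`` and ``end.date``;
    ``start.date`` and ``ID`` are optional.  Year-only end dates resolve to
    December 31, year-only start dates to January 1; when ``start.date`` is
    absent the window opens on January 1 of (end year - time_series_length).
    Missing IDs are generated as ``Site<k>__<lat>_<long>`` with coordinates
    at six decimal places.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("lat", "long", "end.date"):
        if col not in df.columns:
            raise SubsetFormatError(f"site table is missing column {col!r}")
    if time_series_length < 0:
        raise ValueError("time_series_length must be non-negative")

    id_col = next((c for c in ("ID", "id") if c in df.columns), None)
    requests: list[SiteRequest] = []
    seen: set[str] = set()
    for k, (_, row) in enumerate(df.iterrows(), start=1):
        rownum = k + 1  # 1-based plus header line
        lat, lon = float(row["lat"]), float(row["long"])
        end = _parse_table_date(row["end.date"], rownum, "end.date", year_end=True)
        if "start.date" in df.columns and not pd.isna(row.get("start.date")):
            start = _parse_table_date(
                row["start.date"], rownum, "start.date", year_end=False
            )
        else:
            start = dt.date(end.year - time_series_length, 1, 1)
        if id_col is not None and not pd.isna(row[id_col]):
            site_id = str(row[id_col])
        else:
            site_id = f"Site{k}__{lat:.6f}_{lon:.6f}"
        if site_id in seen:
            raise SubsetFormatError(f"duplicate site ID {site_id!r}")
        seen.add(site_id)
        requests.append(
            SiteRequest(
                site_id=site_id, lat=lat, lon=lon, start_date=start, end_date=end
            )
        )
    return requests


def collate_time_series(
    paths: Iterable[str | Path], band: str
) -> pd.DataFrame:
    """Collate many subset files into one (site, pixel) x date value table.

    Returns a DataFrame with a (site_id, pixel) MultiIndex, one column per
    composite calendar date, and stored-unit values as floats; slots with no
    record are NaN (missing, never zero).  The result is independent of the
    order in which files are given.
    """
    cells: dict[tuple[str, int], dict[dt.date, float]] = {}
    for path in sorted(Path(p) for p in paths):
        site = site_id_from_filename(path)
        for rec in parse_subset_file(path):
            if rec.band != band:
                continue
            date = rec.composite_date.calendar_date
            for pixel, value in enumerate(rec.values):
                slot = cells.setdefault((site, pixel), {})
                if date in slot and slot[date] != value:
                    raise DuplicateConflictError(
                        f"conflicting values for site {site!r}, band {band!r}, "
                        f"pixel {pixel}, date {date}: {slot[date]} vs {value}"
                    )
                slot[date] = float(value)
    if not cells:
        return pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["site_id", "pixel"])
        )
    frame = pd.DataFrame.from_dict(cells, orient="index").sort_index(axis=1)
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["site_id", "pixel"])
    frame.sort_index(inplace=True)
    frame = frame.astype(float)
    return frame
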