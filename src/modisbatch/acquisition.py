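"""Batch subset acquisition: fetch, persist, log, retry, update.

Transport is an injectable :class:`SubsetSource`; the package ships
:class:`FixtureSource`, which serves records from a local archive in the
ASCII subset dialect, and a skeletal HTTP adapter left unwired (the original
SOAP service is historical).  For each unique (site, product) request the
downloader writes one subset file holding every requested band, retrying
transient failures within a per-subset window (15 minutes by default, with
a 30 s pause between attempts) and making a second pass over anything the
first pass could not fetch before marking it Failed.  Every request gets
exactly one row in the download log.
"""

from __future__ import annotations

import datetime as dt
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

from . import catalog, geometry, subset_io
from .geometry import SizeKm
from .subset_io import SiteRequest, SubsetRecord

__all__ = [
    "SourceError",
    "TransientSourceError",
    "PermanentSourceError",
    "SubsetSource",
    "FixtureSource",
    "HttpSource",
    "Clock",
    "SystemClock",
    "FakeClock",
    "RetryPolicy",
    "DownloadLogEntry",
    "DownloadLog",
    "LOG_FILENAME",
    "download_subsets",
    "update_subsets",
]

logger = logging.getLogger(__name__)

LOG_FILENAME = "download_log.txt"
_LOG_COLUMNS = (
    "site_id",
    "product",
    "bands",
    "size_ns",
    "size_ew",
    "start_date",
    "end_date",
    "status",
    "attempts",
    "message",
    "timestamp",
)


class SourceError(Exception):
    """Base failure reported by a subset source."""


class TransientSourceError(SourceError):
    """A failure worth retrying (lost connection, server busy)."""


class PermanentSourceError(SourceError):
    """A failure retrying cannot fix (no such subset, malformed archive)."""


class SubsetSource(Protocol):
    """Transport contract: fetch one band of one subset.

    ``fetch`` must be idempotent for identical arguments and raise
    :class:`TransientSourceError` for retryable conditions,
    :class:`PermanentSourceError` otherwise.
    """

    def fetch(
        self,
        site: SiteRequest,
        product: str,
        band: str,
        size: SizeKm,
        start: dt.date,
        end: dt.date,
    ) -> list[SubsetRecord]: ...


class FixtureSource:
    """Serve subset records from a local archive directory.

    The archive holds one ``<site_id>__<product>.asc`` file per site (as
    written by the synthetic-scene generator); ``fetch`` filters it to the
    requested band and window and extracts a centred sub-tile when a smaller
    size than the archived tile is requested.
    """

    def __init__(self, archive_dir: str | Path):
        self.archive_dir = Path(archive_dir)

    def fetch(
        self,
        site: SiteRequest,
        product: str,
        band: str,
        size: SizeKm,
        start: dt.date,
        end: dt.date,
    ) -> list[SubsetRecord]:
        path = self.archive_dir / subset_io.subset_filename(site.site_id, product)
        if not path.exists():
            raise PermanentSourceError(f"no archived subset for {site.site_id!r}")
        try:
            records = subset_io.parse_subset_file(path)
        except subset_io.SubsetFormatError as exc:
            raise PermanentSourceError(f"corrupt archive {path.name}: {exc}")
        spec = catalog.get_band(product, band)
        want_rows, want_cols = geometry.tile_dims(size, spec.nominal_resolution_m)
        out = []
        for rec in records:
            if rec.band != band:
                continue
            date = rec.composite_date.calendar_date
            if not start <= date <= end:
                continue
            if (want_rows, want_cols) != (rec.nrows, rec.ncols):
                if want_rows > rec.nrows or want_cols > rec.ncols:
                    raise PermanentSourceError(
                        f"archived tile {rec.nrows}x{rec.ncols} smaller than "
                        f"requested {want_rows}x{want_cols}"
                    )
                inner = geometry.extract_tile(
                    list(rec.values),
                    (rec.nrows, rec.ncols),
                    size,
                    spec.nominal_resolution_m,
                )
                dr = (rec.nrows - want_rows) // 2
                dc = (rec.ncols - want_cols) // 2
                rec = SubsetRecord(
                    nrows=want_rows,
                    ncols=want_cols,
                    xll_m=rec.xll_m + dc * rec.cell_size_m,
                    yll_m=rec.yll_m + dr * rec.cell_size_m,
                    cell_size_m=rec.cell_size_m,
                    unique_id=rec.unique_id,
                    product=rec.product,
                    date_code=rec.date_code,
                    lat=rec.lat,
                    lon=rec.lon,
                    processed_stamp=rec.processed_stamp,
                    values=tuple(inner),
                )
            out.append(rec)
        if not out:
            raise PermanentSourceError(
                f"archive for {site.site_id!r} has no {band!r} records in "
                f"{start}..{end}"
            )
        return out


class HttpSource:
    """Skeletal adapter for a live subset web service (unwired).

    Kept as the extension point for adapter authors; the historical SOAP
    transport is not revived here.
    """

    def __init__(self, endpoint: str):
        self.endpoint = endpoint

    def fetch(self, site, product, band, size, start, end):  # pragma: no cover
        raise PermanentSourceError(
            "no live transport is wired; use FixtureSource or supply an adapter"
        )


class Clock(Protocol):
    def now(self) -> float: ...
    def sleep(self, seconds: float) -> None: ...


class SystemClock:
    def now(self) -> float:
        return time.monotonic()

    def sleep(self, seconds: float) -> None:  # pragma: no cover - wall clock
        time.sleep(seconds)


class FakeClock:
    """Deterministic clock for tests: sleep() advances simulated time."""

    def __init__(self, start: float = 0.0):
        self._t = start

    def now(self) -> float:
        return self._t

    def sleep(self, seconds: float) -> None:
        self._t += seconds


@dataclass(frozen=True)
class RetryPolicy:
    """Retry budget per subset: total window and pause between attempts."""

    per_subset_window_s: float = 15 * 60.0
    backoff_s: float = 30.0

    def __post_init__(self) -> None:
        if self.per_subset_window_s < 0 or self.backoff_s <= 0:
            raise ValueError("retry window must be >= 0 and backoff > 0")


@dataclass
class DownloadLogEntry:
    site_id: str
    product: str
    bands: tuple[str, ...]
    size: SizeKm
    start_date: dt.date
    end_date: dt.date
    status: str  # Success | Retried-Success | Failed | Cached
    attempts: int
    message: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.status == "Failed" and not self.message:
            raise ValueError("Failed entries must carry an error message")
        if self.status != "Cached" and self.attempts < 1:
            raise ValueError("fetched entries must record at least one attempt")


@dataclass
class DownloadLog:
    entries: list[DownloadLogEntry] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        lines = ["\t".join(_LOG_COLUMNS)]
        for e in self.entries:
            lines.append(
                "\t".join(
                    [
                        e.site_id,
                        e.product,
                        ";".join(e.bands),
                        str(e.size.km_ns),
                        str(e.size.km_ew),
                        e.start_date.isoformat(),
                        e.end_date.isoformat(),
                        e.status,
                        str(e.attempts),
                        e.message.replace("\t", " ").replace("\n", " "),
                        e.timestamp,
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @property
    def n_failed(self) -> int:
        return sum(1 for e in self.entries if e.status == "Failed")


def _fetch_subset(
    site: SiteRequest,
    product: str,
    bands: Sequence[str],
    size: SizeKm,
    source: SubsetSource,
) -> list[SubsetRecord]:
    records: list[SubsetRecord] = []
    for band in bands:
        records.extend(
            source.fetch(site, product, band, size, site.start_date, site.end_date)
        )
    return records


def _attempt_with_retry(
    site: SiteRequest,
    product: str,
    bands: Sequence[str],
    size: SizeKm,
    source: SubsetSource,
    out_dir: Path,
    policy: RetryPolicy,
    clock: Clock,
) -> tuple[bool, int, str]:
    """One retry pass for one subset: (succeeded, attempts, last message)."""
    started = clock.now()
    attempts = 0
    message = ""
    while True:
        attempts += 1
        try:
            records = _fetch_subset(site, product, bands, size, source)
            subset_io.write_subset_file(
                records, out_dir / subset_io.subset_filename(site.site_id, product)
            )
            return True, attempts, message
        except TransientSourceError as exc:
            message = str(exc)
            logger.warning(
                "transient failure for %s (%s): %s", site.site_id, product, exc
            )
        except (PermanentSourceError, subset_io.SubsetFormatError) as exc:
            return False, attempts, str(exc)
        if clock.now() - started + policy.backoff_s >= policy.per_subset_window_s:
            return False, attempts, message
        clock.sleep(policy.backoff_s)


def download_subsets(
    sites: Sequence[SiteRequest],
    product: str,
    bands: Sequence[str],
    size: SizeKm,
    source: SubsetSource,
    out_dir: str | Path,
    policy: RetryPolicy | None = None,
    clock: Clock | None = None,
    skip_existing: bool = True,
) -> DownloadLog:
    """Fetch one subset file per site and write the download log.

    Unknown bands and an unwritable directory are configuration errors
    raised before any transfer.  Duplicate (site, product, bands, size,
    window) requests are collapsed with a log notice.  Subsets whose files
    already exist and cover the window are logged ``Cached`` and not
    fetched, so re-running over a completed directory performs no fetches
    and leaves files byte-identical.
    """
    policy = policy or RetryPolicy()
    clock = clock or SystemClock()
    out_dir = Path(out_dir)
    size = size if isinstance(size, SizeKm) else SizeKm(*size)
    for band in bands:
        catalog.get_band(product, band)  # raises before any transfer
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}")
    logger.info("writing subsets to %s", out_dir.resolve())

    unique: list[SiteRequest] = []
    seen: set[tuple] = set()
    n_dupes = 0
    for site in sites:
        key = (
            site.site_id,
            product,
            tuple(sorted(bands)),
            (size.km_ns, size.km_ew),
            site.start_date,
            site.end_date,
        )
        if key in seen:
            n_dupes += 1
            continue
        seen.add(key)
        unique.append(site)
    if n_dupes:
        logger.info("collapsed %d duplicate subset request(s)", n_dupes)

    needed = (
        update_subsets(unique, product, bands, size, out_dir)
        if skip_existing
        else list(unique)
    )
    needed_ids = {s.site_id for s in needed}

    log = DownloadLog()
    results: dict[str, DownloadLogEntry] = {}
    failed: list[SiteRequest] = []
    for site in unique:
        stamp = dt.datetime.now().isoformat(timespec="seconds")
        if site.site_id not in needed_ids:
            results[site.site_id] = DownloadLogEntry(
                site.site_id, product, tuple(bands), size,
                site.start_date, site.end_date,
                status="Cached", attempts=0,
                message="complete subset file already present",
                timestamp=stamp,
            )
            continue
        ok, attempts, message = _attempt_with_retry(
            site, product, bands, size, source, out_dir, policy, clock
        )
        status = "Success" if ok and attempts == 1 else (
            "Retried-Success" if ok else "Failed"
        )
        results[site.site_id] = DownloadLogEntry(
            site.site_id, product, tuple(bands), size,
            site.start_date, site.end_date,
            status=status, attempts=attempts,
            message=message if not ok else ("" if attempts == 1 else message),
            timestamp=stamp,
        )
        if not ok:
            failed.append(site)

    # Second pass over anything the first pass could not fetch.
    for site in failed:
        ok, attempts, message = _attempt_with_retry(
            site, product, bands, size, source, out_dir, policy, clock
        )
        entry = results[site.site_id]
        entry.attempts += attempts
        if ok:
            entry.status = "Retried-Success"
            entry.message = ""
        else:
            entry.status = "Failed"
            entry.message = message or entry.message or "second pass failed"

    log.entries = [results[s.site_id] for s in unique]
    log.write(out_dir / LOG_FILENAME)
    return log


def update_subsets(
    sites: Sequence[SiteRequest],
    product: str,
    bands: Sequence[str],
    size: SizeKm,
    out_dir: str | Path,
) -> list[SiteRequest]:
    """Sites whose subsets are still needed (missing, corrupt or incomplete).

    A site is satisfied when its subset file exists, parses, holds all
    requested bands at the requested tile dimensions, and its composite
    dates cover the requested window to within one composite interval.
    Corrupt files are treated as missing, with a warning.
    """
    out_dir = Path(out_dir)
    size = size if isinstance(size, SizeKm) else SizeKm(*size)
    interval = catalog.composite_interval_days(product)
    want_dims = {
        band: geometry.tile_dims(
            size, catalog.get_band(product, band).nominal_resolution_m
        )
        for band in bands
    }
    needed = []
    for site in sites:
        path = out_dir / subset_io.subset_filename(site.site_id, product)
        if not path.exists():
            needed.append(site)
            continue
        try:
            records = subset_io.parse_subset_file(path)
        except subset_io.SubsetFormatError as exc:
            logger.warning("treating corrupt subset file %s as missing: %s",
                           path.name, exc)
            needed.append(site)
            continue
        ok = True
        for band in bands:
            dates = [
                r.composite_date.calendar_date
                for r in records
                if r.band == band and (r.nrows, r.ncols) == want_dims[band]
            ]
            if not dates:
                ok = False
                break
            margin = dt.timedelta(days=interval)
            if min(dates) > site.start_date + margin or (
                max(dates) < site.end_date - margin
            ):
                ok = False
                break
        if not ok:
            needed.append(site)
    return needed
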