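"""Per-pixel time-series summaries and the site-table merge.

After screening, each pixel carries a dated physical-unit series with gaps.
Gaps are filled by piecewise-linear interpolation in calendar days (leading
and trailing gaps take the nearest valid value, so interpolants never leave
the observed range); summaries are then:

* ``max``/``min`` — extremes over the valid observations;
* ``mean`` — temporal mean of the interpolated (smoothed) series, i.e. the
  trapezoid-weighted time average over the spanned interval;
* ``variability`` — the time-averaged area between the interpolated series
  and its minimum,  V = [AUC(v) - min(v) * (t_n - t_1)] / (t_n - t_1),
  with AUC by the trapezoidal rule on the actual date spacing.  For a pure
  sinusoid sampled over whole periods V equals the amplitude; it measures
  seasonality (or offtake) in band units.

Per-site values aggregate the per-pixel statistics across the tile (by
default an unweighted mean of per-pixel statistics) and are merged back onto
the user's table as new ``<band>__<stat>`` columns, ready for modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import catalog, screening, subset_io
from .screening import PixelSeries

__all__ = [
    "InsufficientObservationsError",
    "SummaryStats",
    "interpolate_series",
    "temporal_variability",
    "summarize_pixel",
    "summarize_table",
    "aggregate_sites",
    "merge_summaries",
    "diagnostic_table",
    "STAT_NAMES",
]

STAT_NAMES = ("max_value", "min_value", "mean_value", "variability", "n_valid")


class InsufficientObservationsError(ValueError):
    """Fewer than two valid observations: nothing to interpolate."""


@dataclass(frozen=True)
class SummaryStats:
    """Per-pixel summary statistics in band physical units."""

    max_value: float
    min_value: float
    mean_value: float
    variability: float
    n_valid: int
    interpolated: bool

    def __post_init__(self) -> None:
        if self.n_valid >= 2:
            lo, mid, hi = self.min_value, self.mean_value, self.max_value
            if math.isfinite(mid) and math.isfinite(lo) and math.isfinite(hi):
                if not lo - 1e-12 <= mid <= hi + 1e-12:
                    raise ValueError("summary ordering min <= mean <= max violated")
            if math.isfinite(self.variability) and math.isfinite(hi - lo):
                if not -1e-12 <= self.variability <= hi - lo + 1e-12:
                    raise ValueError("variability outside [0, max - min]")


def interpolate_series(s: PixelSeries) -> PixelSeries:
    """Fill masked dates by linear interpolation in calendar days.

    Interior gaps are interpolated between the nearest valid neighbours;
    leading/trailing gaps take the nearest valid value (constant extension).
    Valid observations are returned unchanged.
    """
    if s.n_valid < 2:
        raise InsufficientObservationsError(
            f"site {s.site_id!r} pixel {s.pixel_index}: {s.n_valid} valid "
            "observations, need at least 2"
        )
    t = s.day_offsets
    valid = np.asarray(s.valid, dtype=bool)
    filled = np.interp(t, t[valid], np.asarray(s.values)[valid])
    return replace(
        s, values=filled, valid=np.ones_like(valid, dtype=bool)
    )


def temporal_variability(s: PixelSeries) -> float:
    """Time-averaged area between a fully-valid series and its minimum.

    Equivalently the trapezoid-weighted temporal mean of (value - min);
    zero for a constant series, shift-invariant, and scales linearly with
    the series amplitude.
    """
    if not np.all(s.valid):
        raise ValueError("temporal_variability requires a fully valid series")
    if len(s.dates) < 2:
        raise InsufficientObservationsError("need at least 2 dates")
    t = s.day_offsets
    v = np.asarray(s.values, dtype=float)
    span = t[-1] - t[0]
    auc = np.trapezoid(v, t)
    return float((auc - v.min() * span) / span)


def summarize_pixel(
    s: PixelSeries,
    *,
    want_max: bool = True,
    want_mean: bool = True,
    want_yield: bool = True,
    do_interpolate: bool = True,
) -> SummaryStats:
    """Summary statistics for one screened pixel series.

    Degenerate series never raise: with no valid observations every field is
    NaN; with a single one only max/min are defined (mean and variability
    need an interpolable series).
    """
    n_valid = s.n_valid
    nan = float("nan")
    vmax = vmin = mean = var = nan
    interpolated = False
    if n_valid >= 1:
        observed = np.asarray(s.values)[np.asarray(s.valid, dtype=bool)]
        if want_max:
            vmax = float(observed.max())
        vmin = float(observed.min())
    if n_valid >= 2:
        smooth = interpolate_series(s) if do_interpolate else None
        interpolated = do_interpolate
        if want_mean:
            if smooth is not None:
                # Temporal (trapezoid-weighted) mean, consistent with the
                # variability definition: variability = mean - min exactly.
                t = smooth.day_offsets
                mean = float(
                    np.trapezoid(np.asarray(smooth.values), t) / (t[-1] - t[0])
                )
            else:
                observed = np.asarray(s.values)[np.asarray(s.valid, dtype=bool)]
                mean = float(observed.mean())
        if want_yield:
            var = temporal_variability(
                smooth
                if smooth is not None
                else interpolate_series(s)
            )
    return SummaryStats(
        max_value=vmax if want_max else nan,
        min_value=vmin,
        mean_value=mean if want_mean else nan,
        variability=var if want_yield else nan,
        n_valid=n_valid,
        interpolated=interpolated,
    )


def summarize_table(
    series: list[PixelSeries],
    **flags,
) -> pd.DataFrame:
    """Summarize many pixel series into a (site_id, pixel)-indexed frame."""
    rows = {}
    for s in series:
        stats = summarize_pixel(s, **flags)
        rows[(s.site_id, s.pixel_index)] = {
            "max_value": stats.max_value,
            "min_value": stats.min_value,
            "mean_value": stats.mean_value,
            "variability": stats.variability,
            "n_valid": stats.n_valid,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["site_id", "pixel"])
    return frame.sort_index()


def aggregate_sites(
    pixel_stats: pd.DataFrame, how: str = "pixel_stat_mean"
) -> pd.DataFrame:
    """Aggregate per-pixel statistics to one row per site.

    ``pixel_stat_mean`` (default) averages each per-pixel statistic over the
    site's pixels, NaN-aware.
    """
    if how != "pixel_stat_mean":
        raise ValueError(f"unknown aggregation {how!r}")
    return pixel_stats.groupby(level="site_id").mean()


def merge_summaries(
    user_table: pd.DataFrame,
    site_stats: dict[str, pd.DataFrame],
    site_ids: list[str],
) -> pd.DataFrame:
    """Append ``<band>__<stat>`` columns to the user's table.

    ``site_stats`` maps band name to a site-indexed statistics frame;
    ``site_ids`` gives the site ID of each user-table row in order.  Row
    count and order are preserved; sites without data get NaN.  Statistics
    for a site absent from ``site_ids`` are a consistency error.
    """
    if len(site_ids) != len(user_table):
        raise ValueError("site_ids must parallel the user table rows")
    known = set(site_ids)
    out = user_table.copy()
    for band, stats in site_stats.items():
        unknown = set(stats.index) - known
        if unknown:
            raise ValueError(
                f"statistics for site IDs absent from the user table: "
                f"{sorted(unknown)}"
            )
        for stat in ("max_value", "min_value", "mean_value", "variability"):
            col = f"{band}__{stat.replace('_value', '')}"
            if stat in stats.columns:
                lookup = stats[stat]
                out[col] = [
                    float(lookup.get(sid, math.nan)) for sid in site_ids
                ]
            else:
                out[col] = math.nan
    return out


def screen_collated(
    data: pd.DataFrame,
    quality: pd.DataFrame | None,
    band: catalog.BandSpec,
    *,
    threshold: int = 0,
    screen_on: bool = True,
) -> list[PixelSeries]:
    """Screen a collated (site, pixel) x date frame into pixel series.

    ``data`` and ``quality`` are frames as returned by
    :func:`modisbatch.subset_io.collate_time_series`; quality rows are
    aligned to data rows by (site, pixel) and dates by column.
    """
    series = []
    for (site, pixel), row in data.iterrows():
        dates = [
            d.date() if hasattr(d, "date") else d for d in row.index
        ]
        qrow = None
        if quality is not None:
            if (site, pixel) in quality.index:
                qrow = quality.loc[(site, pixel)].reindex(row.index).to_numpy()
            else:
                qrow = np.full(len(row), np.nan)
        series.append(
            screening.apply_screen(
                dates,
                row.to_numpy(),
                qrow,
                band,
                threshold=threshold,
                screen_on=screen_on,
                site_id=site,
                pixel_index=pixel,
            )
        )
    return series


def summarize_subset_files(
    paths,
    product: str,
    bands,
    quality_band: str | None = None,
    *,
    threshold: int = 0,
    screen_on: bool = True,
    aggregation: str = "pixel_stat_mean",
    **flags,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Collate, screen and summarize an archive of subset files.

    Returns ``(site_stats, pixel_stats)``: for each data band, a site-level
    and a (site, pixel)-level statistics frame.
    """
    paths = list(paths)
    quality = (
        subset_io.collate_time_series(paths, quality_band)
        if quality_band is not None
        else None
    )
    site_stats: dict[str, pd.DataFrame] = {}
    pixel_stats: dict[str, pd.DataFrame] = {}
    for band_name in bands:
        spec = catalog.get_band(product, band_name)
        if spec.is_quality_band:
            continue
        data = subset_io.collate_time_series(paths, band_name)
        series = screen_collated(
            data, quality, spec, threshold=threshold, screen_on=screen_on
        )
        stats = summarize_table(series, **flags)
        pixel_stats[band_name] = stats
        site_stats[band_name] = aggregate_sites(stats, how=aggregation)
    return site_stats, pixel_stats


def diagnostic_table(s: PixelSeries) -> pd.DataFrame:
    """Per-date diagnostics for one pixel: observed, interpolant, reference lines.

    The frame backs a diagnostic plot of the screened series with its
    interpolant and the max/min/mean reference levels.
    """
    interp = interpolate_series(s)
    stats = summarize_pixel(s)
    return pd.DataFrame(
        {
            "date": list(s.dates),
            "observed": np.asarray(s.values),
            "interpolated": np.asarray(interp.values),
            "max_line": stats.max_value,
            "min_line": stats.min_value,
            "mean_line": stats.mean_value,
        }
    )
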