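"""Synthetic subset-archive generator with known ground truth.

Emulates per-pixel 16-day composite vegetation-index series so the
acquisition, screening and summary stages can be exercised end to end with
no remote service: each pixel follows a seasonal sinusoid in physical units,

    v(t) = offset - amplitude * cos(2*pi*(t - phase_days)/period_days),

(minimum at t = phase_days, so a composite grid aligned with the phase
samples the true minimum exactly), plus optional Gaussian noise.  Physical
values are divided by the band scale factor and rounded to stored integers,
as MODIS products store them; a fraction of observations is replaced by the
band's no-data fill and another fraction is marked unreliable in the
parallel pixel-reliability band.  A truth table of per-pixel noise-free
summary statistics accompanies the archive.

The generated files are the same ASCII subset dialect the parser reads, so
archives double as fixtures for the acquisition layer's FixtureSource.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog, geometry, subset_io
from .screening import PixelSeries
from .subset_io import SiteRequest, SubsetRecord

__all__ = ["SceneSpec", "generate_archive", "TRUTH_FILENAME", "SITES_FILENAME"]

TRUTH_FILENAME = "truth.csv"
SITES_FILENAME = "sites.csv"

#: Reliability rank written for deliberately unreliable composites
#: (3 = cloudy in the MOD13 convention).
BAD_RELIABILITY_RANK = 3


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic archive.

    Defaults emulate the conditions of a multi-site temperate-forest
    vegetation-index study: MOD13Q1 NDVI/EVI plus pixel reliability on a
    16-day composite grid spanning three years (69 composites), a seasonal
    cycle of 23 composites (368 days) with NDVI-scale offset 0.55 and
    amplitude 0.25, observation noise 0.015, and roughly one fifth of
    composites lost to fill values or poor reliability.
    """

    n_sites: int = 4
    size: geometry.SizeKm = field(default_factory=lambda: geometry.SizeKm(1, 1))
    product: str = "MOD13Q1"
    bands: tuple[str, ...] = ("250m_16_days_NDVI", "250m_16_days_EVI")
    quality_band: str = "250m_16_days_pixel_reliability"
    start_year: int = 2006
    n_composites: int = 69
    interval_days: int = 16
    signal_offset: float = 0.55
    signal_amplitude: float = 0.25
    period_days: float = 368.0
    phase_days: float = 0.0
    noise_sd: float = 0.015
    fraction_fill: float = 0.05
    fraction_bad_quality: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_fill", "fraction_bad_quality"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {f}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_composites < 1 or self.n_sites < 1:
            raise ValueError("need at least one composite and one site")

    @property
    def dates(self) -> list[dt.date]:
        t0 = dt.date(self.start_year, 1, 1)
        return [
            t0 + dt.timedelta(days=i * self.interval_days)
            for i in range(self.n_composites)
        ]

    def clean_signal(self, day_offsets: np.ndarray) -> np.ndarray:
        """Noise-free physical-unit signal at the given day offsets."""
        return self.signal_offset - self.signal_amplitude * np.cos(
            2.0 * np.pi * (day_offsets - self.phase_days) / self.period_days
        )


def _site_requests(spec: SceneSpec) -> list[SiteRequest]:
    dates = spec.dates
    sites = []
    for k in range(spec.n_sites):
        # Deterministic spread across the temperate band; no two sites share
        # a focal pixel.
        lat = 40.0 + 0.37 * k
        lon = -75.0 - 0.53 * k
        sites.append(
            SiteRequest(
                site_id=f"FixtureSite{k + 1}",
                lat=lat,
                lon=lon,
                start_date=dates[0],
                end_date=dates[-1],
            )
        )
    return sites


def _truth_stats(spec: SceneSpec) -> tuple[float, float, float]:
    """Noise-free max/mean/variability of the sampled signal (trapezoid mean)."""
    t = np.array(
        [i * spec.interval_days for i in range(spec.n_composites)], dtype=float
    )
    v = spec.clean_signal(t)
    if len(t) < 2:
        return float(v.max()), float(v[0]), float("nan")
    span = t[-1] - t[0]
    mean = float(np.trapezoid(v, t) / span)
    variability = float((np.trapezoid(v, t) - v.min() * span) / span)
    return float(v.max()), mean, variability


def generate_archive(
    spec: SceneSpec, out_dir: str | Path
) -> tuple[list[SiteRequest], pd.DataFrame]:
    """Write a synthetic subset archive plus ground truth to *out_dir*.

    Produces one subset file per site (all data bands plus the reliability
    band), a ``sites.csv`` site table, and a ``truth.csv`` table of
    per-pixel noise-free max/mean/variability.  Byte-identical across runs
    for the same spec (including seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    band_specs = {b: catalog.get_band(spec.product, b) for b in spec.bands}
    qspec = catalog.get_band(spec.product, spec.quality_band)
    nominal = qspec.nominal_resolution_m
    cell = round(qspec.actual_cell_size_m, 4)
    dates = spec.dates
    day_offsets = np.array(
        [(d - dates[0]).days for d in dates], dtype=float
    )
    clean = spec.clean_signal(day_offsets)
    stamp = f"{spec.start_year:04d}020003129"

    sites = _site_requests(spec)
    truth_rows = []
    true_max, true_mean, true_var = _truth_stats(spec)

    for site in sites:
        geom = geometry.tile_geometry_for(
            site.lat, site.lon, spec.size, nominal, qspec.actual_cell_size_m
        )
        h, v = geometry.modis_tile_hv(site.lat, site.lon)
        n_px = geom.n_pixels
        xll = round(geom.xll_m)
        yll = round(geom.yll_m)

        # Fault masks are drawn once per data band so NDVI and EVI carry the
        # same reliability series, as in the real product.
        fill_mask = rng.random((len(dates), n_px)) < spec.fraction_fill
        bad_mask = (~fill_mask) & (
            rng.random((len(dates), n_px)) < spec.fraction_bad_quality
        )
        reliability = np.zeros((len(dates), n_px), dtype=int)
        reliability[bad_mask] = BAD_RELIABILITY_RANK

        records: list[SubsetRecord] = []
        for band_name, bspec in band_specs.items():
            noise = (
                rng.normal(0.0, spec.noise_sd, size=(len(dates), n_px))
                if spec.noise_sd > 0
                else np.zeros((len(dates), n_px))
            )
            stored = np.rint(
                (clean[:, None] + noise) / bspec.scale_factor
            ).astype(int)
            stored[fill_mask] = bspec.no_data_fill
            for i, date in enumerate(dates):
                code = subset_io.format_date_code(date)
                records.append(
                    SubsetRecord(
                        nrows=geom.nrows,
                        ncols=geom.ncols,
                        xll_m=float(xll),
                        yll_m=float(yll),
                        cell_size_m=cell,
                        unique_id=(
                            f"{spec.product}.{code}.h{h:02d}v{v:02d}.005."
                            f"{stamp}.{band_name}"
                        ),
                        product=spec.product,
                        date_code=code,
                        lat=site.lat,
                        lon=site.lon,
                        processed_stamp=stamp,
                        values=tuple(int(x) for x in stored[i]),
                    )
                )
            for px in range(n_px):
                truth_rows.append(
                    {
                        "site_id": site.site_id,
                        "band": band_name,
                        "pixel": px,
                        "true_max": true_max,
                        "true_mean": true_mean,
                        "true_variability": true_var,
                    }
                )
        for i, date in enumerate(dates):
            code = subset_io.format_date_code(date)
            records.append(
                SubsetRecord(
                    nrows=geom.nrows,
                    ncols=geom.ncols,
                    xll_m=float(xll),
                    yll_m=float(yll),
                    cell_size_m=cell,
                    unique_id=(
                        f"{spec.product}.{code}.h{h:02d}v{v:02d}.005."
                        f"{stamp}.{spec.quality_band}"
                    ),
                    product=spec.product,
                    date_code=code,
                    lat=site.lat,
                    lon=site.lon,
                    processed_stamp=stamp,
                    values=tuple(int(x) for x in reliability[i]),
                )
            )
        subset_io.write_subset_file(
            records,
            out_dir / subset_io.subset_filename(site.site_id, spec.product),
        )

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / TRUTH_FILENAME, index=False)
    site_table = pd.DataFrame(
        {
            "ID": [s.site_id for s in sites],
            "lat": [s.lat for s in sites],
            "long": [s.lon for s in sites],
            "start.date": [s.start_date.isoformat() for s in sites],
            "end.date": [s.end_date.isoformat() for s in sites],
        }
    )
    site_table.to_csv(out_dir / SITES_FILENAME, index=False)
    return sites, truth


def clean_pixel_series(spec: SceneSpec, site_id: str = "truth") -> PixelSeries:
    """The noise-free physical-unit series as a fully valid PixelSeries."""
    dates = spec.dates
    t = np.array([(d - dates[0]).days for d in dates], dtype=float)
    v = spec.clean_signal(t)
    return PixelSeries(
        site_id=site_id,
        pixel_index=0,
        dates=tuple(dates),
        values=v,
        valid=np.ones(len(dates), dtype=bool),
    )
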