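"""Quality screening: mask unreliable, fill and out-of-range values, then scale.

MOD13-class products ship a per-pixel integer reliability rank alongside the
vegetation-index bands (0 = good, larger = worse).  Screening keeps a stored
value only if it is not the band's no-data fill, lies inside the band's valid
range (checked in stored units), and — when the reliability screen is on —
has a reliability record at that date with rank <= the threshold.  Surviving
values are multiplied by the band scale factor; masked entries are NaN and
never carry a number.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import BandSpec

__all__ = ["ScreeningConfigError", "PixelSeries", "apply_screen"]


class ScreeningConfigError(ValueError):
    """The screen is on but no reliability series was supplied."""


@dataclass(frozen=True)
class PixelSeries:
    """Dated physical-unit series for one pixel, with a validity mask."""

    site_id: str
    pixel_index: int
    dates: tuple[dt.date, ...]
    values: np.ndarray  # float, NaN at masked positions
    valid: np.ndarray  # bool, parallel to values

    def __post_init__(self) -> None:
        if not (len(self.dates) == len(self.values) == len(self.valid)):
            raise ValueError("dates, values and valid must be parallel")
        if any(b >= a for a, b in zip(self.dates[1:], self.dates)):
            raise ValueError("dates must be strictly ascending")
        if np.any(np.isnan(np.asarray(self.values)[np.asarray(self.valid)])):
            raise ValueError("valid positions must carry numbers")
        if not np.all(np.isnan(np.asarray(self.values)[~np.asarray(self.valid)])):
            raise ValueError("masked positions must be NaN")

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    @property
    def day_offsets(self) -> np.ndarray:
        """Days since the first date, as floats (the interpolation axis)."""
        t0 = self.dates[0]
        return np.array([(d - t0).days for d in self.dates], dtype=float)


def apply_screen(
    dates: Sequence[dt.date],
    stored: Sequence[float],
    quality: Sequence[float] | None,
    band: BandSpec,
    *,
    threshold: int = 0,
    screen_on: bool = True,
    site_id: str = "",
    pixel_index: int = 0,
) -> PixelSeries:
    """Screen one stored-unit series and scale survivors to physical units.

    ``quality`` is the parallel reliability series (NaN where the quality
    band has no record for a date).  A value is valid iff it is not the fill,
    is inside the band's valid range, and — with ``screen_on`` — has a
    reliability rank present and <= ``threshold`` (ranks strictly above the
    threshold are omitted).  A missing reliability record while the screen is
    on masks that date.
    """
    stored_arr = np.asarray(stored, dtype=float)
    lo, hi = band.valid_range
    valid = (
        ~np.isnan(stored_arr)
        & (stored_arr != band.no_data_fill)
        & (stored_arr >= lo)
        & (stored_arr <= hi)
    )
    if screen_on:
        if quality is None:
            raise ScreeningConfigError(
                f"reliability screening requested for band {band.band_name!r} "
                "but no quality series was supplied"
            )
        q = np.asarray(quality, dtype=float)
        if q.shape != stored_arr.shape:
            raise ValueError("quality series not aligned with data series")
        valid &= ~np.isnan(q) & (q <= threshold)
    values = np.where(valid, stored_arr * band.scale_factor, np.nan)
    return PixelSeries(
        site_id=site_id,
        pixel_index=pixel_index,
        dates=tuple(dates),
        values=values,
        valid=valid,
    )
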