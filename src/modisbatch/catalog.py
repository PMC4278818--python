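"""Static product/band metadata for supported MODIS land products.

The catalogue is the local stand-in for the remote product/band listing
services: every numeric constant other modules need (valid ranges, fill
sentinels, scale factors, sinusoidal cell sizes, composite intervals) lives
here, loaded once from a YAML data file shipped with the package so new
products can be added without code changes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import yaml

__all__ = [
    "BandSpec",
    "UnknownProductError",
    "UnknownBandError",
    "list_products",
    "list_bands",
    "get_band",
    "composite_interval_days",
]


class UnknownProductError(KeyError):
    """Raised for a product code absent from the catalogue."""


class UnknownBandError(KeyError):
    """Raised for a band name absent from a product's band list."""


@dataclass(frozen=True)
class BandSpec:
    """Metadata for one Science Data Set (band) of a MODIS product.

    ``valid_range`` and ``no_data_fill`` are in stored integer units;
    ``scale_factor`` converts stored values to physical units.  Quality
    bands (pixel reliability ranks, QC words) carry ``scale_factor`` 1 and
    are never scaled.
    """

    product_code: str
    band_name: str
    valid_range: tuple[int, int]
    no_data_fill: int
    scale_factor: float
    nominal_resolution_m: int
    actual_cell_size_m: float
    composite_interval_days: int
    is_quality_band: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if lo > hi:
            raise ValueError(f"valid_range lower {lo} exceeds upper {hi}")
        if lo <= self.no_data_fill <= hi:
            raise ValueError(
                f"no_data_fill {self.no_data_fill} lies inside valid_range "
                f"[{lo}, {hi}] for band {self.band_name}"
            )
        if self.nominal_resolution_m not in (250, 500, 1000):
            raise ValueError(
                f"unsupported nominal resolution {self.nominal_resolution_m}"
            )
        if abs(self.actual_cell_size_m - self.nominal_resolution_m) > (
            0.1 * self.nominal_resolution_m
        ):
            raise ValueError(
                f"cell size {self.actual_cell_size_m} not within 10% of "
                f"nominal {self.nominal_resolution_m}"
            )
        if self.is_quality_band and self.scale_factor != 1.0:
            raise ValueError("quality bands must carry scale_factor 1")


@lru_cache(maxsize=1)
def _load_catalog() -> dict[str, dict[str, BandSpec]]:
    text = (
        importlib.resources.files("modisbatch") / "data" / "catalog.yaml"
    ).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    catalog: dict[str, dict[str, BandSpec]] = {}
    for product_code, entry in raw.items():
        interval = int(entry["composite_interval_days"])
        bands: dict[str, BandSpec] = {}
        for band in entry["bands"]:
            spec = BandSpec(
                product_code=product_code,
                band_name=band["band_name"],
                valid_range=tuple(band["valid_range"]),
                no_data_fill=int(band["no_data_fill"]),
                scale_factor=float(band["scale_factor"]),
                nominal_resolution_m=int(band["nominal_resolution_m"]),
                actual_cell_size_m=float(band["actual_cell_size_m"]),
                composite_interval_days=interval,
                is_quality_band=bool(band["is_quality_band"]),
            )
            bands[spec.band_name] = spec
        catalog[product_code] = bands
    return catalog


def list_products() -> list[str]:
    """Product codes known to the catalogue, sorted and deduplicated."""
    return sorted(_load_catalog())


def list_bands(product: str) -> list[BandSpec]:
    """All band specifications for *product*.

    Raises :class:`UnknownProductError` for a code not in the catalogue.
    """
    catalog = _load_catalog()
    if product not in catalog:
        raise UnknownProductError(f"unknown product: {product!r}")
    return list(catalog[product].values())


def get_band(product: str, band_name: str) -> BandSpec:
    """Look up a single band of a product."""
    catalog = _load_catalog()
    if product not in catalog:
        raise UnknownProductError(f"unknown product: {product!r}")
    bands = catalog[product]
    if band_name not in bands:
        raise UnknownBandError(
            f"unknown band {band_name!r} for product {product!r}"
        )
    return bands[band_name]


def composite_interval_days(product: str) -> int:
    """Nominal days between composites for *product* (16 for MOD13Q1)."""
    return list_bands(product)[0].composite_interval_days
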