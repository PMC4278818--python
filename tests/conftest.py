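import pytest

from modisbatch import catalog, fixtures, geometry, subset_io

# A worked-example subset row in the documented field order: 1x1 tile of the
# EVI band, one composite date, single stored value 1567.
EXAMPLE_ROW = (
    "1,1,13702705,-3709977,231.6564,"
    "MOD13Q1.A2009001.h30v12.005.2009020003129.250m_16_days_EVI,"
    "MOD13Q1,A2009001,Lat-33.3636449991Lon147.548402Samp1Line1,"
    "2009020003129,1567"
)
EXAMPLE_LAT = -33.3636449991
EXAMPLE_LON = 147.548402


@pytest.fixture
def example_record():
    return subset_io._parse_row(EXAMPLE_ROW, 1)


@pytest.fixture
def ndvi_band():
    return catalog.get_band("MOD13Q1", "250m_16_days_NDVI")


@pytest.fixture
def reliability_band():
    return catalog.get_band("MOD13Q1", "250m_16_days_pixel_reliability")


@pytest.fixture
def small_scene():
    """One focal-pixel site, 24 noise-free composites over one whole period."""
    return fixtures.SceneSpec(
        n_sites=1,
        size=geometry.SizeKm(0, 0),
        n_composites=24,
        noise_sd=0.0,
        fraction_fill=0.0,
        fraction_bad_quality=0.0,
        seed=7,
    )


@pytest.fixture
def noisy_scene():
    """Four sites, 9x9-pixel tiles, defaults for noise and data loss."""
    return fixtures.SceneSpec(
        n_sites=4,
        size=geometry.SizeKm(1, 1),
        n_composites=23,
        seed=11,
    )


@pytest.fixture
def archive(tmp_path, noisy_scene):
    out = tmp_path / "archive"
    sites, truth = fixtures.generate_archive(noisy_scene, out)
    return out, sites, truth
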