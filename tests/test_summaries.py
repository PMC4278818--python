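import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modisbatch import fixtures, geometry, summaries
from modisbatch.screening import PixelSeries
from modisbatch.summaries import (
    InsufficientObservationsError,
    interpolate_series,
    merge_summaries,
    summarize_pixel,
    temporal_variability,
)

T0 = dt.date(2009, 1, 1)


def series(values, days=None, site="s", pixel=0):
    """Build a PixelSeries from floats with None marking masked dates."""
    if days is None:
        days = [16 * i for i in range(len(values))]
    arr = np.array([math.nan if v is None else float(v) for v in values])
    valid = ~np.isnan(arr)
    return PixelSeries(
        site_id=site,
        pixel_index=pixel,
        dates=tuple(T0 + dt.timedelta(days=d) for d in days),
        values=arr,
        valid=valid,
    )


class TestInterpolation:
    def test_interior_gap_is_linear_midpoint(self):
        out = interpolate_series(series([0.2, None, 0.4]))
        np.testing.assert_allclose(out.values, [0.2, 0.3, 0.4])

    def test_boundary_gaps_take_nearest_valid_value(self):
        out = interpolate_series(series([None, 0.5, 0.7]))
        np.testing.assert_allclose(out.values, [0.5, 0.5, 0.7])
        out = interpolate_series(series([0.5, 0.7, None, None]))
        np.testing.assert_allclose(out.values, [0.5, 0.7, 0.7, 0.7])

    def test_fully_valid_series_unchanged(self):
        s = series([0.1, 0.9, 0.5])
        np.testing.assert_array_equal(interpolate_series(s).values, s.values)

    def test_interpolation_respects_actual_date_spacing(self):
        # gap at day 8 of an irregular 0/8/32 grid: 1/4 of the way along
        out = interpolate_series(series([0.0, None, 1.0], days=[0, 8, 32]))
        assert out.values[1] == pytest.approx(0.25)

    def test_fewer_than_two_valid_observations_signal(self):
        with pytest.raises(InsufficientObservationsError):
            interpolate_series(series([None, 0.5, None]))

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_interpolant_stays_within_observed_range(self, data):
        n = data.draw(st.integers(3, 20))
        vals = data.draw(
            st.lists(
                st.one_of(st.none(), st.floats(-0.2, 1.0)),
                min_size=n,
                max_size=n,
            ).filter(lambda v: sum(x is not None for x in v) >= 2)
        )
        s = series(vals)
        out = interpolate_series(s)
        observed = s.values[s.valid]
        assert out.values.min() >= observed.min() - 1e-12
        assert out.values.max() <= observed.max() + 1e-12
        np.testing.assert_array_equal(out.values[s.valid], observed)


class TestTemporalVariability:
    def test_constant_series_has_zero_variability(self):
        assert temporal_variability(series([0.4] * 5)) == 0.0

    def test_triangle_pulse_by_hand(self):
        # trapezoid AUC of (0,1,0) over days (0,16,32) is 16; V = 16/32
        assert temporal_variability(series([0.0, 1.0, 0.0])) == pytest.approx(0.5)

    def test_scaling_and_shift_invariance(self):
        base = series([0.1, 0.7, 0.3, 0.5])
        v = temporal_variability(base)
        scaled = series([3 * x for x in (0.1, 0.7, 0.3, 0.5)])
        shifted = series([x + 2.0 for x in (0.1, 0.7, 0.3, 0.5)])
        assert temporal_variability(scaled) == pytest.approx(3 * v)
        assert temporal_variability(shifted) == pytest.approx(v)

    def test_riemann_oracle_agreement(self):
        """Trapezoid variability matches brute-force integration at dt=0.01 day."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            # random subsets of a 16-day composite grid over ~3 years
            days = np.sort(rng.choice(np.arange(69) * 16, size=n, replace=False))
            vals = rng.uniform(0.0, 1.0, size=n)
            s = series(vals, days=days.tolist())
            # independent oracle: midpoint Riemann sum over the linear
            # interpolant on a 0.01-day grid
            grid = np.arange(days[0], days[-1], 0.01) + 0.005
            f = np.interp(grid, days, vals)
            span = days[-1] - days[0]
            oracle = (f.sum() * 0.01 - vals.min() * span) / span
            assert temporal_variability(s) == pytest.approx(oracle, abs=1e-6)

    def test_single_date_is_undefined(self):
        with pytest.raises(InsufficientObservationsError):
            temporal_variability(series([0.4]))


class TestSummarizePixel:
    def test_noise_free_sinusoid_recovers_offset_and_amplitude(self, small_scene):
        s = fixtures.clean_pixel_series(small_scene)
        stats = summarize_pixel(s)
        m, a = small_scene.signal_offset, small_scene.signal_amplitude
        # sampling can miss the crest by up to half a composite interval
        max_slack = a * (
            1
            - math.cos(
                math.pi * small_scene.interval_days / small_scene.period_days
            )
        )
        assert stats.max_value == pytest.approx(m + a, abs=max_slack + 1e-9)
        assert stats.min_value == pytest.approx(m - a, abs=1e-9)
        assert stats.mean_value == pytest.approx(m, abs=1e-9)
        assert stats.variability == pytest.approx(a, abs=1e-9)

    def test_all_masked_series_yields_all_missing(self):
        stats = summarize_pixel(series([None, None]))
        assert stats.n_valid == 0
        assert all(
            math.isnan(x)
            for x in (
                stats.max_value,
                stats.min_value,
                stats.mean_value,
                stats.variability,
            )
        )

    def test_single_valid_value_keeps_extremes_only(self):
        stats = summarize_pixel(series([None, 0.42, None]))
        assert stats.max_value == stats.min_value == pytest.approx(0.42)
        assert math.isnan(stats.mean_value) and math.isnan(stats.variability)
        assert stats.n_valid == 1

    def test_flags_switch_outputs_off(self):
        s = series([0.2, 0.4, 0.3])
        stats = summarize_pixel(s, want_max=False, want_yield=False)
        assert math.isnan(stats.max_value) and math.isnan(stats.variability)
        assert not math.isnan(stats.mean_value)

    def test_mean_without_interpolation_averages_observations(self):
        s = series([0.2, None, 0.6])
        stats = summarize_pixel(s, do_interpolate=False)
        assert stats.mean_value == pytest.approx(0.4)
        assert not stats.interpolated

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_summary_invariants(self, data):
        n = data.draw(st.integers(2, 25))
        vals = data.draw(
            st.lists(
                st.one_of(st.none(), st.floats(-0.2, 1.0)),
                min_size=n,
                max_size=n,
            ).filter(lambda v: sum(x is not None for x in v) >= 2)
        )
        stats = summarize_pixel(series(vals))
        assert stats.min_value - 1e-12 <= stats.mean_value <= stats.max_value + 1e-12
        assert -1e-12 <= stats.variability
        assert stats.variability <= stats.max_value - stats.min_value + 1e-12

    def test_interpolation_never_changes_observed_extremes(self):
        s = series([0.3, None, 0.9, None, 0.1])
        with_interp = summarize_pixel(s, do_interpolate=True)
        without = summarize_pixel(s, do_interpolate=False)
        assert with_interp.max_value == without.max_value
        assert with_interp.min_value == without.min_value


class TestMergeSummaries:
    def make_stats(self, ids, offset=0.0):
        return pd.DataFrame(
            {
                "max_value": [0.8 + offset] * len(ids),
                "min_value": [0.2 + offset] * len(ids),
                "mean_value": [0.5 + offset] * len(ids),
                "variability": [0.25 + offset] * len(ids),
                "n_valid": [20] * len(ids),
            },
            index=pd.Index(ids, name="site_id"),
        )

    def test_row_count_order_and_new_columns(self):
        user = pd.DataFrame({"richness": [5, 9, 2]}, index=[10, 11, 12])
        ids = ["a", "b", "c"]
        out = merge_summaries(
            user,
            {"NDVI": self.make_stats(ids), "EVI": self.make_stats(ids, 0.1)},
            ids,
        )
        assert len(out) == 3 and list(out.index) == [10, 11, 12]
        new_cols = set(out.columns) - {"richness"}
        assert new_cols == {
            f"{b}__{s}" for b in ("NDVI", "EVI")
            for s in ("max", "min", "mean", "variability")
        }

    def test_sites_without_stats_get_missing_markers(self):
        user = pd.DataFrame({"richness": [5, 9]})
        out = merge_summaries(user, {"NDVI": self.make_stats(["a"])}, ["a", "b"])
        assert out.loc[0, "NDVI__mean"] == pytest.approx(0.5)
        assert math.isnan(out.loc[1, "NDVI__mean"])

    def test_empty_stats_add_all_missing_columns(self):
        user = pd.DataFrame({"richness": [5, 9]})
        out = merge_summaries(user, {"NDVI": self.make_stats([])}, ["a", "b"])
        assert out["NDVI__variability"].isna().all()
        assert out["richness"].tolist() == [5, 9]

    def test_duplicate_site_rows_both_receive_stats(self):
        user = pd.DataFrame({"richness": [5, 9]})
        out = merge_summaries(user, {"NDVI": self.make_stats(["a"])}, ["a", "a"])
        assert out["NDVI__mean"].tolist() == pytest.approx([0.5, 0.5])

    def test_unknown_site_in_stats_is_a_consistency_error(self):
        user = pd.DataFrame({"richness": [5]})
        with pytest.raises(ValueError, match="absent"):
            merge_summaries(user, {"NDVI": self.make_stats(["ghost"])}, ["a"])


class TestPipeline:
    def test_screen_then_summarize_matches_direct_summaries(self, tmp_path):
        """On an all-reliable, in-range archive the pipeline equals plain stats."""
        spec = fixtures.SceneSpec(
            n_sites=2,
            size=geometry.SizeKm(0, 0),
            n_composites=24,
            noise_sd=0.01,
            fraction_fill=0.0,
            fraction_bad_quality=0.0,
            seed=5,
        )
        fixtures.generate_archive(spec, tmp_path)
        paths = sorted(tmp_path.glob("*__MOD13Q1.asc"))
        screened, _ = summaries.summarize_subset_files(
            paths, "MOD13Q1", ["250m_16_days_NDVI"],
            "250m_16_days_pixel_reliability",
        )
        unscreened, _ = summaries.summarize_subset_files(
            paths, "MOD13Q1", ["250m_16_days_NDVI"], None, screen_on=False
        )
        pd.testing.assert_frame_equal(
            screened["250m_16_days_NDVI"], unscreened["250m_16_days_NDVI"]
        )

    def test_site_aggregation_is_pixel_mean(self, archive):
        archive_dir, _, _ = archive
        paths = sorted(archive_dir.glob("*__MOD13Q1.asc"))
        site_stats, pixel_stats = summaries.summarize_subset_files(
            paths, "MOD13Q1", ["250m_16_days_NDVI"],
            "250m_16_days_pixel_reliability",
        )
        band = "250m_16_days_NDVI"
        manual = pixel_stats[band].groupby(level="site_id").mean()
        pd.testing.assert_frame_equal(site_stats[band], manual)

    def test_recovery_on_noisy_masked_fixture(self, archive):
        """Site-level recovered stats sit close to the generator's truth."""
        archive_dir, _, truth = archive
        paths = sorted(archive_dir.glob("*__MOD13Q1.asc"))
        site_stats, _ = summaries.summarize_subset_files(
            paths, "MOD13Q1", ["250m_16_days_NDVI"],
            "250m_16_days_pixel_reliability",
        )
        stats = site_stats["250m_16_days_NDVI"]
        t = truth[truth.band == "250m_16_days_NDVI"].iloc[0]
        # 81 pixels averaged: generous 3-sigma-scale bounds
        assert stats["mean_value"].mean() == pytest.approx(
            t.true_mean, abs=0.01
        )
        assert stats["variability"].mean() == pytest.approx(
            t.true_variability, rel=0.15
        )
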