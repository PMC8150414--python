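import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandecg.errors import (
    ConfigurationError,
    InsufficientDataError,
    UncorrectableSeriesError,
    ValidationError,
)
from bandecg.hr import (
    HRSeries,
    RRISeries,
    compute_rri,
    correct_rri,
    hr_from_rri,
    smooth_hr,
)
from bandecg.qrs import BeatAnnotations


def rri_from_intervals(intervals) -> RRISeries:
    intervals = np.asarray(intervals, dtype=float)
    return RRISeries(end_times=np.cumsum(intervals), intervals=intervals)


class TestComputeRri:
    def test_basic_differences(self):
        rri = compute_rri(BeatAnnotations(np.array([0.0, 1000.0, 2000.0])))
        np.testing.assert_array_equal(rri.intervals, [1000.0, 1000.0])
        np.testing.assert_array_equal(rri.end_times, [1000.0, 2000.0])

    def test_72bpm_interval(self):
        beats = BeatAnnotations(np.arange(20) * (60000.0 / 72.0))
        rri = compute_rri(beats)
        np.testing.assert_allclose(rri.intervals, 60000.0 / 72.0, atol=1e-9)

    def test_minimal_two_beats(self):
        assert len(compute_rri(BeatAnnotations(np.array([0.0, 750.0])))) == 1

    def test_single_beat_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_rri(BeatAnnotations(np.array([0.0])))


class TestCorrectRri:
    def test_single_lost_beat_restored(self):
        out = correct_rri(rri_from_intervals([800, 800, 1600, 800]))
        np.testing.assert_allclose(out.intervals, [800] * 5, atol=1e-9)
        np.testing.assert_array_equal(out.corrected_mask,
                                      [False, False, True, True, False])

    def test_no_abnormal_values_identity(self):
        rri = rri_from_intervals([800.0] * 10)
        out = correct_rri(rri)
        np.testing.assert_array_equal(out.intervals, rri.intervals)
        assert not out.corrected_mask.any()

    def test_two_lost_beats_equal_split(self):
        out = correct_rri(rri_from_intervals([800, 2400, 800]))
        np.testing.assert_allclose(out.intervals, [800] * 5, atol=1e-9)
        assert out.total_duration_ms == pytest.approx(4000.0, abs=1e-9)

    def test_end_times_preserved_at_original_beats(self):
        rri = rri_from_intervals([800, 800, 1600, 800])
        out = correct_rri(rri)
        assert set(np.round(rri.end_times, 6)).issubset(
            set(np.round(out.end_times, 6)))

    def test_abnormal_median_uncorrectable(self):
        # the dropout appears before any normal interval and the series
        # median is itself beyond the absolute threshold: no sane reference
        with pytest.raises(UncorrectableSeriesError):
            correct_rri(rri_from_intervals([4000.0, 1600.0, 1700.0]))

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(600, 1100), min_size=4, max_size=30),
        st.data(),
    )
    def test_duration_conserved_and_idempotent(self, base, data):
        # inject 0-3 long dropout intervals into an otherwise sane series
        intervals = list(base)
        n_drop = data.draw(st.integers(0, 3))
        for _ in range(n_drop):
            pos = data.draw(st.integers(0, len(intervals)))
            factor = data.draw(st.integers(2, 5))
            intervals.insert(pos, float(np.median(base)) * factor)
        rri = rri_from_intervals(intervals)
        once = correct_rri(rri)
        assert once.total_duration_ms == pytest.approx(
            rri.total_duration_ms, rel=1e-9)
        twice = correct_rri(once)
        np.testing.assert_allclose(twice.intervals, once.intervals, rtol=1e-9)
        # no remaining interval is abnormal under the correction rule
        assert np.all(once.intervals <= max(1500.0,
                                            1.5 * np.median(once.intervals)) + 1e-6)


class TestHrConversion:
    @pytest.mark.parametrize(
        "interval,expected",
        [(60000.0 / 72.0, 72.0), (1000.0, 60.0), (500.0, 120.0)],
    )
    def test_reciprocal(self, interval, expected):
        hr = hr_from_rri(rri_from_intervals([interval]))
        assert hr.hr[0] == pytest.approx(expected, abs=1e-9)

    def test_times_are_interval_end_times(self):
        rri = rri_from_intervals([800.0, 900.0])
        np.testing.assert_array_equal(hr_from_rri(rri).times, rri.end_times)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValidationError):
            RRISeries(end_times=np.array([1.0]), intervals=np.array([-5.0]))


class TestSmoothHr:
    def test_constant_series_unchanged(self):
        hr = HRSeries(np.arange(10) * 800.0, np.full(10, 72.0))
        np.testing.assert_allclose(smooth_hr(hr, 5).hr, 72.0)

    def test_trailing_mean_of_five(self):
        hr = HRSeries(np.arange(5) * 800.0, np.array([70.0, 71, 72, 73, 74]))
        out = smooth_hr(hr, 5)
        assert out.hr[-1] == pytest.approx(72.0)
        assert out.hr[0] == pytest.approx(70.0)  # partial leading window
        assert len(out) == len(hr)

    def test_matches_bruteforce_sliding_mean(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(50, 150, 100)
        hr = HRSeries(np.arange(100) * 800.0, vals)
        out = smooth_hr(hr, 5)
        expected = [np.mean(vals[max(0, i - 4) : i + 1]) for i in range(100)]
        np.testing.assert_allclose(out.hr, expected, rtol=1e-12)

    def test_never_increases_variance(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(55, 140, 200)
        hr = HRSeries(np.arange(200) * 800.0, vals)
        assert np.var(smooth_hr(hr, 5).hr) <= np.var(vals)

    @pytest.mark.parametrize("window", [0, -3, 2, 4])
    def test_bad_window_rejected(self, window):
        hr = HRSeries(np.arange(5) * 800.0, np.full(5, 60.0))
        with pytest.raises(ConfigurationError):
            smooth_hr(hr, window)


class TestRecoveryProperties:
    def test_worked_example_50ms_perturbation_bound(self):
        # a 50 ms fiducial error at a true rate of 72 bpm moves the
        # one-interval HR by at most ~4.6 bpm
        rri = 60000.0 / 72.0
        devs = [abs(60000.0 / (rri + d) - 72.0) for d in (-50.0, 50.0)]
        assert max(devs) == pytest.approx(60000.0 / (rri - 50.0) - 72.0)
        assert max(devs) <= 5.0

    def test_isolated_deletions_recovered_within_1ms(self):
        rri = 60000.0 / 72.0
        beats = np.arange(73) * rri  # 60 s at 72 bpm
        rng = np.random.default_rng(2)
        candidates = np.arange(2, 71, 2)  # guaranteed non-adjacent
        drop = rng.choice(candidates, size=4, replace=False)  # ~5% of beats
        kept = BeatAnnotations(np.delete(beats, drop))
        corrected = correct_rri(compute_rri(kept))
        np.testing.assert_allclose(corrected.intervals, rri, atol=1.0)
        assert corrected.total_duration_ms == pytest.approx(
            beats[-1] - beats[0], rel=1e-12)
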