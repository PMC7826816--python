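"""Filtering, imputation and corruption scrubbing."""

import numpy as np
import pytest

from premac import preprocess as pp
from premac.streams_io import SensorStream


def _stream(values, rate, channels=None, modality="x"):
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == 1:
        values = values.T
    n = len(values)
    channels = channels or tuple(f"c{i}" for i in range(values.shape[1]))
    ts = np.round(np.arange(n) * 1000.0 / rate).astype(np.int64)
    return SensorStream(modality, channels, rate, ts, values)


def _sine(freq, rate, dur_s=20.0):
    t = np.arange(int(dur_s * rate)) / rate
    return np.sin(2 * np.pi * freq * t)


def _steady_amplitude(x, rate):
    mid = x[int(3 * rate):-int(3 * rate)]  # skip edge transients
    return float(np.max(np.abs(mid)))


class TestFilters:
    def test_lowpass_passes_dc(self):
        s = _stream(np.ones(500), 32.0)
        out = pp.lowpass_filter(s, 10.0)
        np.testing.assert_allclose(out.values, 1.0, atol=1e-6)
        np.testing.assert_array_equal(out.timestamps, s.timestamps)

    @pytest.mark.parametrize("freq, passes", [(1.0, True), (14.0, False)])
    def test_lowpass_matches_analytic_response(self, freq, passes):
        s = _stream(_sine(freq, 32.0), 32.0)
        out = pp.lowpass_filter(s, 10.0)
        amp = _steady_amplitude(out.values[:, 0], 32.0)
        gain = pp.butterworth_gain(
            pp.FilterSpec("lowpass", (10.0,)), 32.0, freq)
        assert amp == pytest.approx(gain, rel=0.02)
        if passes:
            assert abs(amp - 1.0) < 0.05
        else:
            assert amp < 0.2

    def test_bandpass_rejects_dc(self):
        s = _stream(np.full(800, 2.0), 64.0)
        out = pp.bandpass_filter(s, 1.0, 8.0)
        assert np.abs(out.values[200:-200]).max() < 1e-3

    @pytest.mark.parametrize("freq, rel_tol, bound", [
        (4.0, 0.10, None),     # mid-band preserved
        (0.1, None, 0.1),      # drift removed
    ])
    def test_bandpass_matches_analytic_response(self, freq, rel_tol, bound):
        s = _stream(_sine(freq, 64.0, 60.0), 64.0)
        out = pp.bandpass_filter(s, 1.0, 8.0)
        amp = _steady_amplitude(out.values[:, 0], 64.0)
        gain = pp.butterworth_gain(
            pp.FilterSpec("bandpass", (1.0, 8.0)), 64.0, freq)
        assert amp == pytest.approx(gain, abs=0.02)
        if rel_tol is not None:
            assert amp == pytest.approx(1.0, rel=rel_tol)
        if bound is not None:
            assert amp < bound

    def test_cutoff_beyond_nyquist_rejected(self):
        s = _stream(np.ones(100), 15.0)
        with pytest.raises(pp.FilterParameterError):
            pp.lowpass_filter(s, 10.0)
        with pytest.raises(pp.FilterParameterError):
            pp.bandpass_filter(_stream(np.ones(100), 4.0), 1.0, 3.0)

    def test_filters_are_linear(self, rng):
        x = _stream(rng.normal(size=600), 32.0)
        y = _stream(rng.normal(size=600), 32.0)
        combo = _stream(2.5 * x.values[:, 0] - 1.5 * y.values[:, 0], 32.0)
        lhs = pp.lowpass_filter(combo, 10.0).values
        rhs = (2.5 * pp.lowpass_filter(x, 10.0).values
               - 1.5 * pp.lowpass_filter(y, 10.0).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_missing_values_rejected(self):
        vals = np.ones(100)
        vals[3] = np.nan
        with pytest.raises(pp.FilterParameterError, match="gap-free"):
            pp.lowpass_filter(_stream(vals, 32.0), 10.0)


def _brute_force_neighbors(ts, col, i, k):
    """Exhaustive nearest-by-time search (test-local oracle)."""
    avail = [j for j in range(len(col)) if not np.isnan(col[j])]
    avail.sort(key=lambda j: (abs(int(ts[j]) - int(ts[i])), ts[j]))
    return avail[:k]


class TestImputation:
    def test_constant_gap_filled_with_constant(self):
        vals = np.full(40, 5.0)
        vals[10] = np.nan
        out = pp.impute_numeric(_stream(vals, 10.0))
        assert out.values[10, 0] == 5.0

    def test_ramp_gap_matches_brute_force(self):
        vals = np.arange(40, dtype=float)
        vals[10] = np.nan
        s = _stream(vals, 10.0)
        out = pp.impute_numeric(s, k=20)
        nb = _brute_force_neighbors(s.timestamps, vals, 10, 20)
        assert out.values[10, 0] == pytest.approx(np.mean(vals[nb]))

    def test_random_gaps_match_brute_force(self, rng):
        vals = rng.normal(size=60)
        miss = rng.choice(60, size=15, replace=False)
        vals[miss] = np.nan
        s = _stream(vals.copy(), 10.0)
        out = pp.impute_numeric(s, k=20)
        for i in miss:
            nb = _brute_force_neighbors(s.timestamps, vals, i, 20)
            assert out.values[i, 0] == pytest.approx(np.mean(vals[nb]))
        # untouched non-missing entries
        ok = ~np.isnan(vals)
        np.testing.assert_array_equal(out.values[ok, 0], vals[ok])
        # imputed values bounded by their neighborhoods
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        assert np.all((out.values[miss, 0] >= lo) & (out.values[miss, 0] <= hi))

    def test_fewer_available_than_k_uses_all(self):
        vals = np.full(10, np.nan)
        vals[[0, 2, 4, 5, 7, 8, 9]] = [1, 2, 3, 4, 5, 6, 7]
        out = pp.impute_numeric(_stream(vals, 10.0), k=20)
        assert out.values[1, 0] == pytest.approx(np.mean([1, 2, 3, 4, 5, 6, 7]))

    def test_categorical_mode(self):
        vals = np.array([1.0] * 10 + [np.nan] + [1.0] * 10)
        out = pp.impute_categorical(_stream(vals, 10.0))
        assert out.values[10, 0] == 1.0

    def test_categorical_majority_of_neighbors(self):
        # 20 nearest = twelve 0.5 and eight 0 -> 0.5
        vals = np.array([0.5] * 12 + [np.nan] + [0.0] * 8)
        out = pp.impute_categorical(_stream(vals, 10.0), k=20)
        assert out.values[12, 0] == 0.5
        assert set(np.unique(out.values)) <= {0.0, 0.5, 1.0}

    def test_categorical_tie_breaks_to_nearest(self):
        # exactly 10 vs 10; the single nearest sample (right side) wins
        vals = np.array([0.0] * 10 + [np.nan] + [1.0] * 10)
        s = _stream(vals, 10.0)
        s.timestamps = s.timestamps.copy()
        s.timestamps[11:] -= 10  # right neighbor strictly closer
        out = pp.impute_categorical(s, k=20)
        assert out.values[10, 0] == 1.0

    def test_all_missing_channel_raises(self):
        with pytest.raises(pp.ImputationError):
            pp.impute_numeric(_stream(np.full(5, np.nan), 10.0))


class TestScrubbing:
    def test_clean_stream_untouched(self, rng):
        s = _stream(rng.normal(size=(100, 2)), 15.0,
                    channels=("acclx", "magx"))
        out, rep = pp.scrub_corrupted(s)
        np.testing.assert_array_equal(out.values, s.values)
        assert rep.row_fraction == 0.0

    def test_nonfinite_rows_counted(self, rng):
        vals = rng.normal(size=(1000, 2))
        vals[[5, 500, 900], 0] = np.inf
        s = _stream(vals, 15.0, channels=("acclx", "magx"))
        out, rep = pp.scrub_corrupted(s)
        assert rep.row_fraction == pytest.approx(0.003)
        assert rep.per_channel["acclx"] == pytest.approx(0.003)
        assert np.isnan(out.values[[5, 500, 900], :]).all()

    def test_out_of_range_acceleration_scrubbed(self):
        vals = np.ones((50, 2))
        vals[7, 0] = 20.0   # beyond +-16 g full scale
        vals[9, 1] = 20.0   # magnetometer channel: no range check
        s = _stream(vals, 15.0, channels=("acclx", "magx"))
        out, rep = pp.scrub_corrupted(s)
        assert np.isnan(out.values[7]).all()
        assert not np.isnan(out.values[9]).any()

    def test_simulated_corruption_rate_recovered(self, small_subject):
        fracs, weights = [], []
        for rec in small_subject.sessions:
            _, rep = pp.scrub_corrupted(rec.streams["wings"])
            fracs.append(rep.row_fraction)
            weights.append(rep.n_rows)
        pooled = float(np.average(fracs, weights=weights))
        n = sum(weights)
        sd = np.sqrt(0.003 * 0.997 / n)
        assert abs(pooled - 0.003) < 4 * sd + 1e-12

    def test_bridge_short_gaps(self):
        vals = np.arange(10, dtype=float)
        vals[[3, 4]] = np.nan          # short gap: bridged linearly
        vals[[6, 7, 8]] = np.nan       # long gap: left missing
        out = pp.bridge_short_gaps(_stream(vals, 10.0), max_gap=2)
        assert out.values[3, 0] == pytest.approx(3.0)
        assert out.values[4, 0] == pytest.approx(4.0)
        assert np.isnan(out.values[[6, 7, 8], 0]).all()
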