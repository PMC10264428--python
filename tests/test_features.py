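import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from remhf import SimulationConfig, simulate_hypnogram, simulate_signals, inject_artifacts
from remhf.features import (
    BandTable,
    DEFAULT_BANDS,
    band_average_power,
    epoch_band_powers,
    excise_artifacts,
    extract_features,
    grubbs_critical_value,
    grubbs_replace,
    hourly_summary,
    segment_epochs,
    zscore,
)
from remhf.states import Hypnogram, VigilanceState

W, N, R = VigilanceState.WAKE, VigilanceState.NREM, VigilanceState.REM
FS = 1000.0


class TestBandTable:
    def test_default_has_nine_bands(self):
        table = BandTable()
        assert len(table) == 9
        assert table[0] == (0.1, 4.0)
        assert table[-1] == (350.0, 500.0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BandTable(((0.0, 5.0), (4.0, 8.0)))

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError, match="low must be"):
            BandTable(((8.0, 4.0),))

    def test_nyquist_check(self):
        with pytest.raises(ValueError, match="Nyquist"):
            BandTable(((350.0, 600.0),)).validate_nyquist(1000.0)


class TestExciseArtifacts:
    def test_flat_signal_untouched(self):
        x = np.zeros(1000)
        cleaned, intervals = excise_artifacts(x, threshold=1.0, fs=FS)
        assert intervals == []
        assert np.array_equal(cleaned, x)

    def test_single_spike_excises_101_samples(self):
        x = np.zeros(1000)
        x[500] = 10.0
        cleaned, intervals = excise_artifacts(x, threshold=5.0, fs=FS, pad_ms=50)
        assert intervals == [(450, 551)]
        assert 551 - 450 == 101
        assert np.allclose(cleaned, 0.0)

    def test_interpolation_is_linear(self):
        x = np.arange(100, dtype=float)
        x[50] = 1000.0
        cleaned, intervals = excise_artifacts(x, threshold=500.0, fs=FS, pad_ms=2)
        (a, b), = intervals
        assert (a, b) == (48, 53)
        # linear bridge between x[47]=47 and x[53]=53
        assert np.allclose(cleaned[a:b], np.interp(np.arange(a, b), [47, 53], [47.0, 53.0]))
        assert np.array_equal(cleaned[:a], x[:a])
        assert np.array_equal(cleaned[b:], x[b:])

    def test_edge_spike_uses_nearest_clean_value(self):
        x = np.ones(100)
        x[0] = 50.0
        cleaned, intervals = excise_artifacts(x, threshold=10.0, fs=FS, pad_ms=5)
        (a, b), = intervals
        assert a == 0
        assert np.allclose(cleaned[a:b], 1.0)

    def test_all_above_threshold_raises(self):
        with pytest.raises(ValueError, match="entire signal"):
            excise_artifacts(np.full(100, 9.0), threshold=1.0, fs=FS)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_samples_outside_intervals_untouched(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 500)
        x[rng.integers(0, 500, 3)] += 20.0
        cleaned, intervals = excise_artifacts(x, threshold=6.0, fs=FS, pad_ms=10)
        inside = np.zeros(500, dtype=bool)
        for a, b in intervals:
            inside[a:b] = True
        assert np.array_equal(cleaned[~inside], x[~inside])

    def test_ground_truth_artifacts_covered(self):
        cfg = SimulationConfig(duration_hours=0.25, channels=("eeg_v1",),
                               artifact_rate_per_wake_epoch=1.0, seed=21)
        hyp = simulate_hypnogram(cfg)
        clean = simulate_signals(hyp, cfg)
        dirty, times = inject_artifacts(clean, hyp, cfg)
        assert times
        sig = dirty.channels["eeg_v1"]
        thr = 6.0 * float(np.std(clean.channels["eeg_v1"]))
        _, intervals = excise_artifacts(sig, thr, FS, pad_ms=50)
        excised = np.zeros(len(sig), dtype=bool)
        for a, b in intervals:
            excised[a:b] = True
        truth = np.zeros(len(sig), dtype=bool)
        for t0, t1 in times:
            truth[int(t0 * FS): int(t1 * FS)] = True
        coverage = excised[truth].mean()
        assert coverage >= 0.95


class TestSegmentEpochs:
    def test_23h_arithmetic(self):
        x = np.zeros(int(23 * 3600 * 10))  # 10 Hz stand-in for speed
        blocks = segment_epochs(x, fs=10, epoch_seconds=4)
        assert blocks.shape == (20700, 40)

    def test_trailing_partial_dropped(self):
        blocks = segment_epochs(np.arange(4001.0), FS, 4.0)
        assert blocks.shape == (1, 4000)

    def test_partition_property(self):
        x = np.arange(12345.0)
        blocks = segment_epochs(x, FS, 4.0)
        assert np.array_equal(blocks.reshape(-1), x[: blocks.size])

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter than one epoch"):
            segment_epochs(np.zeros(100), FS, 4.0)


class TestBandAveragePower:
    def test_pure_tone_parseval(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 100.0 * t)
        integrated = band_average_power(x, FS, (80.0, 120.0), mode="integrated")
        assert integrated == pytest.approx(0.5, rel=0.01)
        average = band_average_power(x, FS, (80.0, 120.0), mode="average")
        assert average == pytest.approx(0.5 / 40.0, rel=0.01)
        for band in DEFAULT_BANDS:
            if band == (80.0, 120.0):
                continue
            assert band_average_power(x, FS, band, mode="integrated") < 0.01 * integrated

    def test_zero_signal(self):
        x = np.zeros(4000)
        for band in DEFAULT_BANDS:
            assert band_average_power(x, FS, band) == 0.0

    def test_band_above_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_average_power(np.zeros(4000), FS, (400.0, 600.0))

    def test_parseval_partition_on_bandlimited_noise(self, rng):
        # white noise band-limited to 0.1-500 Hz by FFT masking
        white = rng.normal(0, 1, 4000)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(4000, 1 / FS)
        spec[(freqs < 0.1)] = 0.0
        x = np.fft.irfft(spec, 4000)
        total = sum(
            band_average_power(x, FS, band, mode="integrated")
            for band in DEFAULT_BANDS
        )
        assert total == pytest.approx(np.var(x), rel=0.02)

    def test_vectorised_matches_scalar(self, rng):
        epochs = rng.normal(0, 1, (3, 4000))
        table = BandTable(DEFAULT_BANDS)
        vec = epoch_band_powers(epochs, FS, table)
        for i in range(3):
            for j, band in enumerate(table):
                assert vec[i, j] == pytest.approx(
                    band_average_power(epochs[i], FS, band), rel=1e-12)


def grubbs_oracle(series, alpha=0.05):
    """Brute-force iterative Grubbs: independent of the implementation."""
    x = list(map(float, series))
    active = list(range(len(x)))
    flagged = []
    while len(active) >= 3:
        vals = [x[i] for i in active]
        n = len(vals)
        mean = sum(vals) / n
        sd = (sum((v - mean) ** 2 for v in vals) / (n - 1)) ** 0.5
        if sd == 0:
            break
        devs = [abs(v - mean) for v in vals]
        g = max(devs) / sd
        tcrit = sstats.t.ppf(1 - alpha / (2 * n), n - 2)
        crit = (n - 1) / n**0.5 * (tcrit**2 / (n - 2 + tcrit**2)) ** 0.5
        if g <= crit:
            break
        worst = active[devs.index(max(devs))]
        flagged.append(worst)
        active.remove(worst)
    return sorted(flagged)


class TestGrubbs:
    def test_no_outlier_in_linear_series(self):
        cleaned, idx = grubbs_replace([1, 2, 3, 4, 5])
        assert idx == []
        assert np.array_equal(cleaned, [1, 2, 3, 4, 5])
        # the statistic really is below the critical value
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        assert g == pytest.approx(1.265, abs=1e-3)
        assert g < grubbs_critical_value(5, 0.05)

    def test_single_gross_outlier_replaced_by_neighbour(self):
        cleaned, idx = grubbs_replace([1, 1, 1, 1, 100])
        assert idx == [4]
        assert cleaned[4] == pytest.approx(1.0)

    def test_constant_series_untouched(self):
        cleaned, idx = grubbs_replace([7.0] * 10)
        assert idx == []
        assert np.all(cleaned == 7.0)

    def test_interior_outlier_interpolated(self):
        cleaned, idx = grubbs_replace([0.0, 1.0, 50.0, 3.0, 4.0])
        assert idx == [2]
        assert cleaned[2] == pytest.approx(2.0)  # midpoint of 1 and 3

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            grubbs_replace([1.0, 2.0])

    def test_oracle_agreement_many_series(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 40))
            x = rng.normal(0, 1, n)
            n_out = int(rng.integers(0, 3))
            if n_out:
                pos = rng.choice(n, size=n_out, replace=False)
                x[pos] += rng.choice([-1, 1], n_out) * rng.uniform(5, 20, n_out)
            _, idx = grubbs_replace(x)
            assert idx == grubbs_oracle(x)


class TestZscore:
    def test_basic(self):
        assert np.allclose(zscore([1, 2, 3]), [-1, 0, 1])

    @given(st.floats(0.1, 100.0), st.floats(-50.0, 50.0), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(0, 1, 50)
        assert np.allclose(zscore(a * x + b), zscore(x), atol=1e-9)

    def test_output_moments(self, rng):
        z = zscore(rng.normal(5, 3, 1000))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            zscore([2.0, 2.0, 2.0])


class TestExtractFeatures:
    def test_clean_recording_full_shape(self, small_cfg):
        hyp = simulate_hypnogram(small_cfg)
        rec = simulate_signals(hyp, small_cfg)  # no artifacts injected
        fm = extract_features(rec, hyp)
        assert fm.values.shape == (len(hyp), 9)
        assert fm.dropped_epochs == []
        assert fm.zscored

    def test_column_moments_after_pipeline(self, small_sim):
        rec, hyp, _ = small_sim
        fm = extract_features(rec, hyp)
        assert np.allclose(fm.values.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(fm.values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_dense_burst_epoch_dropped(self, small_cfg):
        hyp = simulate_hypnogram(small_cfg)
        rec = simulate_signals(hyp, small_cfg)
        sig = rec.channels["eeg_v1"]
        n_per = int(FS * small_cfg.epoch_seconds)
        # 10% of epoch 3 saturated
        sd = np.std(sig)
        sig[3 * n_per: 3 * n_per + n_per // 10] = 50.0 * sd
        fm = extract_features(rec, hyp, artifact_threshold=6.0 * sd)
        assert 3 in fm.dropped_epochs
        assert fm.values.shape[0] == len(hyp) - len(fm.dropped_epochs)

    def test_scale_equivariance(self, small_cfg):
        hyp = simulate_hypnogram(small_cfg)
        rec = simulate_signals(hyp, small_cfg)
        thr = 1e9  # effectively no excision
        fm1 = extract_features(rec, hyp, artifact_threshold=thr,
                               apply_zscore=False, grubbs_alpha=1e-12)
        scaled = rec.copy()
        scaled.channels["eeg_v1"] *= 3.0
        fm2 = extract_features(scaled, hyp, artifact_threshold=thr,
                               apply_zscore=False, grubbs_alpha=1e-12)
        assert np.allclose(fm2.values, 9.0 * fm1.values, rtol=1e-10)
        z1 = fm1.zscored_copy()
        z2 = fm2.zscored_copy()
        assert np.allclose(z1.values, z2.values, atol=1e-9)

    def test_alignment_mismatch_raises(self, small_cfg):
        hyp = simulate_hypnogram(small_cfg)
        rec = simulate_signals(hyp, small_cfg)
        short = Hypnogram(list(hyp.labels[:10]), hyp.epoch_seconds)
        with pytest.raises(ValueError, match="misaligned"):
            extract_features(rec, short)


class TestHourlySummary:
    def _features_for(self, hyp):
        rng = np.random.default_rng(0)
        from remhf.features import FeatureMatrix
        vals = rng.normal(0, 1, (len(hyp), 9))
        vals = (vals - vals.mean(0)) / vals.std(0, ddof=1)
        return FeatureMatrix(vals, hyp.labels, BandTable(), zscored=True)

    def test_all_wake_hour(self):
        hyp = Hypnogram([W] * 900)
        hs = hourly_summary(self._features_for(hyp), hyp)
        assert hs.percent_wake[0] == 100.0
        assert hs.percent_rem[0] == 0.0

    def test_45_rem_epochs_is_5_percent(self):
        hyp = Hypnogram([R] * 45 + [N] * 855)
        hs = hourly_summary(self._features_for(hyp), hyp)
        assert hs.percent_rem[0] == pytest.approx(5.0)

    def test_row_count(self):
        hyp = Hypnogram([W] * (3 * 900 + 100))
        hs = hourly_summary(self._features_for(hyp), hyp)
        assert len(hs.hours) == 3

    def test_less_than_one_hour_raises(self):
        hyp = Hypnogram([W] * 100)
        with pytest.raises(ValueError, match="full hour"):
            hourly_summary(self._features_for(hyp), hyp)
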