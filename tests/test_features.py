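import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from appraisal_decode.features import (
    EPS,
    FeatureParams,
    FeatureTable,
    _bank_centers,
    apply_taper,
    build_feature_table,
    extract_features,
    features_per_channel,
    filterbank_log_amps,
    make_windows,
    segment_extras,
    window_descriptors,
)

FS = 256.0


def fft_bank_oracle(segment, fs, n_banks, f_lo, f_hi):
    """Independent re-derivation of the filter-bank amplitudes: explicit FFT
    and per-bin triangular weights evaluated point by point."""
    n = len(segment)
    spectrum = np.fft.rfft(segment)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    centers = np.geomspace(f_lo, f_hi, n_banks)
    out = []
    for i in range(n_banks):
        lo = f_lo if i == 0 else centers[i - 1]
        hi = f_hi if i == n_banks - 1 else centers[i + 1]
        c = centers[i]
        acc = 0.0
        for f, amp in zip(freqs, np.abs(spectrum)):
            if lo <= f <= c:
                w = 1.0 if c == lo else (f - lo) / (c - lo)
            elif c < f <= hi:
                w = (hi - f) / (hi - c)
            else:
                w = 0.0
            acc += w * amp
        out.append(np.log(acc + EPS))
    return np.array(out)


class TestMakeWindows:
    def test_eeg_nine_windows(self):
        wins = make_windows(256, FS, 200.0, 0.5, 1000.0, allow_truncated=False)
        assert len(wins) == 9
        starts_ms = [a / FS * 1000 for a, _ in wins]
        np.testing.assert_allclose(starts_ms, np.arange(9) * 100.0, atol=2.0)
        assert wins[0] == (0, 51)
        assert wins[-1][1] == 256

    def test_emg_seven_windows_with_truncated_last(self):
        wins = make_windows(384, FS, 400.0, 0.5, None, allow_truncated=True)
        assert len(wins) == 7
        # last window 1200-1500 ms: 100 ms shorter than the others
        a, b = wins[-1]
        assert a == round(1200 * FS / 1000) and b == 384

    def test_window_equal_to_signal(self):
        assert make_windows(256, FS, 1000.0, 0.5, None, False) == [(0, 256)]

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_windows(128, FS, 1000.0, 0.5, None, False)

    def test_limit_beyond_signal_reports_achievable(self):
        with pytest.raises(ValueError, match="achievable"):
            make_windows(128, FS, 200.0, 0.5, 1000.0, False)

    def test_no_truncated_window_without_flag(self):
        wins = make_windows(384, FS, 400.0, 0.5, None, allow_truncated=False)
        assert len(wins) == 6


class TestApplyTaper:
    def test_fade_zero_is_identity(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(apply_taper(x, 0.0), x)

    def test_endpoints_zeroed(self, rng):
        x = rng.standard_normal(100) + 5.0
        y = apply_taper(x, 0.10)
        assert y[0] == 0.0 and y[-1] == 0.0

    def test_middle_80_percent_untouched(self, rng):
        x = rng.standard_normal(100)
        y = apply_taper(x, 0.10)
        np.testing.assert_array_equal(y[10:90], x[10:90])

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            apply_taper(np.zeros(10), 0.6)


class TestFilterbank:
    def test_zero_signal_at_floor(self):
        out = filterbank_log_amps(np.zeros(512), FS, 8, 1.0, 40.0)
        np.testing.assert_allclose(out, np.log(EPS))

    def test_scaling_shifts_by_log10(self, rng):
        x = rng.standard_normal(512)
        a = filterbank_log_amps(x, FS, 8, 1.0, 40.0)
        b = filterbank_log_amps(10.0 * x, FS, 8, 1.0, 40.0)
        np.testing.assert_allclose(b - a, np.log(10.0), atol=1e-6)

    @pytest.mark.parametrize("bank", range(1, 8))
    def test_tone_at_center_peaks_at_that_bank(self, bank):
        # 4-second segment for ~0.25 Hz resolution; bank 0 (1 Hz) excluded:
        # its tone also maximally excites the wider bank-1 triangle
        n = 1024
        centers = _bank_centers(8, 1.0, 40.0)
        t = np.arange(n) / FS
        tone = np.sin(2 * np.pi * centers[bank] * t)
        out = filterbank_log_amps(tone, FS, 8, 1.0, 40.0)
        assert np.argmax(out) == bank
        oracle = fft_bank_oracle(tone, FS, 8, 1.0, 40.0)
        np.testing.assert_allclose(out, oracle, atol=1e-8)

    def test_matches_oracle_on_noise(self, rng):
        x = rng.standard_normal(768)
        out = filterbank_log_amps(x, FS, 10, 20.0, 60.0)
        oracle = fft_bank_oracle(x, FS, 10, 20.0, 60.0)
        np.testing.assert_allclose(out, oracle, atol=1e-8)

    def test_too_many_banks_rejected(self):
        with pytest.raises(ValueError, match="banks"):
            filterbank_log_amps(np.zeros(10), FS, 8, 1.0, 40.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            filterbank_log_amps(np.zeros(512), FS, 8, 1.0, 200.0)


class TestWindowDescriptors:
    def test_constant_rms(self):
        params = FeatureParams.eeg_default()
        out = window_descriptors(np.full(256, -3.0), FS, params)
        assert out[-1] == pytest.approx(3.0)

    def test_unit_sine_rms(self):
        t = np.arange(256) / FS
        out = window_descriptors(np.sin(2 * np.pi * 8 * t), FS, FeatureParams.eeg_default())
        assert out[-1] == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_zero_signal(self):
        out = window_descriptors(np.zeros(256), FS, FeatureParams.eeg_default())
        assert out[-1] == 0.0
        np.testing.assert_allclose(out[:-1], np.log(EPS))


class TestSegmentExtras:
    def test_impulse_position(self):
        x = np.zeros(100)
        x[30] = 1.0
        out = segment_extras(x, FS, FeatureParams.eeg_default())
        assert out[2] == pytest.approx(30 / 99)  # pos_max
        assert out[1] == pytest.approx(np.argmin(x) / 99)

    def test_sine_centroid_matches_oracle(self):
        t = np.arange(256) / FS  # 1000 ms
        x = np.sin(2 * np.pi * 10.0 * t)
        out = segment_extras(x, FS, FeatureParams.eeg_default())
        assert out[0] == pytest.approx(10.0, abs=0.5)
        # independent FFT oracle for the centroid on the same tapered input
        from appraisal_decode.features import _spectral_input

        tapered = _spectral_input(x, 0.10)
        freqs = np.fft.rfftfreq(256, 1 / FS)
        mag = np.abs(np.fft.rfft(tapered))
        band = (freqs >= 1.0) & (freqs <= 40.0)
        oracle = (freqs[band] * mag[band]).sum() / mag[band].sum()
        assert out[0] == pytest.approx(oracle, abs=1e-9)

    def test_constant_signal_conventions(self):
        out = segment_extras(np.full(256, 4.2), FS, FeatureParams.eeg_default())
        centroid, pos_min, pos_max, entropy, std, slope = out
        assert std == pytest.approx(0.0, abs=1e-12)
        assert slope == 0.0
        assert centroid == 0.0 and entropy == 0.0

    def test_entropy_of_flat_spectrum_near_log_bins(self, rng):
        x = rng.standard_normal(4096)
        out = segment_extras(x, FS, FeatureParams.eeg_default())
        freqs = np.fft.rfftfreq(4096, 1 / FS)
        n_bins = ((freqs >= 1.0) & (freqs <= 40.0)).sum()
        assert 0 < out[3] <= np.log(n_bins) + 1e-9


class TestExtractFeatures:
    def test_eeg_channel_yields_96(self, rng):
        vec, names = extract_features(rng.standard_normal((1, 256)), FeatureParams.eeg_default())
        assert vec.size == len(names) == 96

    def test_emg_region_yields_94(self, rng):
        vec, names = extract_features(
            np.abs(rng.standard_normal((1, 384))), FeatureParams.emg_default()
        )
        assert vec.size == len(names) == 94

    def test_64_channels_yield_6144(self, rng):
        vec, _ = extract_features(rng.standard_normal((64, 256)), FeatureParams.eeg_default())
        assert vec.size == 6144

    def test_post_stimulus_restriction(self, rng):
        t = np.arange(-51, 256) * 1000.0 / FS
        epoch = rng.standard_normal((2, t.size))
        vec_full, _ = extract_features(epoch, FeatureParams.eeg_default(), time_axis=t)
        vec_post, _ = extract_features(epoch[:, t >= 0], FeatureParams.eeg_default())
        np.testing.assert_array_equal(vec_full, vec_post)

    def test_channel_permutation_permutes_blocks(self, rng):
        epoch = rng.standard_normal((3, 256))
        v, _ = extract_features(epoch, FeatureParams.eeg_default())
        v_perm, _ = extract_features(epoch[[2, 0, 1]], FeatureParams.eeg_default())
        blocks = v.reshape(3, 96)
        np.testing.assert_array_equal(v_perm.reshape(3, 96), blocks[[2, 0, 1]])

    def test_all_finite_for_finite_input(self, rng):
        epoch = 1e6 * rng.standard_normal((2, 256))
        vec, _ = extract_features(epoch, FeatureParams.eeg_default())
        assert np.isfinite(vec).all()

    def test_too_short_epoch_states_achievable(self, rng):
        with pytest.raises(ValueError, match="achievable"):
            extract_features(rng.standard_normal((1, 128)), FeatureParams.eeg_default())

    @settings(max_examples=20, deadline=None)
    @given(
        n_banks=st.integers(2, 12),
        n_win=st.integers(1, 6),
        overlap=st.sampled_from([0.0, 0.25, 0.5]),
    )
    def test_feature_count_formula(self, n_banks, n_win, overlap):
        params = FeatureParams(
            n_banks=n_banks,
            f_lo=2.0,
            f_hi=40.0,
            window_ms=100.0,
            overlap_fraction=overlap,
            window_limit_ms=None,
        )
        n_samples = 512
        epoch = np.linspace(0, 1, n_samples)[None, :] * np.ones((n_win, 1))
        vec, _ = extract_features(epoch, params)
        windows = make_windows(n_samples, FS, 100.0, overlap, None, False)
        assert vec.size == n_win * features_per_channel(params, len(windows))


class TestBuildFeatureTable:
    def test_table_shape_and_columns(self, tiny_design, tiny_effect, quiet_noise):
        from appraisal_decode.synthgen import generate_epochs
        from appraisal_decode.trials import relabel

        epochs = generate_epochs(tiny_design, [tiny_effect], quiet_noise, seed=1)
        inst = relabel(epochs, "target")
        params = FeatureParams(window_ms=200.0, window_limit_ms=None)
        table = build_feature_table(inst, params)
        assert table.X.shape[0] == len(inst)
        assert table.columns[0].startswith("Fz/")
        assert set(table.labels) == {"a", "b"}
        df = table.to_dataframe()
        assert list(df.columns[:2]) == ["participant", "label"]


def test_feature_table_tsv(tmp_path, rng):
    table = FeatureTable(
        X=rng.standard_normal((3, 2)),
        columns=["Fz/full/bank0", "Fz/full/rms"],
        labels=np.array(["a", "b", "a"]),
        participants=np.array(["p01", "p01", "p02"]),
    )
    path = tmp_path / "features.tsv"
    table.to_tsv(path)
    header = path.read_text().split("\n")[0].split("\t")
    assert header == ["participant", "label", "Fz/full/bank0", "Fz/full/rms"]
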