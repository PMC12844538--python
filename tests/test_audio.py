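"""Timbre feature extraction: windowing rule, the five descriptors, track pipeline."""

import numpy as np
import pytest

from emofuse import (
    AudioTrack,
    InvalidInputError,
    ShapeError,
    SpectralFrame,
    extract_windows,
    frame_spectrum,
    spectral_centroid,
    spectral_entropy,
    spectral_flux,
    spectral_skewness,
    spectral_spread,
    track_features,
)
from emofuse.audio import TIMBRE_COLUMNS, count_windows


def make_frame(mags, freqs=None):
    mags = np.asarray(mags, dtype=float)
    if freqs is None:
        freqs = np.arange(mags.size, dtype=float) * 100.0
    return SpectralFrame(mags, freqs)


class TestWindowing:
    def test_one_minute_track_gives_118_windows(self):
        track = AudioTrack(np.zeros(60 * 22050), 22050)
        assert len(extract_windows(track, 1.0, 0.5)) == 118

    def test_track_shorter_than_window_gives_no_windows(self):
        track = AudioTrack(np.zeros(int(0.5 * 22050)), 22050)
        assert extract_windows(track, 1.0, 0.5) == []

    def test_two_second_track_start_times(self):
        track = AudioTrack(np.zeros(2 * 8000), 8000)
        frames = extract_windows(track, 1.0, 0.5)
        assert [s for _, s in frames] == [0.0, 0.5]

    def test_empty_track_rejected(self):
        with pytest.raises(InvalidInputError):
            AudioTrack(np.array([]), 8000)

    def test_invalid_overlap_rejected(self):
        track = AudioTrack(np.zeros(8000), 8000)
        with pytest.raises(InvalidInputError):
            extract_windows(track, 1.0, 1.0)
        with pytest.raises(InvalidInputError):
            extract_windows(track, 0.0, 0.5)

    def test_window_count_matches_brute_force_enumeration(self, rng):
        """count = |{k >= 0 : k*hop + w < D}| on 200 random geometries."""
        for _ in range(200):
            duration = rng.uniform(0.2, 30.0)
            window = rng.uniform(0.05, 3.0)
            hop = window * (1.0 - rng.uniform(0.0, 0.9))
            brute = sum(
                1 for k in range(int(duration / hop) + 2) if k * hop + window < duration
            )
            assert count_windows(duration, window, hop) == brute

    def test_extract_windows_agrees_with_count(self, rng):
        for _ in range(20):
            sr = int(rng.integers(1000, 8000))
            n = int(rng.integers(sr // 2, 6 * sr))
            window = float(rng.uniform(0.1, 1.5))
            overlap = float(rng.uniform(0.0, 0.9))
            track = AudioTrack(np.zeros(n), sr)
            frames = extract_windows(track, window, overlap)
            assert len(frames) == count_windows(n / sr, window, window * (1 - overlap))


class TestSpectrum:
    def test_pure_tone_has_dominant_bin_at_its_frequency(self):
        sr, n, f = 8000, 8000, 1000
        t = np.arange(n) / sr
        s = frame_spectrum(np.sin(2 * np.pi * f * t), sr)
        assert s.bin_freqs[np.argmax(s.magnitudes)] == pytest.approx(f)

    def test_zero_frame_gives_zero_magnitudes(self):
        s = frame_spectrum(np.zeros(512), 8000)
        assert np.all(s.magnitudes == 0)

    def test_two_tone_mixture_has_two_dominant_bins(self):
        sr, n = 8000, 8000
        t = np.arange(n) / sr
        x = np.sin(2 * np.pi * 500 * t) + np.sin(2 * np.pi * 2000 * t)
        s = frame_spectrum(x, sr)
        top2 = s.bin_freqs[np.argsort(s.magnitudes)[-2:]]
        assert sorted(top2) == [500, 2000]

    def test_empty_frame_rejected(self):
        with pytest.raises(InvalidInputError):
            frame_spectrum(np.array([]), 8000)


class TestDescriptors:
    def test_centroid_point_mass(self):
        s = make_frame([0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1.0])  # single bin at 1000 Hz
        assert spectral_centroid(s) == pytest.approx(1000.0)

    def test_centroid_symmetric_two_bins(self):
        s = make_frame([0, 1.0, 0, 1.0])  # equal mass at 100 and 300 Hz
        assert spectral_centroid(s) == pytest.approx(200.0)

    def test_zero_spectrum_conventions(self):
        s = make_frame([0, 0, 0, 0])
        assert spectral_centroid(s) == 0.0
        assert spectral_spread(s) == 0.0
        assert spectral_skewness(s) == 0.0
        assert spectral_entropy(s) == 0.0

    def test_spread_single_bin_is_zero(self):
        s = make_frame([0, 0, 5.0])
        assert spectral_spread(s) == 0.0

    def test_spread_equal_bins(self):
        s = make_frame([0, 1.0, 0, 1.0])
        assert spectral_spread(s) == pytest.approx(100.0)

    def test_spread_weighted_two_bins(self):
        # masses 0.75 at 100 Hz and 0.25 at 300 Hz: sqrt(7500)
        s = make_frame([0, 0.75, 0, 0.25])
        assert spectral_spread(s) == pytest.approx(np.sqrt(7500.0), abs=1e-9)

    def test_skewness_symmetric_is_zero(self):
        s = make_frame([0, 1.0, 0, 1.0])
        assert spectral_skewness(s) == pytest.approx(0.0, abs=1e-12)

    def test_skewness_weighted_two_bins(self):
        # third central moment 750000 over spread^3
        s = make_frame([0, 0.75, 0, 0.25])
        expected = 750000.0 / np.sqrt(7500.0) ** 3
        assert spectral_skewness(s) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.1547, abs=1e-4)

    def test_entropy_uniform_is_one(self):
        s = make_frame(np.ones(16))
        assert spectral_entropy(s) == pytest.approx(1.0)

    def test_entropy_point_mass_is_zero(self):
        s = make_frame([0, 0, 3.0, 0])
        assert spectral_entropy(s) == 0.0

    def test_entropy_two_of_eight_bins(self):
        mags = np.zeros(8)
        mags[[2, 5]] = 1.0
        assert spectral_entropy(make_frame(mags)) == pytest.approx(1.0 / 3.0)

    def test_flux_first_frame_is_zero(self):
        assert spectral_flux(make_frame([1.0, 2.0]), None) == 0.0

    def test_flux_identical_spectra_is_zero(self):
        a, b = make_frame([1.0, 2.0, 3.0]), make_frame([2.0, 4.0, 6.0])
        # scale-invariant: proportional spectra have identical p_k
        assert spectral_flux(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_flux_orthogonal_point_masses(self):
        a, b = make_frame([1.0, 0.0]), make_frame([0.0, 1.0])
        assert spectral_flux(a, b) == pytest.approx(np.sqrt(2.0))

    def test_flux_bin_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            spectral_flux(make_frame([1.0, 0.0]), make_frame([1.0, 0.0, 0.0]))

    def test_scale_invariance_of_all_descriptors(self, rng):
        """Multiplying magnitudes by c > 0 leaves every descriptor unchanged."""
        for _ in range(20):
            mags = rng.random(16)
            c = rng.uniform(0.01, 100.0)
            s1, s2 = make_frame(mags), make_frame(mags * c)
            prev = make_frame(rng.random(16))
            for fn in (spectral_centroid, spectral_spread, spectral_skewness,
                       spectral_entropy):
                assert fn(s1) == pytest.approx(fn(s2), abs=1e-10)
            assert spectral_flux(s1, prev) == pytest.approx(
                spectral_flux(s2, prev), abs=1e-10
            )

    def test_descriptors_match_brute_force_moments(self, rng):
        """Each descriptor equals an independent moment/entropy computation."""
        for _ in range(100):
            mags = rng.random(16)
            freqs = np.sort(rng.uniform(0, 4000, 16))
            s = make_frame(mags, freqs)
            p = mags / mags.sum()
            c = sum(f * w for f, w in zip(freqs, p))
            var = sum((f - c) ** 2 * w for f, w in zip(freqs, p))
            m3 = sum((f - c) ** 3 * w for f, w in zip(freqs, p))
            h = -sum(w * np.log(w) for w in p if w > 0) / np.log(16)
            assert spectral_centroid(s) == pytest.approx(c, abs=1e-9)
            assert spectral_spread(s) == pytest.approx(np.sqrt(var), abs=1e-9)
            assert spectral_skewness(s) == pytest.approx(m3 / var**1.5, abs=1e-9)
            assert spectral_entropy(s) == pytest.approx(h, abs=1e-9)


class TestTrackFeatures:
    def test_sixty_second_track_gives_118_by_5_matrix(self, rng):
        track = AudioTrack(rng.standard_normal(60 * 4000) * 0.1, 4000)
        feats = track_features(track, analysis_rate=4000)
        assert feats.values.shape == (118, 5)
        assert tuple(feats.columns) == TIMBRE_COLUMNS

    def test_matrix_invariants_on_random_track(self, rng):
        track = AudioTrack(rng.standard_normal(5 * 4000), 4000)
        feats = track_features(track, analysis_rate=4000)
        spread, entropy, flux = feats.values[:, 1], feats.values[:, 3], feats.values[:, 4]
        assert np.all(spread >= 0)
        assert np.all((entropy >= 0) & (entropy <= 1))
        assert np.all(flux >= 0)
        assert flux[0] == 0.0

    def test_stationary_tone_has_constant_centroid_and_zero_flux(self):
        sr = 4000
        t = np.arange(6 * sr) / sr
        track = AudioTrack(0.5 * np.sin(2 * np.pi * 440 * t), sr)
        feats = track_features(track, analysis_rate=sr)
        assert np.allclose(feats.values[:, 0], 440.0, atol=15.0)
        assert np.allclose(feats.values[1:, 4], 0.0, atol=1e-6)

    def test_too_short_track_raises_with_minimum_duration(self):
        track = AudioTrack(np.zeros(1000), 4000)
        with pytest.raises(InvalidInputError, match="one window"):
            track_features(track, analysis_rate=4000)

    def test_csv_round_trip(self, tmp_path, rng):
        import pandas as pd

        track = AudioTrack(rng.standard_normal(3 * 4000), 4000, track_id="demo")
        feats = track_features(track, analysis_rate=4000)
        path = tmp_path / "feats.csv"
        feats.to_csv(path)
        table = pd.read_csv(path)
        assert list(table.columns) == ["track_id", "window_start", *TIMBRE_COLUMNS]
        assert len(table) == feats.n_windows
        np.testing.assert_allclose(table["centroid"], feats.values[:, 0])
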