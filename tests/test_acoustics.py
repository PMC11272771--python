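import numpy as np
import pytest
from scipy.fft import rfft

from apephon.acoustics import (
    SpectrogramParams,
    Waveform,
    closure_abruptness,
    detect_voicing,
    estimate_formants,
    speech_shaped_noise_mask,
    stft_spectrogram,
    track_formants,
)
from apephon.synth import UtteranceSynthSpec, synthesize_utterance, synthesize_vowel

RATE = 44100


def _tone(freq=1000.0, duration=0.2, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return Waveform(0.5 * np.sin(2 * np.pi * freq * t), rate)


def _pulse_train(f0=150.0, duration=0.4, rate=RATE):
    n = int(duration * rate)
    phase = np.cumsum(np.full(n, f0)) / rate
    x = np.zeros(n)
    x[np.diff(np.floor(phase), prepend=0.0) > 0] = 0.8
    return Waveform(x, rate)


class TestSpectrogram:
    def test_pure_tone_ridge(self):
        spec = stft_spectrogram(_tone(1000.0))
        bin_width = spec.freqs[1] - spec.freqs[0]
        peak_freqs = spec.freqs[np.argmax(spec.magnitude, axis=0)]
        assert np.all(np.abs(peak_freqs - 1000.0) <= bin_width)

    def test_default_params(self):
        params = SpectrogramParams()
        assert params.window_length == 0.005
        assert params.display_range == (0.0, 4000.0)
        spec = stft_spectrogram(_tone(), params)
        assert spec.display().freqs.max() <= 4000.0

    def test_parseval_per_frame(self, rng):
        x = rng.standard_normal(4000)
        w = Waveform(x / np.abs(x).max(), RATE)
        params = SpectrogramParams(window="hann", hop=0.005)
        spec = stft_spectrogram(w, params)
        nperseg = int(round(params.window_length * RATE))
        hop = int(round(params.hop * RATE))
        win = np.hanning(nperseg + 1)[:-1]  # periodic hann, matches get_window
        for j in (0, 3, 7):
            seg = w.samples[j * hop:j * hop + nperseg] * win
            direct = np.sum(seg**2)
            X = spec.magnitude[:, j] ** 2
            spectral = (X[0] + 2 * X[1:-1].sum() + X[-1]) / nperseg
            assert spectral == pytest.approx(direct, rel=1e-9)

    def test_linearity(self):
        w = _tone()
        a = stft_spectrogram(w).magnitude
        b = stft_spectrogram(w.scaled(2.0)).magnitude
        assert np.allclose(b, 2 * a)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            stft_spectrogram(Waveform(np.zeros(10), RATE))


class TestVoicing:
    def test_pulse_train_f0(self):
        track = detect_voicing(_pulse_train(150.0))
        assert track.voiced.mean() > 0.9
        assert np.nanmedian(track.f0) == pytest.approx(150.0, abs=2.0)

    def test_white_noise_unvoiced(self, rng):
        track = detect_voicing(Waveform(0.3 * rng.standard_normal(RATE // 2), RATE))
        assert track.voiced.mean() < 0.2

    def test_silence_unvoiced(self):
        track = detect_voicing(Waveform(np.zeros(RATE // 2), RATE))
        assert not track.any_voiced
        assert np.all(np.isnan(track.f0))


class TestFormants:
    def test_round_trip_two_resonators(self):
        w = synthesize_vowel(f0=220, formants=(800, 1900), bandwidths=(80, 120),
                             duration=0.5, seed=1)
        f1, f2 = track_formants(w).median_formants(2)
        assert f1 == pytest.approx(800, abs=40)
        assert f2 == pytest.approx(1900, abs=95)

    def test_single_resonator(self):
        w = synthesize_vowel(f0=150, formants=(500,), bandwidths=(80,),
                             duration=0.4, seed=2)
        (f1,) = track_formants(w).median_formants(1)
        assert f1 == pytest.approx(500, abs=25)

    def test_white_noise_flagged_unreliable(self, rng):
        est = estimate_formants(Waveform(0.2 * rng.standard_normal(2000), RATE))
        assert not est.reliable and est.frequencies == ()

    def test_silence_flagged_unreliable(self):
        est = estimate_formants(Waveform(np.zeros(2000), RATE))
        assert not est.reliable

    def test_recovery_grid(self):
        """>= 95% of a seeded two-resonator grid recovered within 5%."""
        hits, total = 0, 0
        for f1 in (300, 600, 900):
            for f2 in (900, 1600, 2500):
                if f2 < f1 + 300:
                    continue
                w = synthesize_vowel(f0=170, formants=(f1, f2), bandwidths=(80, 120),
                                     duration=0.35, seed=5)
                e1, e2 = track_formants(w).median_formants(2)
                total += 1
                hits += abs(e1 - f1) / f1 < 0.05 and abs(e2 - f2) / f2 < 0.05
        assert hits / total >= 0.95


class TestClosure:
    def test_full_closure_is_stop_like(self):
        w = synthesize_utterance(UtteranceSynthSpec(closure_completeness=1.0, seed=3))
        profile = closure_abruptness(w)
        assert profile and all(e.label == "stop_like" for e in profile.events)

    def test_no_closure_is_glide_like(self):
        w = synthesize_utterance(UtteranceSynthSpec(closure_completeness=0.0, seed=3))
        profile = closure_abruptness(w)
        assert profile and all(e.label == "glide_like" for e in profile.events)

    def test_stationary_vowel_empty_profile(self):
        w = synthesize_vowel(duration=0.5, seed=4)
        assert not closure_abruptness(w)

    def test_monotone_in_closure_completeness(self):
        scores = []
        for c in (0.0, 0.25, 0.5, 0.75, 1.0):
            w = synthesize_utterance(UtteranceSynthSpec(closure_completeness=c, seed=11))
            scores.append(max(e.score for e in closure_abruptness(w).events))
        assert all(a < b for a, b in zip(scores, scores[1:]))


class TestMasking:
    def _snr_db(self, clean, masked):
        noise = masked.samples - clean.samples
        return 10 * np.log10(np.sum(clean.samples**2) / np.sum(noise**2))

    def test_requested_snr_realized(self):
        w = synthesize_vowel(duration=0.4, seed=6)
        for snr in (-6.0, 0.0, 12.0):
            masked = speech_shaped_noise_mask(w, snr, seed=7)
            assert self._snr_db(w, masked) == pytest.approx(snr, abs=0.5)

    def test_high_snr_limit_preserves_signal(self):
        w = synthesize_vowel(duration=0.3, seed=8)
        masked = speech_shaped_noise_mask(w, 60.0, seed=9)
        rel = np.linalg.norm(masked.samples - w.samples) / np.linalg.norm(w.samples)
        # exact-SNR scaling makes the relative L2 error equal 10^(-60/20)
        assert rel <= 1e-3 * (1 + 1e-9)

    def test_masker_matches_signal_spectrum_per_octave(self):
        w = synthesize_vowel(duration=0.5, seed=10)
        masked = speech_shaped_noise_mask(w, 0.0, seed=11)
        noise = masked.samples - w.samples
        sig_spec = np.abs(rfft(w.samples)) ** 2
        noise_spec = np.abs(rfft(noise)) ** 2
        freqs = np.fft.rfftfreq(len(noise), 1 / RATE)
        ratios = []
        for lo in (250, 500, 1000, 2000):
            band = (freqs >= lo) & (freqs < 2 * lo)
            ratios.append(noise_spec[band].sum() / sig_spec[band].sum())
        ratios_db = 10 * np.log10(ratios)
        # flat masker-to-signal ratio across octave bands = matched shape
        assert ratios_db.max() - ratios_db.min() < 6.0

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError, match="silent|SNR"):
            speech_shaped_noise_mask(Waveform(np.zeros(1000), RATE), 0.0)
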