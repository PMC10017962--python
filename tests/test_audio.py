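"""Pre-processing and contour/segmentation primitives on known synthesis."""

import numpy as np
import pytest

from robustmark import acoustic, audio
from robustmark.audio import Segmentation, Waveform

from conftest import harmonic


class TestResample:
    def test_length_arithmetic(self):
        w = Waveform(np.random.default_rng(0).standard_normal(48000) * 0.1, 48000)
        out = audio.resample(w, 16000)
        assert out.rate == 16000
        assert len(out.samples) == 16000

    def test_identity_at_target_rate(self):
        w = Waveform(harmonic(0.5), 16000)
        out = audio.resample(w, 16000)
        assert np.array_equal(out.samples, w.samples)

    def test_tone_frequency_preserved(self):
        t = np.arange(44100) / 44100
        w = Waveform(np.sin(2 * np.pi * 440 * t) * 0.5, 44100)
        out = audio.resample(w, 16000)
        freqs = np.fft.rfftfreq(len(out.samples), 1 / 16000)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(out.samples)))]
        assert abs(peak - 440.0) < 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            audio.resample(Waveform(np.array([]), 16000), 8000)


class TestLoudnessNormalization:
    def test_scale_invariance(self):
        w = Waveform(harmonic(1.0), 16000)
        scaled = Waveform(w.samples * 0.1, 16000)
        a = audio.normalize_loudness(w, -23.0)
        b = audio.normalize_loudness(scaled, -23.0)
        assert np.allclose(a.samples, b.samples)

    def test_idempotence(self):
        w = Waveform(harmonic(1.0), 16000)
        once = audio.normalize_loudness(w, -23.0)
        twice = audio.normalize_loudness(once, -23.0)
        assert np.allclose(once.samples, twice.samples, atol=1e-6)

    def test_white_noise_hits_target(self):
        rng = np.random.default_rng(0)
        w = Waveform(rng.standard_normal(32000) * 0.05, 16000)
        out = audio.normalize_loudness(w, -40.0)
        assert abs(audio._integrated_loudness(out) + 40.0) < 0.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            audio.normalize_loudness(Waveform(np.zeros(16000), 16000), -23.0)


class TestConcatenateTdu:
    def test_leading_silence_trimmed(self):
        rec = Waveform(np.concatenate([np.zeros(8000), harmonic(1.0)]), 16000)
        out = audio.concatenate_tdu([rec])
        assert rec.duration - out.duration >= 0.45

    def test_no_edge_silence_keeps_length(self):
        recs = [Waveform(harmonic(0.8), 16000), Waveform(harmonic(0.6), 16000)]
        out = audio.concatenate_tdu(recs)
        total = sum(len(r.samples) for r in recs)
        assert abs(len(out.samples) - total) <= 16000 * 0.06

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            audio.concatenate_tdu([])

    def test_rate_mismatch_rejected(self):
        with pytest.raises(ValueError):
            audio.concatenate_tdu(
                [Waveform(harmonic(0.5), 16000), Waveform(np.ones(100) * 0.1, 8000)]
            )


class TestF0Contour:
    def test_constant_tone(self, constant_tone):
        c = audio.f0_contour(constant_tone)
        assert abs(np.nanmean(c.valid_values) - 150.0) < 2.0
        assert acoustic.contour_std(c) < 2.0

    def test_silence_all_unvoiced(self):
        c = audio.f0_contour(Waveform(np.zeros(16000), 16000))
        assert not c.voiced.any()

    def test_linear_ramp_sd(self):
        # F0 rising 120 -> 180 Hz over 1 s: SD of a uniform ramp = 60/sqrt(12)
        rate = 16000
        t = np.arange(rate) / rate
        f = 120.0 + 60.0 * t
        phase = 2 * np.pi * np.cumsum(f) / rate
        w = Waveform(np.sin(phase) * 0.2, rate)
        sd = acoustic.contour_std(audio.f0_contour(w))
        assert abs(sd - 60.0 / np.sqrt(12)) < 2.0

    def test_amplitude_scaling_invariance(self, constant_tone):
        sd1 = acoustic.contour_std(audio.f0_contour(constant_tone))
        scaled = Waveform(constant_tone.samples * 0.05, 16000)
        sd2 = acoustic.contour_std(audio.f0_contour(scaled))
        assert abs(sd1 - sd2) < 0.1

    def test_bad_range_rejected(self, constant_tone):
        with pytest.raises(ValueError):
            audio.f0_contour(constant_tone, floor=400, ceiling=60)


class TestIntensityContour:
    def test_constant_tone_flat(self, constant_tone):
        assert acoustic.contour_std(audio.intensity_contour(constant_tone)) < 0.5

    def test_doubling_adds_6db(self, constant_tone):
        c1 = audio.intensity_contour(constant_tone)
        c2 = audio.intensity_contour(Waveform(constant_tone.samples * 2, 16000))
        shift = c2.valid_values - c1.values[c2.voiced]
        assert np.allclose(shift, 20 * np.log10(2), atol=0.01)

    def test_two_level_sd(self):
        x = np.concatenate([np.ones(16000) * 0.1, np.ones(16000) * 0.2])
        sd = acoustic.contour_std(audio.intensity_contour(Waveform(x, 16000)))
        assert abs(sd - 20 * np.log10(2) / 2) < 0.15

    def test_scaling_leaves_sd_unchanged(self):
        # why loudness normalization cannot affect INTSTD
        rng = np.random.default_rng(1)
        x = harmonic(1.0) * (1 + 0.3 * np.sin(2 * np.pi * 3 * np.arange(16000) / 16000))
        sd1 = acoustic.contour_std(audio.intensity_contour(Waveform(x, 16000)))
        sd2 = acoustic.contour_std(audio.intensity_contour(Waveform(x * 7.3, 16000)))
        assert abs(sd1 - sd2) < 1e-9


class TestF1Contour:
    @staticmethod
    def _resonated(f1=500.0, f0=120.0, duration=1.5):
        import scipy.signal

        rate = 16000
        x = harmonic(duration, f0=f0, amp=1.0)
        r = np.exp(-np.pi * 120.0 / rate)
        th = 2 * np.pi * f1 / rate
        y = scipy.signal.lfilter([1 - r], [1, -2 * r * np.cos(th), r * r], x)
        return Waveform(y * 0.1, rate)

    def test_single_resonator_recovered(self):
        w = self._resonated(500.0)
        f0c = audio.f0_contour(w)
        f1c = audio.f1_contour(w, f0c)
        assert abs(np.nanmedian(f1c.valid_values) - 500.0) < 50.0
        assert acoustic.contour_std(f1c) < 30.0

    def test_silence_empty_contour(self):
        w = Waveform(np.zeros(16000), 16000)
        f0c = audio.f0_contour(w)
        f1c = audio.f1_contour(w, f0c)
        assert not f1c.voiced.any()


class TestVad:
    def test_known_boundaries(self, speech_pause_speech):
        seg = audio.detect_speech_pauses(speech_pause_speech)
        expected = [(0.0, 2.0, "speech"), (2.0, 3.0, "pause"), (3.0, 5.0, "speech")]
        assert len(seg.intervals) == 3
        for (s, e, lab), (es, ee, elab) in zip(seg.intervals, expected):
            assert lab == elab
            assert abs(s - es) <= 0.05 and abs(e - ee) <= 0.05

    def test_continuous_tone_single_interval(self, constant_tone):
        seg = audio.detect_speech_pauses(constant_tone)
        assert [lab for _, _, lab in seg.intervals] == ["speech"]

    def test_short_pause_smoothed_away(self):
        rate = 16000
        y = np.concatenate([harmonic(1.0), np.zeros(int(0.1 * rate)), harmonic(1.0)])
        seg = audio.detect_speech_pauses(Waveform(y, rate), min_pause=0.15)
        assert "pause" not in [lab for _, _, lab in seg.intervals]

    def test_intervals_tile_duration(self, speech_pause_speech):
        seg = audio.detect_speech_pauses(speech_pause_speech)
        assert seg.intervals[0][0] == 0.0
        for (s1, e1, _), (s2, e2, _) in zip(seg.intervals, seg.intervals[1:]):
            assert e1 == s2
        assert np.isclose(seg.intervals[-1][1], seg.total_duration)
        speech = seg.durations("speech").sum()
        pause = seg.durations("pause").sum()
        assert np.isclose(speech + pause, seg.total_duration)

    def test_deterministic(self, speech_pause_speech):
        a = audio.detect_speech_pauses(speech_pause_speech)
        b = audio.detect_speech_pauses(speech_pause_speech)
        assert a.intervals == b.intervals


class TestSegmentationType:
    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError):
            Segmentation([(0.0, 1.0, "speech"), (1.5, 2.0, "pause")], 2.0)

    def test_tsv_round_trip(self, tmp_path):
        seg = Segmentation(
            [(0.0, 1.25, "speech"), (1.25, 2.0, "pause"), (2.0, 3.5, "speech")], 3.5
        )
        path = tmp_path / "seg.tsv"
        seg.to_tsv(path)
        back = Segmentation.from_tsv(path)
        assert back.intervals == seg.intervals
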