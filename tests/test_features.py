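"""Acoustic feature extraction: oracles, hand computations, invariants."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from bulbarvoice import (
    VoiceSpec,
    corrupt_audio,
    extract_features,
    synthesize_voice,
)
from bulbarvoice.audio import AudioRecording
from bulbarvoice.features import (
    PulseSequence,
    SegmentationResult,
    extract_pulses,
    harmonicity_metrics,
    intensity_metrics,
    jitter_metrics,
    segment_speech_pauses,
    shimmer_metrics,
    timing_rate_metrics,
    track_f0,
    zcr_metrics,
)

from conftest import FS, make_tone


def pulse_sequence(periods, amplitudes=None):
    periods = np.asarray(periods, dtype=float)
    times = 0.01 + np.concatenate([[0.0], np.cumsum(periods)])
    amps = np.ones_like(times) if amplitudes is None else np.asarray(amplitudes, float)
    return PulseSequence(times, amps, np.zeros(times.size, dtype=int))


# direct evaluations of the perturbation-quotient definitions (oracles)

def oracle_rap(T):
    T = np.asarray(T, float)
    devs = [abs(T[i] - (T[i - 1] + T[i] + T[i + 1]) / 3) for i in range(1, len(T) - 1)]
    return 100.0 * np.mean(devs) / np.mean(T)


def oracle_ddp(T):
    T = np.asarray(T, float)
    d = [abs((T[i + 1] - T[i]) - (T[i] - T[i - 1])) for i in range(1, len(T) - 1)]
    return 100.0 * np.mean(d) / np.mean(T)


def oracle_apq3(A):
    A = np.asarray(A, float)
    devs = [abs(A[i] - (A[i - 1] + A[i] + A[i + 1]) / 3) for i in range(1, len(A) - 1)]
    return 100.0 * np.mean(devs) / np.mean(A)


def oracle_dda(A):
    A = np.asarray(A, float)
    d = [abs((A[i + 1] - A[i]) - (A[i] - A[i - 1])) for i in range(1, len(A) - 1)]
    return 100.0 * np.mean(d) / np.mean(A)


class TestF0Tracking:
    @pytest.mark.parametrize("f0", [100.0, 150.0, 300.0])
    def test_known_f0_within_1pct(self, f0):
        rec = synthesize_voice(VoiceSpec(f0_hz=f0, duration_s=1.0,
                                         sample_rate_hz=FS, seed=2))
        contour = track_f0(rec)
        med = np.nanmedian(contour.f0_hz)
        assert abs(med - f0) / f0 < 0.01

    def test_silence_has_no_voiced_frames(self):
        rec = AudioRecording(np.zeros(FS), FS)
        assert track_f0(rec).n_voiced == 0

    def test_glide_is_monotone(self):
        """Linear 100 -> 300 Hz glide tracks monotonically with time."""
        fs = FS
        t = np.arange(2 * fs) / fs
        phase = 2 * np.pi * (100 * t + 50 * t**2)  # f(t) = 100 + 100 t
        rec = AudioRecording(0.5 * np.sin(phase), fs)
        c = track_f0(rec)
        v = c.voiced
        rho = spearmanr(c.times_s[v], c.f0_hz[v]).statistic
        assert rho > 0.95


class TestPulses:
    def test_periods_and_count(self, clean_voice):
        contour = track_f0(clean_voice)
        p = extract_pulses(clean_voice, contour)
        assert np.all(np.abs(p.periods - 1 / 150) < 0.02 / 150)
        assert abs(p.times_s.size - 150) <= 3

    def test_unvoiced_input_gives_none(self):
        rng = np.random.default_rng(0)
        rec = AudioRecording(np.clip(0.3 * rng.standard_normal(FS), -1, 1), FS)
        assert extract_pulses(rec, track_f0(rec)) is None


class TestJitterShimmer:
    def test_constant_sequences_give_zero(self):
        p = pulse_sequence([0.01] * 30)
        # tolerance covers float accumulation in the constructed times
        assert all(abs(v) < 1e-9 for v in jitter_metrics(p).values())
        assert all(abs(v) < 1e-9 for v in shimmer_metrics(p).values())

    def test_alternating_periods_hand_value(self):
        p = pulse_sequence([0.010, 0.011] * 10)
        # mean |dT| / mean T = 0.001 / 0.0105
        assert jitter_metrics(p)["local"] == pytest.approx(100 * 0.001 / 0.0105, rel=1e-6)

    def test_alternating_amplitudes_hand_value(self):
        n = 21
        amps = np.where(np.arange(n) % 2 == 0, 1.0, 0.9)
        p = pulse_sequence([0.01] * (n - 1), amps)
        assert shimmer_metrics(p)["local"] == pytest.approx(100 * 0.1 / 0.95, rel=1e-2)

    def test_identities_match_oracles(self):
        """ddp = 3 rap and dda = 3 apq3, against direct formula evaluation."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(6, 40)
            T = 0.01 * (1 + 0.1 * rng.random(n))
            A = 1 + 0.3 * rng.random(n + 1)
            p = pulse_sequence(T, A)
            jm, sm = jitter_metrics(p), shimmer_metrics(p)
            assert jm["ddp"] == pytest.approx(3 * jm["rap"], abs=1e-10)
            assert sm["dda"] == pytest.approx(3 * sm["apq3"], abs=1e-10)
            assert jm["rap"] == pytest.approx(oracle_rap(T), abs=1e-10)
            assert jm["ddp"] == pytest.approx(oracle_ddp(T), abs=1e-10)
            assert sm["apq3"] == pytest.approx(oracle_apq3(A), abs=1e-10)
            assert sm["dda"] == pytest.approx(oracle_dda(A), abs=1e-10)

    def test_too_few_pulses_missing(self):
        assert np.isnan(jitter_metrics(None)["local"])
        assert np.isnan(shimmer_metrics(None)["apq11"])


class TestHarmonicity:
    def test_clean_voice_high_hnr(self, clean_voice):
        h = harmonicity_metrics(clean_voice, track_f0(clean_voice))
        assert h["hnr_mean"] > 30.0
        assert h["ac_mean"] > 0.99

    def test_hnr_tracks_snr(self):
        values = []
        for snr in (20.0, 10.0, 0.0):
            rec = synthesize_voice(VoiceSpec(f0_hz=150, duration_s=1.0,
                                             noise_snr_db=snr,
                                             sample_rate_hz=FS, seed=2))
            h = harmonicity_metrics(rec, track_f0(rec))
            values.append(h["hnr_mean"])
        assert abs(values[1] - 10.0) <= 3.0
        assert values[0] > values[1] > values[2]


class TestIntensity:
    def test_constant_tone_low_variance(self):
        rec = make_tone(200.0, 1.0)
        m = intensity_metrics(rec)
        assert m["var"] < 0.1
        assert m["min"] <= m["median"] <= m["max"]

    def test_doubling_adds_6db(self, clean_voice):
        quiet = clean_voice.with_samples(0.25 * clean_voice.samples)
        m1 = intensity_metrics(quiet)
        louder = quiet.with_samples(2 * quiet.samples)
        m2 = intensity_metrics(louder)
        assert m2["mean"] - m1["mean"] == pytest.approx(20 * np.log10(2), abs=0.1)


class TestZcr:
    def test_sine_rate(self):
        rec = make_tone(100.0, 1.0, fs=44100)
        m = zcr_metrics(rec)
        assert m["mean"] * 44100 == pytest.approx(200.0, rel=0.02)

    def test_constant_positive_zero(self):
        rec = AudioRecording(0.5 * np.ones(FS), FS)
        assert zcr_metrics(rec)["mean"] == 0.0

    def test_iid_noise_half(self):
        rng = np.random.default_rng(1)
        rec = AudioRecording(np.clip(0.2 * rng.standard_normal(2 * FS), -1, 1), FS)
        assert zcr_metrics(rec)["mean"] == pytest.approx(0.5, abs=0.02)


class TestSegmentation:
    def test_constructed_pause_recovered(self):
        """Speech 0-0.5, silence 0.5-0.9, speech 0.9-1.5."""
        fs = FS
        rng = np.random.default_rng(0)
        x = 0.4 * np.sin(2 * np.pi * 200 * np.arange(int(1.5 * fs)) / fs)
        x *= 1 + 0.05 * rng.standard_normal(x.size)
        x[int(0.5 * fs): int(0.9 * fs)] = 0.0
        seg = segment_speech_pauses(AudioRecording(np.clip(x, -1, 1), fs))
        assert len(seg.pause_segments) == 1
        s, e = seg.pause_segments[0]
        assert (e - s) == pytest.approx(0.40, abs=0.02)

    def test_short_dip_not_a_pause(self):
        fs = FS
        x = 0.4 * np.sin(2 * np.pi * 200 * np.arange(fs) / fs)
        x[int(0.5 * fs): int(0.5 * fs) + int(0.10 * fs)] = 0.0  # 0.10 s dip
        seg = segment_speech_pauses(AudioRecording(x, fs))
        assert len(seg.pause_segments) == 0

    def test_all_silence(self):
        seg = segment_speech_pauses(AudioRecording(np.zeros(FS), FS))
        assert len(seg.speech_segments) == 0


class TestTimingRates:
    def test_rate_arithmetic(self):
        seg = SegmentationResult(
            speech_segments=((0.0, 2.0),),
            pause_segments=((2.0, 2.5),),
            syllable_times_s=tuple(np.linspace(0.1, 1.9, 10)),
            total_duration_s=2.5,
        )
        m = timing_rate_metrics(seg)
        assert m["speech_rate"] == pytest.approx(4.0)
        assert m["articulation_rate"] == pytest.approx(5.0)
        assert m["phonation_ratio"] == pytest.approx(0.8)

    def test_pause_classes(self):
        seg = SegmentationResult(
            speech_segments=((0.0, 1.0), (1.3, 2.0), (2.7, 3.0), (4.2, 5.0)),
            pause_segments=((1.0, 1.3), (2.0, 2.7), (3.0, 4.2)),
            syllable_times_s=(0.5,),
            total_duration_s=5.0,
        )
        m = timing_rate_metrics(seg)
        assert (m["pause_ct_short"], m["pause_ct_med"], m["pause_ct_long"]) == (1, 1, 1)
        assert m["pause_dur_mean"] == pytest.approx((0.3 + 0.7 + 1.2) / 3, abs=1e-9)

    def test_no_pauses(self):
        seg = SegmentationResult(
            speech_segments=((0.0, 2.0),),
            pause_segments=(),
            syllable_times_s=(0.5, 1.0),
            total_duration_s=2.0,
        )
        m = timing_rate_metrics(seg)
        assert m["pause_dur_total"] == 0.0
        assert m["pause_ct"] == 0.0
        assert m["pause_ct_short"] == m["pause_ct_med"] == m["pause_ct_long"] == 0.0


class TestExtractFeatures:
    def test_exactly_53_values_and_deterministic(self, paused_voice, manifest):
        fv1 = extract_features(paused_voice)
        fv2 = extract_features(paused_voice)
        assert tuple(fv1.values) == manifest.names
        assert len(fv1.values) == 53
        assert fv1.values == fv2.values

    def test_whispered_input_splits_missing(self):
        """Unvoiced (noise-burst) input: phonatory missing, timing present."""
        fs = FS
        rng = np.random.default_rng(3)
        x = 0.3 * rng.standard_normal(2 * fs)
        x[int(0.8 * fs): int(1.2 * fs)] = 0.0
        fv = extract_features(AudioRecording(np.clip(x, -1, 1), fs))
        assert np.isnan(fv.values["jitter_local"])
        assert np.isnan(fv.values["f0_mean"])
        assert np.isfinite(fv.values["pause_dur_total"])
        assert np.isfinite(fv.values["speech_dur_total"])

    def test_scale_invariance(self, clean_voice, manifest):
        """Halving the waveform changes only intensity (by -20 log10 2 dB)."""
        fv1 = extract_features(clean_voice)
        quieter = clean_voice.with_samples(0.5 * clean_voice.samples)
        fv2 = extract_features(quieter)
        shift = 20 * np.log10(0.5)
        for name in manifest.names:
            a, b = fv1.values[name], fv2.values[name]
            if not np.isfinite(a):
                assert not np.isfinite(b)
            elif name.startswith("int_") and name not in (
                "int_range", "int_var", "int_sd"
            ):
                assert b - a == pytest.approx(shift, abs=0.05)
            else:
                assert b == pytest.approx(a, rel=1e-4, abs=1e-6)
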