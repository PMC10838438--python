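"""Extraction of the 53-feature acoustic set from one recording.

The feature set spans the three physiologic speech subsystems assessed in
motor-speech examination: phonatory (jitter, shimmer, harmonicity, F0),
respiratory (intensity, pause structure) and articulatory (speech/pause
timing, syllable rates, zero-crossing behaviour). Values that cannot be
measured on a given recording (e.g. perturbation quotients on unvoiced
audio) are returned as NaN and imputed downstream with training-split
medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, find_peaks

from .audio import AudioRecording
from .manifest import FeatureManifest, load_manifest
from .preprocess import activity_mask

__all__ = [
    "F0Contour",
    "PulseSequence",
    "SegmentationResult",
    "FeatureVector",
    "track_f0",
    "extract_pulses",
    "jitter_metrics",
    "shimmer_metrics",
    "harmonicity_metrics",
    "intensity_metrics",
    "zcr_metrics",
    "segment_speech_pauses",
    "timing_rate_metrics",
    "extract_features",
]

# pitch-tracker configuration (standard connected-speech settings)
F0_MIN_HZ = 75.0
F0_MAX_HZ = 500.0
F0_WINDOW_S = 0.040
F0_HOP_S = 0.010
VOICING_THRESHOLD = 0.45
OCTAVE_COST = 0.02        # per octave of lag, breaks period-multiple ties

FRAME_S = 0.010           # energy/intensity/ZCR frame length
MIN_PAUSE_S = 0.15
PAUSE_CLASS_BOUNDS_S = (0.5, 1.0)   # short < 0.5 <= medium < 1.0 <= long
SYLLABLE_PROMINENCE_DB = 2.0
HNR_CAP_DB = 60.0


@dataclass(frozen=True)
class F0Contour:
    """Per-frame pitch track: NaN F0 marks unvoiced frames."""

    times_s: np.ndarray
    f0_hz: np.ndarray          # NaN where unvoiced
    periodicity: np.ndarray    # normalized autocorrelation at the F0 lag

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0_hz)

    @property
    def n_voiced(self) -> int:
        return int(np.sum(self.voiced))


@dataclass(frozen=True)
class PulseSequence:
    """Glottal-cycle marks: times, per-cycle amplitudes, and run labels.

    ``run_ids`` groups pulses into contiguous voiced stretches; periods are
    only defined between successive pulses of the same run.
    """

    times_s: np.ndarray
    amplitudes: np.ndarray
    run_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("pulse amplitudes must be positive")

    @property
    def periods(self) -> np.ndarray:
        """Inter-pulse intervals within runs (cross-run gaps excluded)."""
        same = self.run_ids[1:] == self.run_ids[:-1]
        return np.diff(self.times_s)[same]

    def period_runs(self) -> list[np.ndarray]:
        """Period sequences per contiguous voiced run."""
        out = []
        for rid in np.unique(self.run_ids):
            t = self.times_s[self.run_ids == rid]
            if t.size >= 2:
                out.append(np.diff(t))
        return out

    def amplitude_runs(self) -> list[np.ndarray]:
        return [self.amplitudes[self.run_ids == rid] for rid in np.unique(self.run_ids)]


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-bin position and value of a local maximum via parabolic fit."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:
        return float(i), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    val = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return i + delta, float(val)


def track_f0(rec: AudioRecording) -> F0Contour:
    """Autocorrelation pitch tracking on 40 ms frames with 10 ms hop.

    The normalized autocorrelation r(tau) = sum x_t x_{t+tau} /
    sqrt(sum x_t^2 * sum x_{t+tau}^2) is maximized over lags in the
    75-500 Hz search range with a small per-octave lag cost to break
    period-multiple ties; the peak is refined parabolically. A frame is
    voiced when its refined peak exceeds 0.45 and the frame carries energy.
    """
    fs = rec.sample_rate_hz
    x = rec.samples
    win = int(round(F0_WINDOW_S * fs))
    hop = int(round(F0_HOP_S * fs))
    lag_min = max(int(np.floor(fs / F0_MAX_HZ)), 2)
    lag_max = int(np.ceil(fs / F0_MIN_HZ))
    n_frames = max((x.size - win - lag_max) // hop + 1, 0)

    powers = np.array([
        np.mean(x[i * hop: i * hop + win] ** 2) for i in range(n_frames)
    ]) if n_frames else np.array([])
    p_ref = np.max(powers) if powers.size else 0.0
    octave_pen = OCTAVE_COST * np.log2(
        np.arange(lag_min, lag_max + 1) / float(lag_min)
    )

    times = np.empty(n_frames)
    f0 = np.full(n_frames, np.nan)
    periodicity = np.zeros(n_frames)
    for i in range(n_frames):
        start = i * hop
        times[i] = (start + win / 2.0) / fs
        if p_ref <= 0 or powers[i] < 1e-8 * p_ref:
            continue
        seg = x[start: start + win]
        ext = x[start: start + win + lag_max]
        # num[tau] = sum_t seg[t] * ext[t + tau]
        num = fftconvolve(ext, seg[::-1])[win - 1: win - 1 + lag_max + 1]
        cs = np.concatenate([[0.0], np.cumsum(ext**2)])
        energy = cs[win:] - cs[:-win]          # energy of ext[tau : tau+win]
        denom = np.sqrt(energy[0] * energy)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / denom, 0.0)
        r_band = r[lag_min: lag_max + 1]
        score = r_band - octave_pen
        j = int(np.argmax(score))
        lag, r_peak = _parabolic_refine(r_band, j)
        if r_peak >= VOICING_THRESHOLD:
            f0[i] = fs / (lag + lag_min)
            periodicity[i] = min(r_peak, 1.0)
    return F0Contour(times, f0, periodicity)


def extract_pulses(rec: AudioRecording, contour: F0Contour) -> PulseSequence | None:
    """Mark glottal cycles at waveform peaks spaced by the tracked period.

    Peak times and amplitudes are refined by parabolic interpolation for
    sub-sample accuracy, without which sub-0.1% jitter would be swamped by
    sample-grid quantization. Returns None when fewer than 3 pulses are
    found (perturbation features are then missing).
    """
    fs = rec.sample_rate_hz
    x = rec.samples
    voiced = contour.voiced
    if int(voiced.sum()) < 3:
        return None
    # contiguous voiced frame runs
    edges = np.flatnonzero(np.diff(voiced.astype(int)))
    bounds = np.concatenate([[0], edges + 1, [voiced.size]])
    times, amps, rids = [], [], []
    rid = 0
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if not voiced[b0] or b1 - b0 < 2:
            continue
        t0 = contour.times_s[b0] - F0_WINDOW_S / 2.0
        t1 = contour.times_s[b1 - 1] + F0_WINDOW_S / 2.0
        i0, i1 = max(int(t0 * fs), 0), min(int(t1 * fs), x.size)
        region = x[i0:i1]
        if region.size == 0:
            continue
        period = fs / float(np.nanmedian(contour.f0_hz[b0:b1]))
        peaks, _ = find_peaks(
            region,
            distance=max(int(0.7 * period), 1),
            height=0.2 * np.max(region) if np.max(region) > 0 else None,
        )
        if peaks.size < 3:
            continue
        for p in peaks:
            pos, amp = _parabolic_refine(region, int(p))
            if amp > 0:
                times.append((i0 + pos) / fs)
                amps.append(amp)
                rids.append(rid)
        rid += 1
    if len(times) < 3:
        return None
    t = np.asarray(times)
    a = np.asarray(amps)
    r = np.asarray(rids)
    order = np.argsort(t)
    t, a, r = t[order], a[order], r[order]
    keep = np.concatenate([[True], np.diff(t) > 0])
    return PulseSequence(t[keep], a[keep], r[keep])


def _windowed_deviation(runs: list[np.ndarray], width: int) -> np.ndarray:
    """|x_i - mean of the width-point window centred on i|, within runs."""
    half = width // 2
    out = []
    for v in runs:
        for i in range(half, v.size - half):
            out.append(abs(v[i] - np.mean(v[i - half: i + half + 1])))
    return np.asarray(out)


def _abs_diff(runs: list[np.ndarray], order: int) -> np.ndarray:
    out = []
    for v in runs:
        if v.size > order:
            out.append(np.abs(np.diff(v, n=order)))
    return np.concatenate(out) if out else np.array([])


def jitter_metrics(p: PulseSequence | None) -> dict[str, float]:
    """Cycle-to-cycle period perturbation measures (percent, abs in s).

    local = mean|T_i - T_{i+1}| / mean(T); rap and ppq5 are the 3- and
    5-point perturbation quotients; ddp is the mean absolute second
    difference of periods over mean(T) (algebraically 3 x rap).
    """
    nan = {k: np.nan for k in ("local", "local_abs", "rap", "ppq5", "ddp")}
    if p is None:
        return nan
    runs = p.period_runs()
    periods = p.periods
    if periods.size < 2:
        return nan
    mean_t = float(np.mean(periods))
    d1 = _abs_diff(runs, 1)
    out = dict(nan)
    if d1.size:
        out["local"] = 100.0 * float(np.mean(d1)) / mean_t
        out["local_abs"] = float(np.mean(d1))
    w3 = _windowed_deviation(runs, 3)
    if w3.size:
        out["rap"] = 100.0 * float(np.mean(w3)) / mean_t
    w5 = _windowed_deviation(runs, 5)
    if w5.size:
        out["ppq5"] = 100.0 * float(np.mean(w5)) / mean_t
    d2 = _abs_diff(runs, 2)
    if d2.size:
        out["ddp"] = 100.0 * float(np.mean(d2)) / mean_t
    return out


def shimmer_metrics(p: PulseSequence | None) -> dict[str, float]:
    """Cycle-to-cycle amplitude perturbation measures.

    local and the apqN quotients are percentages of the mean amplitude;
    local_db is the mean absolute dB ratio of successive amplitudes;
    dda is the mean absolute second difference (3 x apq3).
    """
    keys = ("local", "local_db", "apq3", "apq5", "apq11", "dda")
    nan = {k: np.nan for k in keys}
    if p is None:
        return nan
    runs = [a for a in p.amplitude_runs() if a.size >= 2]
    if not runs:
        return nan
    amps = np.concatenate(runs)
    mean_a = float(np.mean(amps))
    out = dict(nan)
    d1 = _abs_diff(runs, 1)
    if d1.size:
        out["local"] = 100.0 * float(np.mean(d1)) / mean_a
        ratios = [20.0 * np.abs(np.log10(a[1:] / a[:-1])) for a in runs if a.size >= 2]
        out["local_db"] = float(np.mean(np.concatenate(ratios)))
    for name, width in (("apq3", 3), ("apq5", 5), ("apq11", 11)):
        w = _windowed_deviation(runs, width)
        if w.size:
            out[name] = 100.0 * float(np.mean(w)) / mean_a
    d2 = _abs_diff(runs, 2)
    if d2.size:
        out["dda"] = 100.0 * float(np.mean(d2)) / mean_a
    return out


def harmonicity_metrics(
    rec: AudioRecording, contour: F0Contour, pulses: PulseSequence | None = None
) -> dict[str, float]:
    """Harmonics-to-noise measures from the voiced frames.

    Per voiced frame, with r the normalized autocorrelation at the pitch
    lag: HNR = 10 log10(r / (1 - r)) capped at +-60 dB; ac_mean is the mean
    r; nhr_mean the mean (1 - r) / r; cc_mean the mean Pearson correlation
    of successive glottal cycles.
    """
    nan = {k: np.nan for k in ("hnr_mean", "hnr_sd", "ac_mean", "cc_mean", "nhr_mean")}
    if contour.n_voiced < 1:
        return nan
    r = np.clip(contour.periodicity[contour.voiced], 1e-6, 1.0 - 1e-6)
    hnr = np.clip(10.0 * np.log10(r / (1.0 - r)), -HNR_CAP_DB, HNR_CAP_DB)
    out = dict(nan)
    out["hnr_mean"] = float(np.mean(hnr))
    out["hnr_sd"] = float(np.std(hnr, ddof=1)) if hnr.size > 1 else 0.0
    out["ac_mean"] = float(np.mean(r))
    out["nhr_mean"] = float(np.mean((1.0 - r) / r))
    if pulses is None:
        pulses = extract_pulses(rec, contour)
    cc = _cycle_cross_correlations(rec, pulses)
    if cc.size:
        out["cc_mean"] = float(np.mean(cc))
    return out


def _cycle_cross_correlations(
    rec: AudioRecording, pulses: PulseSequence | None
) -> np.ndarray:
    if pulses is None:
        return np.array([])
    fs = rec.sample_rate_hz
    x = rec.samples
    vals = []
    for rid in np.unique(pulses.run_ids):
        t = pulses.times_s[pulses.run_ids == rid]
        for i in range(t.size - 1):
            n = int((t[i + 1] - t[i]) * fs)
            a0, b0 = int(t[i] * fs), int(t[i + 1] * fs)
            if n < 4 or b0 + n > x.size:
                continue
            c0, c1 = x[a0: a0 + n], x[b0: b0 + n]
            s0, s1 = np.std(c0), np.std(c1)
            if s0 > 0 and s1 > 0:
                vals.append(float(np.corrcoef(c0, c1)[0, 1]))
    return np.asarray(vals)


def _frame_view(x: np.ndarray, frame: int) -> np.ndarray:
    n = x.size // frame
    return x[: n * frame].reshape(n, frame)


def intensity_metrics(rec: AudioRecording) -> dict[str, float]:
    """Frame-RMS intensity statistics in dB re full scale (speech frames)."""
    keys = ("mean", "median", "min", "max", "range", "var", "sd")
    _, active = activity_mask(rec.samples, rec.sample_rate_hz)
    frame = int(round(FRAME_S * rec.sample_rate_hz))
    frames = _frame_view(rec.samples, frame)
    active = active[: frames.shape[0]]
    if not np.any(active):
        return {k: np.nan for k in keys}
    rms = np.sqrt(np.mean(frames[active] ** 2, axis=1))
    db = 20.0 * np.log10(np.maximum(rms, 1e-10))
    return {
        "mean": float(np.mean(db)),
        "median": float(np.median(db)),
        "min": float(np.min(db)),
        "max": float(np.max(db)),
        "range": float(np.max(db) - np.min(db)),
        "var": float(np.var(db)),
        "sd": float(np.std(db)),
    }


def zcr_metrics(rec: AudioRecording) -> dict[str, float]:
    """Zero-crossing rate per frame (sign changes / frame samples)."""
    frame = int(round(FRAME_S * rec.sample_rate_hz))
    x = rec.samples
    # sign changes over every sample gap (signbit treats exact zeros as
    # positive so a zero-valued sample on a crossing is counted once), then
    # binned into frames so boundary-straddling crossings are not dropped
    s = np.signbit(x)
    changes = (s[1:] != s[:-1]).astype(np.int64)
    n_frames = max(x.size // frame, 1)
    counts = np.bincount(
        np.minimum(np.arange(changes.size) // frame, n_frames - 1),
        weights=changes, minlength=n_frames,
    )
    rate = counts / frame
    return {"mean": float(np.mean(rate)), "var": float(np.var(rate))}


@dataclass(frozen=True)
class SegmentationResult:
    """Speech/pause tiling of a recording plus syllable-nucleus times."""

    speech_segments: tuple[tuple[float, float], ...]
    pause_segments: tuple[tuple[float, float], ...]
    syllable_times_s: tuple[float, ...]
    total_duration_s: float
    min_pause_s: float = MIN_PAUSE_S

    def __post_init__(self) -> None:
        segs = sorted(self.speech_segments + self.pause_segments)
        cursor = 0.0
        for s, e in segs:
            if abs(s - cursor) > 1e-9 or e <= s:
                raise ValueError("segments must tile [0, duration) without overlap")
            cursor = e
        if segs and abs(cursor - self.total_duration_s) > 1e-6:
            raise ValueError("segments must cover the full duration")

    @property
    def speech_time_s(self) -> float:
        return sum(e - s for s, e in self.speech_segments)

    @property
    def pause_durations_s(self) -> np.ndarray:
        return np.array([e - s for s, e in self.pause_segments])


def segment_speech_pauses(rec: AudioRecording) -> SegmentationResult:
    """Energy-based speech/pause segmentation with syllable nuclei.

    Pauses are sub-threshold frame runs of at least 0.15 s; shorter dips
    are absorbed into speech. Syllable nuclei are intensity-contour peaks
    of >= 2 dB prominence inside speech segments.
    """
    fs = rec.sample_rate_hz
    frame = int(round(FRAME_S * fs))
    powers, active = activity_mask(rec.samples, fs)
    n_frames = powers.size
    total = rec.samples.size / fs
    min_frames = int(round(MIN_PAUSE_S / FRAME_S))

    # long-enough inactive runs are pauses; everything else is speech
    is_pause = np.zeros(n_frames, dtype=bool)
    i = 0
    while i < n_frames:
        if not active[i]:
            j = i
            while j < n_frames and not active[j]:
                j += 1
            if j - i >= min_frames:
                is_pause[i:j] = True
            i = j
        else:
            i += 1

    def runs_to_intervals(mask: np.ndarray) -> list[tuple[float, float]]:
        iv, i = [], 0
        while i < mask.size:
            if mask[i]:
                j = i
                while j < mask.size and mask[j]:
                    j += 1
                start = i * FRAME_S
                end = total if j == mask.size else j * FRAME_S
                iv.append((start, end))
                i = j
            else:
                i += 1
        return iv

    pauses = runs_to_intervals(is_pause)
    speech = runs_to_intervals(~is_pause)
    if n_frames == 0:
        speech, pauses = [(0.0, total)], []

    db = 10.0 * np.log10(np.maximum(powers, 1e-12))
    peaks, _ = find_peaks(db, prominence=SYLLABLE_PROMINENCE_DB,
                          distance=max(int(0.1 / FRAME_S), 1))
    nuclei = [
        (p + 0.5) * FRAME_S
        for p in peaks
        if not is_pause[p] and active[p]
    ]
    return SegmentationResult(
        speech_segments=tuple(speech),
        pause_segments=tuple(pauses),
        syllable_times_s=tuple(nuclei),
        total_duration_s=total,
    )


def timing_rate_metrics(seg: SegmentationResult) -> dict[str, float]:
    """The 21 timing/rate features from a segmentation.

    Word-unit durations are speech-chunk durations (transcript alignment is
    out of scope, so chunks stand in for words); speech rate is syllables
    per second of total time, articulation rate per second of speech time.
    """
    total = seg.total_duration_s
    pauses = seg.pause_durations_s
    speech_durs = np.array([e - s for s, e in seg.speech_segments])
    speech_time = seg.speech_time_s
    n_syll = len(seg.syllable_times_s)
    lo, hi = PAUSE_CLASS_BOUNDS_S
    out: dict[str, float] = {
        "total_dur": total,
        "speech_dur_total": speech_time,
        "pause_dur_total": float(np.sum(pauses)) if pauses.size else 0.0,
        "pause_ct": float(pauses.size),
        "pause_ct_short": float(np.sum(pauses < lo)),
        "pause_ct_med": float(np.sum((pauses >= lo) & (pauses < hi))),
        "pause_ct_long": float(np.sum(pauses >= hi)),
        "pause_dur_mean": float(np.mean(pauses)) if pauses.size else 0.0,
        "pause_dur_median": float(np.median(pauses)) if pauses.size else 0.0,
        "pause_dur_var": float(np.var(pauses)) if pauses.size else 0.0,
        "pause_dur_max": float(np.max(pauses)) if pauses.size else 0.0,
        "pause_rate": float(pauses.size) / total if total > 0 else np.nan,
        "speech_seg_ct": float(speech_durs.size),
        "speech_seg_dur_median": float(np.median(speech_durs)) if speech_durs.size else 0.0,
        "speech_seg_dur_max": float(np.max(speech_durs)) if speech_durs.size else 0.0,
        "syllable_ct": float(n_syll),
        "word_dur_mean": float(np.mean(speech_durs)) if speech_durs.size else np.nan,
        "word_dur_var": float(np.var(speech_durs)) if speech_durs.size else np.nan,
    }
    if speech_time > 0 and total > 0:
        out["phonation_ratio"] = speech_time / total
        out["speech_rate"] = n_syll / total
        out["articulation_rate"] = n_syll / speech_time
    else:
        out["phonation_ratio"] = 0.0 if total > 0 else np.nan
        out["speech_rate"] = np.nan
        out["articulation_rate"] = np.nan
    return out


@dataclass(frozen=True)
class FeatureVector:
    """The 53 named acoustic measurements for one subject."""

    subject_id: str
    values: dict[str, float]
    manifest_version: str

    def __post_init__(self) -> None:
        manifest = load_manifest()
        if tuple(self.values) != manifest.names:
            raise ValueError("feature vector does not match the manifest")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id)

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.values.items() if not np.isfinite(v))


def extract_features(
    rec: AudioRecording, manifest: FeatureManifest | None = None
) -> FeatureVector:
    """Run every sub-extractor and assemble the manifest-ordered vector."""
    manifest = manifest or load_manifest()
    contour = track_f0(rec)
    pulses = extract_pulses(rec, contour)
    jit = jitter_metrics(pulses)
    shim = shimmer_metrics(pulses)
    harm = harmonicity_metrics(rec, contour, pulses)
    inten = intensity_metrics(rec)
    zcr = zcr_metrics(rec)
    seg = segment_speech_pauses(rec)
    timing = timing_rate_metrics(seg)

    f0v = contour.f0_hz[contour.voiced]
    if f0v.size:
        f0_stats = {
            "f0_mean": float(np.mean(f0v)),
            "f0_median": float(np.median(f0v)),
            "f0_min": float(np.min(f0v)),
            "f0_max": float(np.max(f0v)),
            "f0_range": float(np.max(f0v) - np.min(f0v)),
            "f0_var": float(np.var(f0v)),
            "f0_sd": float(np.std(f0v)),
        }
    else:
        f0_stats = {k: np.nan for k in (
            "f0_mean", "f0_median", "f0_min", "f0_max", "f0_range", "f0_var", "f0_sd")}

    raw = {
        **{f"jitter_{k}": v for k, v in jit.items()},
        **{f"shimmer_{k}": v for k, v in shim.items()},
        **harm,
        **f0_stats,
        **{f"int_{k}": v for k, v in inten.items()},
        **{f"zcr_{k}": v for k, v in zcr.items()},
        **timing,
    }
    values = {name: float(raw[name]) for name in manifest.names}
    return FeatureVector(rec.subject_id, values, manifest.version)
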