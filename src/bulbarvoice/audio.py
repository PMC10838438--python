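"""Core audio container and WAV I/O.

Recordings are held as float arrays normalized to [-1, 1] regardless of the
on-disk bit depth, mirroring how phonetics toolkits treat PCM audio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioRecording", "read_wav", "write_wav"]


@dataclass(frozen=True)
class AudioRecording:
    """One mono recording: samples in [-1, 1] plus sampling metadata."""

    samples: np.ndarray
    sample_rate_hz: int
    subject_id: str = ""
    bit_depth: int = 16  # provenance only; samples are float in memory

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise ValueError("samples must lie in [-1, 1]")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def with_samples(self, samples: np.ndarray) -> "AudioRecording":
        return replace(self, samples=samples)


def read_wav(path: str | Path, subject_id: str | None = None) -> AudioRecording:
    """Read a mono WAV file (16/24/32-bit PCM or float) into [-1, 1] floats."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples, bits = data / 32768.0, 16
    elif data.dtype == np.int32:
        samples, bits = data / 2147483648.0, 32
    elif data.dtype == np.uint8:
        samples, bits = (data.astype(np.float64) - 128.0) / 128.0, 8
    elif np.issubdtype(data.dtype, np.floating):
        samples, bits = np.clip(data.astype(np.float64), -1.0, 1.0), 32
    else:
        raise ValueError(f"{path}: unsupported WAV dtype {data.dtype}")
    sid = subject_id if subject_id is not None else Path(path).stem
    return AudioRecording(np.clip(samples, -1.0, 1.0), int(rate),
                          subject_id=sid, bit_depth=bits)


def write_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as mono 16-bit PCM WAV."""
    pcm = np.clip(np.round(rec.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), rec.sample_rate_hz, pcm)
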