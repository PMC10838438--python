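import numpy as np
import pytest

from bulbarvoice import VoiceSpec, synthesize_voice, load_manifest
from bulbarvoice.audio import AudioRecording

# 16 kHz keeps fixtures fast and puts the full noise bandwidth inside the
# 80 Hz - 10 kHz suppression band of the noise-reduction stage
FS = 16000


@pytest.fixture(scope="session")
def manifest():
    return load_manifest()


@pytest.fixture(scope="session")
def clean_voice():
    """Perfectly periodic 150 Hz vowel, 1 s."""
    return synthesize_voice(
        VoiceSpec(f0_hz=150.0, duration_s=1.0, sample_rate_hz=FS, seed=1)
    )


@pytest.fixture(scope="session")
def paused_voice():
    """2 s vowel with a scheduled 0.4 s pause at 0.5 s."""
    return synthesize_voice(
        VoiceSpec(f0_hz=150.0, duration_s=2.0, pause_schedule=((0.5, 0.4),),
                  sample_rate_hz=FS, seed=4)
    )


def make_tone(freq_hz: float, duration_s: float, fs: int = FS,
              amplitude: float = 0.5, lead_in_s: float = 0.0) -> AudioRecording:
    """Sine tone, optionally preceded by digital silence."""
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    x[: int(lead_in_s * fs)] = 0.0
    return AudioRecording(x, fs, subject_id=f"tone{freq_hz:g}")
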