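from __future__ import annotations

import numpy as np
import pytest

from moanscan import synthdata as sd
from moanscan.audio_core import compute_spectrogram


@pytest.fixture(scope="session")
def ref_template():
    """Canonical moan template cut from a clean synthetic recording."""
    return sd.reference_template()


@pytest.fixture(scope="session")
def moan_scene_10db(ref_template):
    """100 s scene with five moans injected at 10 dB in-band SNR.

    Returns (audio, annotations, spectrogram); the spectrogram is
    precomputed once with the template's parameters.
    """
    times = (5.0, 20.0, 42.0, 61.0, 83.0)
    spec = sd.SceneSpec(
        duration=100.0,
        schedule=tuple(sd.ScheduledCall(t, target_snr_db=10.0) for t in times),
        seed=7,
    )
    audio, annotations = sd.build_scene(spec)
    sgram = compute_spectrogram(audio, ref_template.params)
    return audio, annotations, sgram
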