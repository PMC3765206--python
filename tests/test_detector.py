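"""Template matching: normalization, peak logic, invariances, review flow."""

from __future__ import annotations

import math
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from moanscan import synthdata as sd
from moanscan.audio_core import (
    CalibratedAudio,
    SpectrogramParams,
    compute_spectrogram,
)
from moanscan.detector import (
    correlate,
    detect,
    events_from_csv,
    events_to_csv,
    extract_template,
    filter_verified,
    review_export,
    review_import,
)

T0 = datetime(2008, 4, 1, tzinfo=timezone.utc)


def test_template_row_count_matches_band_arithmetic(ref_template):
    """A 240 Hz band at 48 kHz / fft 4048 spans ceil(240 / (48000/4048)) = 21
    frequency rows."""
    bin_width = 48000.0 / 4048
    assert ref_template.patch.shape[0] == math.ceil(240.0 / bin_width) == 21


def test_template_is_normalized(ref_template):
    assert ref_template.patch.mean() == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.norm(ref_template.patch) == pytest.approx(1.0, rel=1e-9)


def test_self_correlation_peaks_at_unity_at_source_location():
    """Correlating a template against its own source spectrogram scores 1
    exactly at the excerpt's lag."""
    scene = sd.SceneSpec(
        duration=4.0, schedule=(sd.ScheduledCall(1.5, target_snr_db=20.0),),
        noise=sd.NoiseParams(transient_rate_per_min=0.0), seed=3)
    audio, _ = sd.build_scene(scene)
    tpl = extract_template(audio, 1.5, 2.6, sd.template_band(sd.MoanSynthesisParams()))
    spec = compute_spectrogram(audio, tpl.params)
    scores = correlate(tpl, spec)
    j = int(np.argmax(scores))
    assert scores[j] == pytest.approx(1.0, abs=1e-6)
    assert spec.time_axis[j] == pytest.approx(1.5, abs=spec.frame_step)


def test_flat_excerpt_cannot_become_template():
    audio = CalibratedAudio(np.zeros(48000 * 2), 48000.0, T0, 150.0)
    with pytest.raises(ValueError, match="flat|contrast"):
        extract_template(audio, 0.2, 1.3, (40.0, 280.0))


def test_band_beyond_nyquist_rejected():
    rng = np.random.default_rng(0)
    audio = CalibratedAudio(0.1 * rng.standard_normal(16000).clip(-5, 5) / 5,
                            8000.0, T0, 150.0)
    with pytest.raises(ValueError, match="Nyquist"):
        extract_template(audio, 0.0, 1.0, (3900.0, 4200.0),
                         SpectrogramParams(fft_size=1024))


def test_parameter_mismatch_is_a_hard_error(ref_template):
    rng = np.random.default_rng(0)
    audio = CalibratedAudio(0.1 * rng.standard_normal(48000).clip(-5, 5) / 5,
                            48000.0, T0, 150.0)
    other = compute_spectrogram(audio, SpectrogramParams(fft_size=4096))
    with pytest.raises(ValueError, match="parameters"):
        correlate(ref_template, other)


def test_detects_all_injected_moans(ref_template, moan_scene_10db):
    """Five moans at 10 dB in-band SNR: all recovered at threshold 0.42,
    each within 0.25 s of its injected onset."""
    audio, annotations, sgram = moan_scene_10db
    events = detect(ref_template, audio, threshold=0.42, spectrogram=sgram)
    assert len(events) == len(annotations) == 5
    for ev, onset in zip(events, annotations["onset_s"]):
        assert (ev.time - audio.start_time).total_seconds() == pytest.approx(
            onset, abs=0.25)


def test_unattainable_threshold_yields_nothing(ref_template, moan_scene_10db):
    audio, _, sgram = moan_scene_10db
    assert detect(ref_template, audio, threshold=1.01, spectrogram=sgram) == []


def test_event_count_monotone_in_threshold(ref_template, moan_scene_10db):
    """Raising the threshold never adds an event."""
    audio, _, sgram = moan_scene_10db
    counts = [len(detect(ref_template, audio, threshold=th, spectrogram=sgram))
              for th in (0.2, 0.35, 0.42, 0.6, 0.75, 0.9)]
    assert counts == sorted(counts, reverse=True)


def test_close_pair_suppressed_and_matches_bruteforce(ref_template):
    """Two identical moans 0.5 s apart with 1.1 s separation collapse to one
    event; the greedy suppression agrees with a brute-force enumeration."""
    scene = sd.SceneSpec(
        duration=8.0,
        schedule=(sd.ScheduledCall(3.0, target_snr_db=12.0),
                  sd.ScheduledCall(3.5, target_snr_db=12.0)),
        seed=11)
    audio, _ = sd.build_scene(scene)
    sgram = compute_spectrogram(audio, ref_template.params)
    events = detect(ref_template, audio, threshold=0.42, min_separation=1.1,
                    spectrogram=sgram)
    assert len(events) == 1

    # brute-force oracle: enumerate all local maxima >= threshold, accept in
    # descending score, drop any within 1.1 s of an accepted one
    scores = correlate(ref_template, sgram)
    hop = sgram.frame_step
    maxima = [j for j in range(len(scores))
              if scores[j] >= 0.42
              and (j == 0 or scores[j] > scores[j - 1]
                   or (scores[j] == scores[j - 1]))
              and (j == len(scores) - 1 or scores[j] >= scores[j + 1])]
    accepted: list[int] = []
    for j in sorted(maxima, key=lambda j: (-scores[j], j)):
        if all(abs(j - a) * hop >= 1.1 for a in accepted):
            accepted.append(j)
    assert len(events) == len(accepted)
    ev_t = (events[0].time - audio.start_time).total_seconds()
    assert ev_t == pytest.approx(sgram.time_axis[accepted[0]], abs=1e-9)


def test_scores_invariant_to_recording_gain(ref_template, moan_scene_10db):
    """Zero-mean normalization cancels uniform dB offsets, so halving the
    digital gain (with compensated calibration) leaves scores unchanged."""
    audio, _, sgram = moan_scene_10db
    quiet = CalibratedAudio(audio.samples * 0.25, audio.sample_rate,
                            audio.start_time,
                            audio.full_scale_db - 20 * math.log10(0.25))
    s1 = correlate(ref_template, sgram)
    s2 = correlate(ref_template, compute_spectrogram(quiet, ref_template.params))
    assert np.allclose(s1, s2, atol=1e-9)


def test_detection_times_shift_with_the_audio(ref_template, moan_scene_10db):
    """Dropping the first second of audio shifts every event back by one
    second, within one frame hop."""
    audio, _, sgram = moan_scene_10db
    shift = 1.0
    cut = int(shift * audio.sample_rate)
    shifted = CalibratedAudio(audio.samples[cut:], audio.sample_rate,
                              audio.start_time, audio.full_scale_db)
    ev0 = detect(ref_template, audio, threshold=0.42, spectrogram=sgram)
    ev1 = detect(ref_template, shifted, threshold=0.42)
    assert len(ev0) == len(ev1)
    hop = sgram.frame_step
    for a, b in zip(ev0, ev1):
        t_a = (a.time - audio.start_time).total_seconds()
        t_b = (b.time - shifted.start_time).total_seconds()
        assert t_b == pytest.approx(t_a - shift, abs=hop + 1e-9)


def test_white_noise_rarely_crosses_threshold(ref_template):
    """On stationary white noise the correlation maximum stays below 0.42 in
    at least 95% of 50 seeded one-minute trials, and a strong tone outside
    the template band does not change that."""
    fs = 48000.0
    below = 0
    for trial in range(50):
        rng = np.random.default_rng(1000 + trial)
        x = 0.01 * rng.standard_normal(int(60 * fs))
        audio = CalibratedAudio(x, fs, T0, 150.0)
        spec = compute_spectrogram(audio, ref_template.params)
        if correlate(ref_template, spec).max() < 0.42:
            below += 1
    assert below >= 48  # >= 95% of 50

    rng = np.random.default_rng(4242)
    t = np.arange(int(60 * fs)) / fs
    x = 0.01 * rng.standard_normal(t.size) + 0.5 * np.sin(2 * np.pi * 1000.0 * t)
    audio = CalibratedAudio(x, fs, T0, 150.0)
    spec = compute_spectrogram(audio, ref_template.params)
    assert correlate(ref_template, spec).max() < 0.42


class TestReviewWorkflow:
    def _events(self, ref_template, moan_scene_10db):
        audio, _, sgram = moan_scene_10db
        return audio, detect(ref_template, audio, threshold=0.42,
                             spectrogram=sgram)[:3]

    def test_export_writes_clips_and_unreviewed_rows(self, tmp_path, ref_template,
                                                     moan_scene_10db):
        audio, events = self._events(ref_template, moan_scene_10db)
        csv_path = review_export(events, audio, tmp_path)
        assert sorted(p.name for p in tmp_path.glob("*.wav")) == [
            "event0000.wav", "event0001.wav", "event0002.wav"]
        lines = csv_path.read_text().strip().splitlines()
        assert len(lines) == 4
        assert all("unreviewed" in ln for ln in lines[1:])

    def test_unchanged_review_keeps_everything_unreviewed(self, tmp_path,
                                                          ref_template,
                                                          moan_scene_10db):
        audio, events = self._events(ref_template, moan_scene_10db)
        csv_path = review_export(events, audio, tmp_path)
        merged = review_import(events, csv_path)
        assert filter_verified(merged) == []

    def test_verdicts_merge_back(self, tmp_path, ref_template, moan_scene_10db):
        audio, events = self._events(ref_template, moan_scene_10db)
        csv_path = review_export(events, audio, tmp_path)
        text = csv_path.read_text()
        lines = text.strip().splitlines()
        lines[1] = lines[1].replace("unreviewed", "true")
        lines[2] = lines[2].replace("unreviewed", "true")
        lines[3] = lines[3].replace("unreviewed", "false")
        csv_path.write_text("\n".join(lines) + "\n")
        merged = review_import(events, csv_path)
        assert len(filter_verified(merged)) == 2

    def test_unknown_event_id_is_an_error(self, tmp_path, ref_template,
                                          moan_scene_10db):
        audio, events = self._events(ref_template, moan_scene_10db)
        csv_path = review_export(events, audio, tmp_path)
        csv_path.write_text("event_id,time,score,verified\n99,x,0.5,true\n")
        with pytest.raises(KeyError):
            review_import(events, csv_path)

    def test_event_csv_roundtrip(self, tmp_path, ref_template, moan_scene_10db):
        audio, events = self._events(ref_template, moan_scene_10db)
        events_to_csv(events, tmp_path / "ev.csv")
        back = events_from_csv(tmp_path / "ev.csv")
        assert [e.time for e in back] == [e.time for e in events]
        assert [e.score for e in back] == pytest.approx([e.score for e in events])
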