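"""Template-based call detection by normalized spectrogram cross-correlation.

A detection template is a small dB-magnitude time-frequency patch (for
humpback moans: ~1.1 s by 240 Hz around the arch-shaped ~100 Hz fundamental).
The detector slides it along a recording spectrogram, restricted to the
template's frequency band, computing at each frame lag the zero-mean
normalized cross-correlation between the patch and the same-size spectrogram
window.  Scores live in [-1, 1], are invariant to uniform dB offsets of the
recording (hence to recording gain), and peaks above a threshold become
timed detection events.

The default score threshold is 0.42, a value established in practice for
this call type; it is a plain parameter here and can be tuned per dataset.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .audio_core import (
    CalibratedAudio,
    Spectrogram,
    SpectrogramParams,
    compute_spectrogram,
    measure_received_level,
    write_wav,
)

__all__ = [
    "SpectroTemplate",
    "DetectionEvent",
    "DEFAULT_THRESHOLD",
    "extract_template",
    "correlate",
    "detect",
    "attach_received_levels",
    "filter_verified",
    "events_to_csv",
    "events_from_csv",
    "events_to_selection_table",
    "review_export",
    "review_import",
]

DEFAULT_THRESHOLD = 0.42


@dataclass
class SpectroTemplate:
    """A zero-mean, unit-norm dB spectrogram patch used for matching.

    ``band`` is the (low, high) Hz interval the patch rows cover; ``params``
    are the STFT settings the patch was built with.  Correlation against a
    spectrogram built with different settings is refused rather than
    silently resampled.
    """

    patch: np.ndarray  # rows: frequency, cols: time frames
    duration: float
    band: tuple[float, float]
    params: SpectrogramParams

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.float64)
        if self.patch.ndim != 2:
            raise ValueError("template patch must be 2-D")
        if abs(float(self.patch.mean())) > 1e-8:
            raise ValueError("template patch must be zero-mean")


@dataclass
class DetectionEvent:
    """A scored candidate call.

    ``verified`` carries the manual-review status: every automatic detection
    starts "unreviewed" and only events marked "true" feed presence
    statistics downstream.
    """

    time: datetime
    score: float
    duration: float
    band: tuple[float, float]
    received_level_db: float | None = None
    verified: str = "unreviewed"

    def __post_init__(self) -> None:
        if self.verified not in ("unreviewed", "true", "false"):
            raise ValueError(f"invalid verified status {self.verified!r}")


def _band_rows(freq_axis: np.ndarray, band, bin_width: float) -> tuple[int, int]:
    """Row slice for a band: first bin at/above the low edge, then
    ceil(band_height / bin_width) rows."""
    lo, hi = float(band[0]), float(band[1])
    if hi <= lo:
        raise ValueError(f"empty band ({lo}, {hi})")
    i0 = int(np.searchsorted(freq_axis, lo - 1e-9))
    n_rows = int(math.ceil((hi - lo) / bin_width))
    if i0 + n_rows > freq_axis.size:
        raise ValueError(f"band ({lo}, {hi}) Hz extends beyond Nyquist "
                         f"({freq_axis[-1]:.1f} Hz)")
    return i0, n_rows


def extract_template(
    audio: CalibratedAudio,
    t0: float,
    t1: float,
    band,
    params: SpectrogramParams | None = None,
) -> SpectroTemplate:
    """Cut a template patch from a recording excerpt.

    Rows are the bins of ``band``; columns the frames whose start falls in
    ``[t0, t1)``.  The patch is stored zero-mean and unit-norm, so
    correlating a template against its own source location scores 1.
    """
    if params is None:
        params = SpectrogramParams()
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    spec = compute_spectrogram(audio, params)
    i0, n_rows = _band_rows(spec.freq_axis, band, spec.bin_width)
    j = np.flatnonzero((spec.time_axis >= t0 - 1e-9) & (spec.time_axis < t1 - 1e-9))
    if j.size == 0:
        raise ValueError(f"no spectrogram frames start within [{t0}, {t1}] s")
    patch = spec.magnitude_db[i0:i0 + n_rows, j[0]:j[-1] + 1].copy()
    patch -= patch.mean()
    norm = float(np.linalg.norm(patch))
    if norm < 1e-12:
        raise ValueError("template excerpt has zero contrast (flat patch); "
                         "cannot normalize")
    patch /= norm
    return SpectroTemplate(patch, t1 - t0, (float(band[0]), float(band[1])), params)


def correlate(template: SpectroTemplate, spec: Spectrogram) -> np.ndarray:
    """Zero-mean normalized cross-correlation series over frame lags.

    Only rows inside the template band participate, so out-of-band energy
    (e.g. ice noise above the call band) cannot move the scores.  The value
    at lag ``j`` corresponds to a template placed with its first frame at
    ``spec.time_axis[j]``.
    """
    if spec.params != template.params:
        raise ValueError("spectrogram parameters differ from the template's; "
                         "rebuild the spectrogram instead of resampling")
    i0, n_rows = _band_rows(spec.freq_axis, template.band, spec.bin_width)
    if n_rows != template.patch.shape[0]:
        raise ValueError("spectrogram band rows do not match template rows")
    S = spec.magnitude_db[i0:i0 + n_rows]
    k = template.patch.shape[1]
    if S.shape[1] < k:
        raise ValueError("spectrogram shorter than the template")
    n_pix = template.patch.size
    # Template is zero-mean, so subtracting each window's mean leaves the
    # numerator untouched: num[j] = sum(T * S[:, j:j+k]).
    num = _signal.correlate(S, template.patch, mode="valid")[0]
    col1 = S.sum(axis=0)
    col2 = np.square(S).sum(axis=0)
    w1 = np.convolve(col1, np.ones(k), mode="valid")
    w2 = np.convolve(col2, np.ones(k), mode="valid")
    var = np.maximum(w2 - w1 * w1 / n_pix, 0.0)
    denom = np.sqrt(var)
    scores = np.zeros_like(num)
    ok = denom > 1e-12
    scores[ok] = num[ok] / denom[ok]
    return np.clip(scores, -1.0, 1.0)


def detect(
    template: SpectroTemplate,
    audio: CalibratedAudio,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation: float | None = None,
    spectrogram: Spectrogram | None = None,
) -> list[DetectionEvent]:
    """Run the template detector over one audio segment.

    Local maxima of the correlation series at or above ``threshold`` are
    accepted greedily in descending score order; maxima within
    ``min_separation`` seconds (default: the template duration, since one
    call cannot overlap itself) of an already accepted event are suppressed.
    Score ties break toward the earlier time.  A precomputed ``spectrogram``
    of the same audio may be passed to avoid recomputation.
    """
    if not 0.0 < threshold:
        raise ValueError("threshold must be positive")
    if min_separation is None:
        min_separation = template.duration
    spec = spectrogram if spectrogram is not None else compute_spectrogram(audio, template.params)
    scores = correlate(template, spec)
    if scores.size == 0:
        return []
    padded = np.concatenate(([-np.inf], scores, [-np.inf]))
    peaks, _ = _signal.find_peaks(padded)
    peaks -= 1
    peaks = peaks[scores[peaks] >= threshold]
    order = sorted(peaks, key=lambda j: (-scores[j], j))
    hop_s = spec.frame_step
    accepted: list[int] = []
    for j in order:
        if all(abs(j - a) * hop_s >= min_separation for a in accepted):
            accepted.append(j)
    events = [
        DetectionEvent(
            time=audio.start_time + timedelta(seconds=float(spec.time_axis[j])),
            score=float(scores[j]),
            duration=template.duration,
            band=template.band,
        )
        for j in sorted(accepted)
    ]
    return events


def attach_received_levels(events, audio: CalibratedAudio) -> list[DetectionEvent]:
    """Measure each event's band-limited rms received level from the audio."""
    out = []
    for ev in events:
        t0 = (ev.time - audio.start_time).total_seconds()
        t1 = min(t0 + ev.duration, audio.duration)
        rl = measure_received_level(audio, t0, t1, ev.band)
        out.append(replace(ev, received_level_db=rl))
    return out


def filter_verified(events) -> list[DetectionEvent]:
    """Keep only events a reviewer confirmed; unreviewed events never count."""
    return [ev for ev in events if ev.verified == "true"]


_CSV_COLS = ["time", "score", "duration_s", "band_low_hz", "band_high_hz",
             "received_level_db", "verified"]


def events_to_csv(events, path) -> None:
    rows = [
        {
            "time": ev.time.isoformat(),
            "score": ev.score,
            "duration_s": ev.duration,
            "band_low_hz": ev.band[0],
            "band_high_hz": ev.band[1],
            "received_level_db": "" if ev.received_level_db is None else ev.received_level_db,
            "verified": ev.verified,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)


def events_from_csv(path) -> list[DetectionEvent]:
    df = pd.read_csv(path, dtype={"verified": str})
    events = []
    for row in df.itertuples():
        rl = None if pd.isna(row.received_level_db) else float(row.received_level_db)
        events.append(DetectionEvent(
            time=datetime.fromisoformat(str(row.time)),
            score=float(row.score),
            duration=float(row.duration_s),
            band=(float(row.band_low_hz), float(row.band_high_hz)),
            received_level_db=rl,
            verified=str(row.verified),
        ))
    return events


def events_to_selection_table(events, path) -> None:
    """Export events in the begin/end-time, low/high-frequency column layout
    common to annotation tools."""
    rows = [
        {
            "Selection": i + 1,
            "Begin Time (s)": (ev.time - events[0].time).total_seconds() if events else 0.0,
            "End Time (s)": (ev.time - events[0].time).total_seconds() + ev.duration,
            "Low Freq (Hz)": ev.band[0],
            "High Freq (Hz)": ev.band[1],
            "Score": ev.score,
        }
        for i, ev in enumerate(events)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def review_export(
    events,
    audio: CalibratedAudio,
    out_dir,
    clip_pad: float = 1.0,
    write_spectrograms: bool = False,
) -> Path:
    """Write per-event review material: an audio clip (and optionally a
    spectrogram image) per event plus a review CSV.

    The CSV has columns ``event_id, time, score, verified`` with every event
    initially "unreviewed".  A reviewer edits the ``verified`` column and the
    file is merged back with :func:`review_import`.  Returns the CSV path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, ev in enumerate(events):
        t0 = max(0.0, (ev.time - audio.start_time).total_seconds() - clip_pad)
        t1 = min(audio.duration, t0 + ev.duration + 2 * clip_pad)
        i0 = int(t0 * audio.sample_rate)
        i1 = int(t1 * audio.sample_rate)
        clip = CalibratedAudio(audio.samples[i0:i1], audio.sample_rate,
                               audio.start_time + timedelta(seconds=t0),
                               audio.full_scale_db)
        write_wav(out_dir / f"event{i:04d}.wav", clip)
        if write_spectrograms:
            _write_clip_image(out_dir / f"event{i:04d}.png", clip, ev)
    csv_path = out_dir / "review.csv"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event_id", "time", "score", "verified"])
        for i, ev in enumerate(events):
            w.writerow([i, ev.time.isoformat(), f"{ev.score:.4f}", ev.verified])
    return csv_path


def review_import(events, csv_path) -> list[DetectionEvent]:
    """Merge reviewer verdicts from a review CSV back onto the events.

    Rows left "unreviewed" stay unreviewed (and therefore excluded from
    presence statistics).  An event id not matching the event list is an
    error.
    """
    df = pd.read_csv(csv_path, dtype={"verified": str})
    out = list(events)
    for row in df.itertuples():
        idx = int(row.event_id)
        if not 0 <= idx < len(out):
            raise KeyError(f"unknown event id {idx} in review file")
        out[idx] = replace(out[idx], verified=str(row.verified).strip().lower())
    return out


def _write_clip_image(path, clip: CalibratedAudio, ev: DetectionEvent) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = min(1024, clip.samples.size)
    params = SpectrogramParams(fft_size=n, overlap_fraction=0.5)
    spec = compute_spectrogram(clip, params)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.pcolormesh(spec.time_axis, spec.freq_axis, spec.magnitude_db, shading="auto")
    ax.set_ylim(0, max(2 * ev.band[1], 500))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"{ev.time.isoformat()}  score={ev.score:.2f}")
    fig.savefig(path, dpi=100)
    plt.close(fig)
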