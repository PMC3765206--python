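"""Calibrated single-channel audio: I/O, spectrograms, absolute sound levels.

Digital amplitudes live in [-1, 1].  The absolute sound pressure level that
corresponds to digital full scale (|x| = 1) is carried per file as
``full_scale_db`` in dB re 1 uPa, so an rms measured in digital units maps to
an absolute received level as ``20*log10(rms) + full_scale_db``.  Recorders
whose gain is adjusted in the field log a full-scale value per file (typical
range 138-150 dB re 1 uPa); keeping it attached to the samples makes every
downstream level calculation gain-independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "CalibratedAudio",
    "SpectrogramParams",
    "Spectrogram",
    "read_wav",
    "write_wav",
    "parse_filename_time",
    "read_calibration_log",
    "write_calibration_log",
    "load_timestamped_sequence",
    "write_effort_gaps",
    "compute_spectrogram",
    "measure_received_level",
    "bandpass",
]

#: dB value assigned to an all-zero spectrogram (no reference magnitude exists).
SILENCE_DB = -300.0

DEFAULT_FILENAME_PATTERN = "%Y%m%d_%H%M%S"


@dataclass
class CalibratedAudio:
    """A contiguous mono recording segment with absolute calibration.

    Parameters
    ----------
    samples : ndarray
        Digital amplitudes in [-1, 1] (full scale = 1).
    sample_rate : float
        Sampling rate in Hz.
    start_time : datetime
        UTC timestamp of the first sample.
    full_scale_db : float
        Sound pressure level, dB re 1 uPa, of a full-scale (amplitude 1) tone.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: datetime
    full_scale_db: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array (mono audio)")
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ValueError("samples exceed digital full scale [-1, 1]")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not math.isfinite(self.full_scale_db):
            raise ValueError("full_scale_db must be finite")
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.replace(tzinfo=timezone.utc)

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.duration)


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT analysis parameters.

    ``overlap_fraction`` is the fraction of each window shared with its
    neighbour, so the hop is ``fft_size * (1 - overlap_fraction)`` samples.
    Some tools quote the complementary convention (overlap meaning the hop
    fraction); set ``overlap_denotes_hop`` to adopt it.
    """

    fft_size: int = 4048
    overlap_fraction: float = 0.25
    window: str = "hann"
    overlap_denotes_hop: bool = False
    db_floor_range: float = 120.0

    def __post_init__(self) -> None:
        if self.fft_size < 2:
            raise ValueError("fft_size must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def hop(self) -> int:
        frac = self.overlap_fraction if self.overlap_denotes_hop else 1.0 - self.overlap_fraction
        return max(1, int(round(self.fft_size * frac)))


@dataclass
class Spectrogram:
    """dB-scaled magnitude spectrogram (frequency x time).

    ``time_axis`` holds frame *start* offsets in seconds from the segment
    start; ``freq_axis`` holds bin centre frequencies from 0 to Nyquist.
    """

    magnitude_db: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    params: SpectrogramParams
    sample_rate: float

    def __post_init__(self) -> None:
        if self.magnitude_db.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValueError("axis lengths must match magnitude dimensions")

    @property
    def bin_width(self) -> float:
        """Frequency resolution in Hz per bin."""
        return self.sample_rate / self.params.fft_size

    @property
    def frame_step(self) -> float:
        """Hop between frames in seconds."""
        return self.params.hop / self.sample_rate


def read_wav(path, start_time: datetime, full_scale_db: float) -> CalibratedAudio:
    """Read a mono PCM16 or float WAV file into a calibrated segment."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError(f"{path}: multi-channel audio is not supported")
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483648.0
    elif data.dtype.kind == "f":
        x = np.asarray(data, dtype=np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return CalibratedAudio(x, float(rate), start_time, full_scale_db)


def write_wav(path, audio: CalibratedAudio) -> None:
    """Write a segment as PCM16 WAV."""
    pcm = np.clip(np.round(audio.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(round(audio.sample_rate)), pcm)


def parse_filename_time(path, pattern: str = DEFAULT_FILENAME_PATTERN) -> datetime:
    """Parse a UTC timestamp from a file name (extension stripped)."""
    stem = Path(path).stem
    try:
        return datetime.strptime(stem, pattern).replace(tzinfo=timezone.utc)
    except ValueError as exc:
        raise ValueError(f"cannot parse timestamp from file name {path!r} "
                         f"with pattern {pattern!r}") from exc


def read_calibration_log(path) -> dict[str, float]:
    """Read a CSV calibration log with columns ``filename, full_scale_db``."""
    df = pd.read_csv(path)
    return {str(row.filename): float(row.full_scale_db) for row in df.itertuples()}


def write_calibration_log(path, entries: dict[str, float]) -> None:
    pd.DataFrame(
        {"filename": list(entries), "full_scale_db": list(entries.values())}
    ).to_csv(path, index=False)


def load_timestamped_sequence(
    paths,
    calibration_log: dict[str, float],
    pattern: str = DEFAULT_FILENAME_PATTERN,
    gap_tolerance: float = 0.5,
):
    """Load a time-stamped file sequence with per-file calibration.

    Returns ``(segments, gaps)`` where segments are sorted by start time and
    ``gaps`` lists ``(start, end)`` pairs of recording outages between
    consecutive segments (gaps shorter than ``gap_tolerance`` seconds are
    treated as continuous).  Gaps are preserved, never zero-filled: effort
    accounting downstream relies on them.
    """
    segments: list[CalibratedAudio] = []
    for p in paths:
        name = Path(p).name
        if name not in calibration_log:
            raise KeyError(f"no calibration entry for file {name!r}")
        t0 = parse_filename_time(p, pattern)
        segments.append(read_wav(p, t0, calibration_log[name]))
    segments.sort(key=lambda s: s.start_time)
    gaps: list[tuple[datetime, datetime]] = []
    for prev, nxt in zip(segments, segments[1:]):
        if (nxt.start_time - prev.end_time).total_seconds() > gap_tolerance:
            gaps.append((prev.end_time, nxt.start_time))
    return segments, gaps


def write_effort_gaps(path, gaps) -> None:
    pd.DataFrame(
        {"start": [g[0].isoformat() for g in gaps],
         "end": [g[1].isoformat() for g in gaps]}
    ).to_csv(path, index=False)


def compute_spectrogram(audio: CalibratedAudio, params: SpectrogramParams | None = None) -> Spectrogram:
    """Short-time Fourier magnitude spectrogram in dB.

    Frames advance by ``params.hop`` samples; the frame count is
    ``floor((N - fft_size)/hop) + 1``.  Magnitudes are ``20*log10(|STFT|)``
    re digital units, floored ``db_floor_range`` dB below the per-spectrogram
    maximum to bound the dynamic range.  All-zero audio maps to a uniform
    silence floor.
    """
    if params is None:
        params = SpectrogramParams()
    n = params.fft_size
    if audio.samples.size < n:
        raise ValueError(
            f"audio ({audio.samples.size} samples) shorter than one window ({n})")
    hop = params.hop
    win = signal.get_window(params.window, n, fftbins=True)
    frames = sliding_window_view(audio.samples, n)[::hop] * win
    mag = np.abs(np.fft.rfft(frames, axis=1)).T  # freq x time
    peak = mag.max()
    if peak <= 0.0:
        db = np.full(mag.shape, SILENCE_DB)
    else:
        floor = peak * 10.0 ** (-params.db_floor_range / 20.0)
        db = 20.0 * np.log10(np.maximum(mag, floor))
    freq = np.fft.rfftfreq(n, 1.0 / audio.sample_rate)
    times = np.arange(mag.shape[1]) * hop / audio.sample_rate
    return Spectrogram(db, freq, times, params, audio.sample_rate)


def bandpass(x: np.ndarray, band, sample_rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band filter; degenerates gracefully at the edges.

    A band reaching down to 0 Hz becomes a low-pass, one reaching Nyquist a
    high-pass, and a band covering the whole spectrum is a no-op.  Zero-phase
    (forward-backward) filtering keeps event timing intact.
    """
    lo, hi = float(band[0]), float(band[1])
    nyq = sample_rate / 2.0
    if hi <= lo:
        raise ValueError(f"empty frequency band ({lo}, {hi})")
    lo = max(lo, 0.0)
    hi = min(hi, nyq)
    if lo <= 0.0 and hi >= nyq:
        return np.asarray(x, dtype=np.float64)
    if lo <= 0.0:
        sos = signal.butter(order, hi, btype="lowpass", fs=sample_rate, output="sos")
    elif hi >= nyq:
        sos = signal.butter(order, lo, btype="highpass", fs=sample_rate, output="sos")
    else:
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def measure_received_level(audio: CalibratedAudio, t0: float, t1: float, band) -> float:
    """Band-limited rms received level in dB re 1 uPa over ``[t0, t1]`` seconds.

    ``RL = 20*log10(rms of band-filtered samples) + full_scale_db``.  The
    result is invariant to digital gain because a gain change moves the
    digital rms and the full-scale value in opposite directions.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if t0 < 0 or t1 > audio.duration + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] s outside segment of {audio.duration:.3f} s")
    nyq = audio.sample_rate / 2.0
    if band[0] < 0 or band[1] > nyq + 1e-9:
        raise ValueError(f"band {band} outside [0, {nyq}] Hz")
    i0 = int(round(t0 * audio.sample_rate))
    i1 = min(int(round(t1 * audio.sample_rate)), audio.samples.size)
    seg = bandpass(audio.samples[i0:i1], band, audio.sample_rate)
    rms = float(np.sqrt(np.mean(np.square(seg))))
    if rms <= 0.0:
        warnings.warn("silent window: received level is -inf", stacklevel=2)
        return float("-inf")
    return 20.0 * math.log10(rms) + audio.full_scale_db
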