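"""Synthetic inputs with exact ground truth for every pipeline stage.

The generators emulate the statistical structure of an Antarctic shelf-edge
hydrophone dataset: arch-shaped ~100 Hz humpback moans of ~1.1 s embedded in
ice-dominated ambient noise, 80 s narrow-band FM sweeps from a moored
calibration source, per-file full-scale settings in the 138-150 dB re 1 uPa
range, and seasonal ice-concentration grids (open water in February, >90%
ice in August).  Every generator is a pure function of its parameters and a
seed, returns its ground truth (call onsets and contours, true transmission
loss, true seasonal curve) alongside the data, and is bit-identical across
reruns with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .audio_core import CalibratedAudio, SpectrogramParams, bandpass
from .ice_cover import IceGrid
from .presence import EffortLog
from .ranging import CalibrationReception

__all__ = [
    "MoanSynthesisParams",
    "SweepParams",
    "NoiseParams",
    "ScheduledCall",
    "SceneSpec",
    "MoanWaveform",
    "template_band",
    "synth_moan",
    "moan_for_rl",
    "synth_sweep",
    "build_scene",
    "synth_receptions",
    "synth_ice_year",
    "synth_presence_year",
    "reference_template",
]

#: km of meridian arc per degree of latitude on a 6371 km sphere.
_KM_PER_DEG = 6371.0 * math.pi / 180.0


@dataclass(frozen=True)
class MoanSynthesisParams:
    """Arch-shaped moan: fundamental rises half the bandwidth and returns.

    The fundamental contour is ``f1(t) = fundamental + (bandwidth/2) *
    sin(pi t / duration)``, so it spans ``[fundamental, fundamental +
    bandwidth/2]`` Hz.  Harmonics stack on top with a fixed per-harmonic
    level decay; a short Tukey taper removes onset/offset clicks.
    """

    fundamental: float = 100.0
    duration: float = 1.1
    bandwidth: float = 240.0
    n_harmonics: int = 3
    harmonic_decay_db: float = 6.0
    taper_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.fundamental <= 0 or self.duration <= 0 or self.bandwidth < 0:
            raise ValueError("fundamental and duration must be positive, "
                             "bandwidth non-negative")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")


@dataclass(frozen=True)
class SweepParams:
    """Calibration-source signal: a slow narrow FM sweep."""

    f_start: float = 259.0
    f_end: float = 261.0
    duration: float = 80.0
    source_level_db: float = 180.0

    def __post_init__(self) -> None:
        if self.f_end <= self.f_start or self.duration <= 0:
            raise ValueError("require f_end > f_start and positive duration")


@dataclass(frozen=True)
class NoiseParams:
    """Ambient noise: sloped Gaussian background plus ice-crack transients.

    ``level_db`` is the broadband rms level in dB re 1 uPa; the spectral
    slope (dB per octave, negative = red) shapes the background; transients
    are Poisson-scheduled short broadband bursts standing the given number
    of dB above the background rms.
    """

    level_db: float = 90.0
    slope_db_per_octave: float = -5.0
    transient_rate_per_min: float = 6.0
    transient_db_above: float = 12.0
    transient_duration: float = 0.02


@dataclass(frozen=True)
class ScheduledCall:
    """One call injection: give either an absolute in-band received level or
    an in-band SNR relative to the scene's own noise."""

    time_s: float
    params: MoanSynthesisParams = MoanSynthesisParams()
    target_rl_db: float | None = None
    target_snr_db: float | None = None

    def __post_init__(self) -> None:
        if (self.target_rl_db is None) == (self.target_snr_db is None):
            raise ValueError("set exactly one of target_rl_db / target_snr_db")


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one reproducible calibrated audio scene."""

    duration: float
    sample_rate: float = 48000.0
    full_scale_db: float = 150.0
    start_time: datetime = datetime(2008, 1, 1, tzinfo=timezone.utc)
    noise: NoiseParams = NoiseParams()
    schedule: tuple[ScheduledCall, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 138.0 - 1e-9 <= self.full_scale_db <= 150.0 + 1e-9:
            raise ValueError("full_scale_db outside the emulated 138-150 dB range")
        for c in self.schedule:
            if not 0 <= c.time_s <= self.duration - c.params.duration:
                raise ValueError(f"scheduled call at {c.time_s} s does not fit "
                                 f"inside a {self.duration} s scene")


@dataclass
class MoanWaveform:
    """A synthesized moan plus its exact fundamental contour."""

    samples: np.ndarray
    sample_rate: float
    contour_times: np.ndarray
    contour_hz: np.ndarray
    harmonic_amplitudes: np.ndarray

    @property
    def analytic_rms(self) -> float:
        """Closed-form rms for the untapered harmonic stack:
        sqrt(sum(A_h^2) / 2)."""
        return math.sqrt(float(np.sum(self.harmonic_amplitudes ** 2)) / 2.0)


def template_band(params: MoanSynthesisParams, height: float = 240.0) -> tuple[float, float]:
    """Detection band of the stated height centred on the fundamental
    contour's midline (e.g. 40-280 Hz for the default moan)."""
    center = params.fundamental + params.bandwidth / 4.0
    lo = max(center - height / 2.0, 1.0)
    return (lo, center + height / 2.0)


def synth_moan(
    params: MoanSynthesisParams,
    sample_rate: float,
    amplitude: float = 1.0,
) -> MoanWaveform:
    """Synthesize one moan with fundamental amplitude ``amplitude``.

    Harmonic ``h`` runs at ``h * f1(t)`` with amplitude decayed
    ``harmonic_decay_db`` per harmonic.  The phase uses the analytic
    integral of the contour, so the instantaneous frequency matches the
    returned ground-truth contour exactly.
    """
    n = int(round(params.duration * sample_rate))
    t = np.arange(n) / sample_rate
    f1 = params.fundamental + (params.bandwidth / 2.0) * np.sin(np.pi * t / params.duration)
    # integral of f1: f0*t + (B/2)*(d/pi)*(1 - cos(pi t / d))
    phase1 = params.fundamental * t + (params.bandwidth / 2.0) * (
        params.duration / math.pi) * (1.0 - np.cos(np.pi * t / params.duration))
    amps = amplitude * 10.0 ** (
        -params.harmonic_decay_db * np.arange(params.n_harmonics) / 20.0)
    x = np.zeros(n)
    for h, a in enumerate(amps, start=1):
        x += a * np.sin(2.0 * math.pi * h * phase1)
    if params.taper_fraction > 0:
        x *= _signal.windows.tukey(n, alpha=2.0 * params.taper_fraction)
    return MoanWaveform(x, sample_rate, t, f1, amps)


def moan_for_rl(
    params: MoanSynthesisParams,
    sample_rate: float,
    target_rl_db: float,
    full_scale_db: float,
    band=None,
) -> MoanWaveform:
    """Scale a moan so its in-band rms hits a target received level.

    ``target_rl_db`` is the level (dB re 1 uPa) of the call measured in
    ``band`` (default: the template band) under the given full-scale
    calibration; harmonics outside the band ride on top.
    """
    if band is None:
        band = template_band(params)
    moan = synth_moan(params, sample_rate, amplitude=1.0)
    inband = bandpass(moan.samples, band, sample_rate)
    rms = float(np.sqrt(np.mean(np.square(inband))))
    if rms <= 0:
        raise ValueError("degenerate moan: zero in-band energy")
    target_rms = 10.0 ** ((target_rl_db - full_scale_db) / 20.0)
    scale = target_rms / rms
    return MoanWaveform(moan.samples * scale, sample_rate, moan.contour_times,
                        moan.contour_hz, moan.harmonic_amplitudes * scale)


def synth_sweep(params: SweepParams, sample_rate: float, amplitude: float = 1.0) -> np.ndarray:
    """Linear FM sweep emulating the calibration source's transmission."""
    n = int(round(params.duration * sample_rate))
    t = np.arange(n) / sample_rate
    return amplitude * _signal.chirp(t, params.f_start, params.duration, params.f_end)


def _shaped_noise(n: int, sample_rate: float, slope_db_per_octave: float,
                  rng: np.random.Generator, f_ref: float = 100.0) -> np.ndarray:
    """Unit-rms Gaussian noise with a power-law spectral slope."""
    white = rng.standard_normal(n)
    if slope_db_per_octave == 0.0:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / sample_rate)
        f = np.maximum(f, 10.0)  # flatten below the band of interest
        gain = 10.0 ** (slope_db_per_octave * np.log2(f / f_ref) / 20.0)
        x = np.fft.irfft(spec * gain, n)
    return x / np.sqrt(np.mean(np.square(x)))


def build_scene(spec: SceneSpec):
    """Assemble a calibrated scene: shaped noise, ice-crack transients, and
    scheduled moans, with a ground-truth annotation table.

    Returns ``(audio, annotations)``.  Annotation columns: ``onset_s, time,
    duration_s, band_low_hz, band_high_hz, target_rl_db, overlaps``.
    Overlapping scheduled calls are allowed but flagged.  Output is
    bit-identical for identical spec (including seed).
    """
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)
    noise_rms = 10.0 ** ((spec.noise.level_db - spec.full_scale_db) / 20.0)
    x = noise_rms * _shaped_noise(n, fs, spec.noise.slope_db_per_octave, rng)

    n_trans = rng.poisson(spec.noise.transient_rate_per_min * spec.duration / 60.0)
    t_len = max(int(spec.noise.transient_duration * fs), 8)
    t_amp = noise_rms * 10.0 ** (spec.noise.transient_db_above / 20.0)
    env = np.exp(-np.arange(t_len) / (t_len / 4.0))
    for start in np.sort(rng.integers(0, max(n - t_len, 1), size=n_trans)):
        x[start:start + t_len] += t_amp * env * rng.standard_normal(t_len)

    rows = []
    intervals = []
    for call in spec.schedule:
        band = template_band(call.params)
        if call.target_rl_db is not None:
            rl = call.target_rl_db
        else:
            i0 = int(call.time_s * fs)
            i1 = min(i0 + int(call.params.duration * fs), n)
            seg = bandpass(x[i0:i1], band, fs)
            noise_db = 20.0 * math.log10(float(np.sqrt(np.mean(np.square(seg))))) \
                + spec.full_scale_db
            rl = noise_db + call.target_snr_db
        moan = moan_for_rl(call.params, fs, rl, spec.full_scale_db, band)
        i0 = int(round(call.time_s * fs))
        x[i0:i0 + moan.samples.size] += moan.samples[:n - i0]
        intervals.append((call.time_s, call.time_s + call.params.duration))
        rows.append({
            "onset_s": call.time_s,
            "time": spec.start_time + timedelta(seconds=call.time_s),
            "duration_s": call.params.duration,
            "band_low_hz": band[0],
            "band_high_hz": band[1],
            "target_rl_db": rl,
        })
    for i, row in enumerate(rows):
        a0, a1 = intervals[i]
        row["overlaps"] = any(
            j != i and intervals[j][0] < a1 and a0 < intervals[j][1]
            for j in range(len(intervals)))

    peak = float(np.max(np.abs(x))) if n else 0.0
    if peak > 1.0:
        raise ValueError(
            f"scene clips (peak {peak:.3f} digital units); lower the scheduled "
            "levels or raise full_scale_db")
    audio = CalibratedAudio(x, fs, spec.start_time, spec.full_scale_db)
    cols = ["onset_s", "time", "duration_s", "band_low_hz", "band_high_hz",
            "target_rl_db", "overlaps"]
    return audio, pd.DataFrame(rows, columns=cols)


def synth_receptions(
    true_a: float = 20.9,
    source_level: float = 180.0,
    range_m: float = 177_000.0,
    rl_sd: float = 7.0,
    n: int = 939,
    seed: int = 0,
    start_time: datetime = datetime(2008, 3, 1, tzinfo=timezone.utc),
    interval_hours: float = 12.0,
) -> list[CalibrationReception]:
    """Calibration-source receptions under a known transmission-loss law.

    ``RL_i = SL - true_a * log10(r) + N(0, rl_sd)``, one reception every
    ``interval_hours`` (the source transmits on a fixed schedule).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    mean_rl = source_level - true_a * math.log10(range_m)
    rls = mean_rl + rl_sd * rng.standard_normal(n)
    return [
        CalibrationReception(float(rl), source_level, range_m,
                             start_time + timedelta(hours=interval_hours * i))
        for i, rl in enumerate(rls)
    ]


def synth_ice_year(
    year: int = 2008,
    center: tuple[float, float] = (-70.517, -8.217),
    shape: tuple[int, int] = (48, 48),
    cell_size_km: float = 6.25,
    step_days: int = 1,
    min_pct: float = 5.0,
    max_pct: float = 95.0,
    min_day_of_year: int = 45,
    spatial_noise_sd: float = 5.0,
    seed: int = 0,
) -> list[IceGrid]:
    """Dated concentration grids following the Antarctic seasonal cycle.

    The field oscillates sinusoidally between ``min_pct`` (mid-February,
    open water) and ``max_pct`` (mid-August, near-total cover), plus
    per-cell Gaussian noise, clipped to [0, 100].  Cells form a regular
    lat/lon grid of the given nominal cell size centred on ``center``.
    """
    rng = np.random.default_rng(seed)
    nr, nc = shape
    lat0, lon0 = center
    dlat = cell_size_km / _KM_PER_DEG
    dlon = cell_size_km / (_KM_PER_DEG * math.cos(math.radians(lat0)))
    lat = lat0 + (np.arange(nr) - (nr - 1) / 2.0) * dlat
    lon = lon0 + (np.arange(nc) - (nc - 1) / 2.0) * dlon
    cell_lat, cell_lon = np.meshgrid(lat, lon, indexing="ij")
    mid = (min_pct + max_pct) / 2.0
    amp = (max_pct - min_pct) / 2.0
    grids = []
    d = date(year, 1, 1)
    end = date(year, 12, 31)
    while d <= end:
        doy = d.timetuple().tm_yday
        base = mid - amp * math.cos(2.0 * math.pi * (doy - min_day_of_year) / 365.25)
        conc = base + spatial_noise_sd * rng.standard_normal(shape)
        grids.append(IceGrid(np.clip(conc, 0.0, 100.0), cell_lat, cell_lon,
                             cell_size_km, d))
        d += timedelta(days=step_days)
    return grids


def synth_presence_year(
    year: int = 2008,
    peak_day_of_year: int = 75,
    peak_width_days: float = 45.0,
    peak_rate_per_day: float = 8.0,
    base_rate_per_day: float = 0.25,
    outage_days: tuple[tuple[int, int], ...] = (),
    seed: int = 0,
):
    """Verified detection events with a late-summer seasonal peak.

    The daily Poisson rate is a Gaussian bump of the given width centred on
    ``peak_day_of_year`` (default: mid-March, the February-April maximum of
    the emulated system) on top of a low year-round base rate, so sporadic
    winter calling occurs too.  ``outage_days`` lists (start_doy, end_doy)
    recording outages excluded from effort (no events are generated there).
    Returns ``(events, effort)``.
    """
    from .detector import DetectionEvent  # deferred: avoids import cycle

    rng = np.random.default_rng(seed)
    year_start = datetime(year, 1, 1, tzinfo=timezone.utc)
    n_days = (date(year + 1, 1, 1) - date(year, 1, 1)).days
    off = set()
    for a, b in outage_days:
        off.update(range(a, b + 1))
    events = []
    for doy in range(1, n_days + 1):
        if doy in off:
            continue
        rate = base_rate_per_day + peak_rate_per_day * math.exp(
            -0.5 * ((doy - peak_day_of_year) / peak_width_days) ** 2)
        k = rng.poisson(rate)
        day_start = year_start + timedelta(days=doy - 1)
        for s in np.sort(rng.uniform(0.0, 86400.0, size=k)):
            events.append(DetectionEvent(
                time=day_start + timedelta(seconds=float(s)),
                score=float(rng.uniform(0.45, 0.95)),
                duration=1.1,
                band=(40.0, 280.0),
                verified="true",
            ))
    intervals = []
    run_start = None
    for doy in range(1, n_days + 1):
        if doy not in off and run_start is None:
            run_start = doy
        if (doy in off or doy == n_days) and run_start is not None:
            last = doy - 1 if doy in off else doy
            intervals.append((
                year_start + timedelta(days=run_start - 1),
                year_start + timedelta(days=last),
            ))
            run_start = None
    return events, EffortLog(intervals)


def reference_template(
    params: MoanSynthesisParams = MoanSynthesisParams(),
    sample_rate: float = 48000.0,
    spec_params: SpectrogramParams | None = None,
    snr_db: float = 25.0,
    seed: int = 12345,
):
    """Build the canonical moan template from a clean synthetic recording.

    Mirrors field practice: the template is cut from an (emulated) recording
    of a loud, clean call rather than from a noiseless ideal, so its
    background pixels carry realistic noise texture.  Deterministic for
    fixed arguments.
    """
    from .detector import extract_template

    if spec_params is None:
        spec_params = SpectrogramParams()
    onset = 1.0
    scene_len = onset + params.duration + 1.0
    spec = SceneSpec(
        duration=scene_len, sample_rate=sample_rate, full_scale_db=150.0,
        noise=NoiseParams(transient_rate_per_min=0.0),
        schedule=(ScheduledCall(onset, params, target_snr_db=snr_db),),
        seed=seed,
    )
    audio, _ = build_scene(spec)
    return extract_template(audio, onset, onset + params.duration,
                            template_band(params), spec_params)
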