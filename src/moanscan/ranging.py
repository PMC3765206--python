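"""Empirical transmission-loss fitting and single-receiver range estimation.

A moored calibration source of known source level SL and known range r gives
direct measurements of transmission loss TL = SL - RL.  We model it as a
one-parameter logarithmic law

    TL = a * log10(r),     r in metres,

with a = 20 corresponding to spherical spreading.  Fitted from calibration
receptions, the coefficient and its uncertainty then invert a call's
received level into a distance estimate

    r = 10 ** ((SL - RL) / a),

with bounds from the one-standard-deviation corners of (RL, a).  Distance is
strictly decreasing in both RL and a (for SL > RL), so the extremes of the
+-sd box are attained at its corners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationReception",
    "TransmissionLossModel",
    "CallLevelAssumption",
    "DistanceEstimate",
    "fit_tl",
    "fit_tl_summary",
    "estimate_distance",
    "read_receptions_csv",
    "write_receptions_csv",
    "write_model",
    "read_model",
]


@dataclass(frozen=True)
class CalibrationReception:
    """One reception of the calibration source.

    ``source_level`` in dB rms re 1 uPa @ 1 m, ``received_level`` in dB rms
    re 1 uPa, ``range_m`` the known source-receiver distance in metres.
    """

    received_level: float
    source_level: float
    range_m: float
    time: object = None

    def __post_init__(self) -> None:
        if not self.range_m > 1.0:
            raise ValueError("range must exceed 1 m (the source-level reference)")
        if not (math.isfinite(self.received_level) and math.isfinite(self.source_level)):
            raise ValueError("levels must be finite")


@dataclass(frozen=True)
class TransmissionLossModel:
    """TL = coefficient * log10(r); coefficient in dB per decade of range."""

    coefficient: float
    coefficient_sd: float
    n_receptions: int

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError("TL coefficient must be positive")
        if self.coefficient_sd < 0:
            raise ValueError("coefficient sd must be non-negative")

    def predicted_rl(self, source_level: float, range_m: float) -> float:
        """Received level predicted at a given range under the fitted law."""
        return source_level - self.coefficient * math.log10(range_m)


@dataclass(frozen=True)
class CallLevelAssumption:
    """Assumed source level and measured received level of the call to range.

    ``source_level`` dB re 1 uPa @ 1 m; ``received_level`` (mean) and
    ``received_level_sd`` in dB rms re 1 uPa.
    """

    source_level: float
    received_level: float
    received_level_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.source_level <= self.received_level:
            raise ValueError("source level must exceed received level "
                             "(the caller is farther than 1 m)")
        if self.received_level_sd < 0:
            raise ValueError("received-level sd must be non-negative")


@dataclass(frozen=True)
class DistanceEstimate:
    """Central distance and one-sd bounds, metres."""

    r_central: float
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= self.r_central <= self.r_max:
            raise ValueError("require 0 < r_min <= r_central <= r_max")


def fit_tl(receptions) -> TransmissionLossModel:
    """Fit the logarithmic transmission-loss law to calibration receptions.

    Each reception yields a per-event coefficient
    ``a_i = (SL_i - RL_i) / log10(r_i)``; the model coefficient is their
    mean.  With a single moored source (all ranges equal) the coefficient
    spread comes entirely from the received-level spread, so the uncertainty
    is ``sd(RL) / log10(r)``; with mixed ranges it is ``sd(a_i)``.
    """
    receptions = list(receptions)
    if not receptions:
        raise ValueError("need at least one reception")
    a_i = np.array([
        (rc.source_level - rc.received_level) / math.log10(rc.range_m)
        for rc in receptions
    ])
    ranges = np.array([rc.range_m for rc in receptions])
    a = float(a_i.mean())
    n = len(receptions)
    if n == 1:
        a_sd = 0.0
    elif np.allclose(ranges, ranges[0], rtol=1e-9):
        rls = np.array([rc.received_level for rc in receptions])
        a_sd = float(np.std(rls, ddof=1) / math.log10(ranges[0]))
    else:
        a_sd = float(np.std(a_i, ddof=1))
    return TransmissionLossModel(a, a_sd, n)


def fit_tl_summary(
    source_level: float,
    mean_received_level: float,
    received_level_sd: float,
    range_m: float,
    n: int = 1,
) -> TransmissionLossModel:
    """Fit from summary statistics of receptions of one source at one range.

    Equivalent to :func:`fit_tl` on the raw receptions: the coefficient is
    ``(SL - mean RL) / log10(r)`` and its uncertainty maps the received-level
    spread through the fixed range, ``sd(RL) / log10(r)``.
    """
    if not range_m > 1.0:
        raise ValueError("range must exceed 1 m")
    log_r = math.log10(range_m)
    return TransmissionLossModel(
        (source_level - mean_received_level) / log_r,
        received_level_sd / log_r,
        n,
    )


def estimate_distance(tl: TransmissionLossModel, call: CallLevelAssumption) -> DistanceEstimate:
    """Invert the transmission-loss law for a call's distance, with bounds.

    Central estimate ``10**((SL - RL)/a)``; bounds are the min/max of
    ``10**((SL - (RL +- sd)) / (a +- a_sd))`` over the four sign
    combinations.  The bounds are one-sd excursions, not a formal confidence
    interval.
    """
    if tl.coefficient - tl.coefficient_sd <= 0:
        raise ValueError("degenerate model: a - a_sd <= 0")
    sl, rl, sd = call.source_level, call.received_level, call.received_level_sd
    r_central = 10.0 ** ((sl - rl) / tl.coefficient)
    corners = [
        10.0 ** ((sl - (rl + drl)) / (tl.coefficient + da))
        for drl in (-sd, sd)
        for da in (-tl.coefficient_sd, tl.coefficient_sd)
    ]
    return DistanceEstimate(r_central, min(corners), max(corners))


def read_receptions_csv(path) -> list[CalibrationReception]:
    """Columns: received_level_db, source_level_db, range_m[, time]."""
    df = pd.read_csv(path)
    return [
        CalibrationReception(
            float(r.received_level_db), float(r.source_level_db), float(r.range_m),
            getattr(r, "time", None),
        )
        for r in df.itertuples()
    ]


def write_receptions_csv(path, receptions) -> None:
    pd.DataFrame({
        "received_level_db": [r.received_level for r in receptions],
        "source_level_db": [r.source_level for r in receptions],
        "range_m": [r.range_m for r in receptions],
        "time": [r.time for r in receptions],
    }).to_csv(path, index=False)


def write_model(path, model: TransmissionLossModel, provenance: str = "") -> None:
    """Persist a fitted model as a small key: value text file."""
    with open(path, "w") as fh:
        fh.write(f"coefficient_db_per_decade: {model.coefficient!r}\n")
        fh.write(f"coefficient_sd: {model.coefficient_sd!r}\n")
        fh.write(f"n_receptions: {model.n_receptions}\n")
        if provenance:
            fh.write(f"provenance: {provenance}\n")


def read_model(path) -> TransmissionLossModel:
    vals: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if ":" in line:
                k, v = line.split(":", 1)
                vals[k.strip()] = v.strip()
    return TransmissionLossModel(
        float(vals["coefficient_db_per_decade"]),
        float(vals["coefficient_sd"]),
        int(vals["n_receptions"]),
    )
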