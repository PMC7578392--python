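"""Frame-wise f0 estimation and third-wise summary features.

A conversation is split into elapsed-time thirds; for each speaker the mean
f0 (feature k = 1) and the f0 interquartile range (k = 2) are summarised
over the first and last third, giving the dyad's start point S and end
point E in (participant, partner) Hz space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datatypes import TIME_TOL, DyadFeatures, F0Track, ValidationError

log = logging.getLogger(__name__)

#: search band of the pitch estimator per speaker class, Hz.  The child and
#: teen bands follow developmental-acoustics conventions; adult bands mirror
#: the nearest child/teen class and are configurable.
DEFAULT_PITCH_RANGES: dict[str, tuple[float, float]] = {
    "child": (100.0, 450.0),
    "teen_girl": (100.0, 400.0),
    "teen_boy": (50.0, 350.0),
    "adult_female": (100.0, 400.0),
    "adult_male": (50.0, 350.0),
}

#: minimum voiced frames per speaker per third for a usable feature
DEFAULT_MIN_FRAMES = 50

#: normalized-autocorrelation peak below which a frame is unvoiced
DEFAULT_VOICING_THRESHOLD = 0.45


@dataclass(frozen=True)
class SpeakerClassRange:
    """Pitch search band [floor, ceiling] in Hz for one speaker class."""

    speaker_class: str
    floor: float
    ceiling: float

    def __post_init__(self) -> None:
        if not 0 < self.floor < self.ceiling:
            raise ValidationError("need 0 < floor < ceiling")

    @classmethod
    def for_class(cls, speaker_class: str,
                  ranges: dict[str, tuple[float, float]] = DEFAULT_PITCH_RANGES):
        floor, ceiling = ranges[speaker_class]
        return cls(speaker_class, floor, ceiling)


@dataclass(frozen=True)
class ThirdWindow:
    """One analysis window: the first or last third of the timeline."""

    label: str  # "first" | "last"
    start: float
    end: float


@dataclass(frozen=True)
class ThirdSummary:
    mean_f0: float
    iqr_f0: float
    n_frames: int
    missing: bool


def partition_thirds(duration: float) -> tuple[ThirdWindow, ThirdWindow]:
    """Split [0, duration) into its first and last elapsed-time thirds.

    The middle third is deliberately unused: entrainment is measured as the
    change between the opening and closing stretch of the conversation.
    """
    if not duration > 0:
        raise ValidationError(f"duration must be positive, got {duration}")
    return (
        ThirdWindow("first", 0.0, duration / 3.0),
        ThirdWindow("last", 2.0 * duration / 3.0, duration),
    )


def estimate_f0(
    waveform: np.ndarray,
    rate: float,
    pitch_range: SpeakerClassRange,
    step: float = 0.010,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
    speaker_id: str = "",
) -> F0Track:
    """Autocorrelation pitch tracking at a 10 ms hop.

    Each frame takes a window of three floor-periods, computes the
    normalized autocorrelation over lags corresponding to
    [floor, ceiling] Hz, and keeps the highest interior peak; frames whose
    peak falls below ``voicing_threshold`` (or that are near-silent) are
    unvoiced.  The peak lag is refined by parabolic interpolation, so a
    periodic signal inside the band is recovered to well under 1%.
    """
    if rate < 2.0 * pitch_range.ceiling:
        raise ValidationError(
            f"sampling rate {rate} Hz too low for ceiling {pitch_range.ceiling} Hz"
        )
    x = np.asarray(waveform, dtype=float)
    if x.ndim == 2:  # stereo: average channels
        x = x.mean(axis=1)
    window = int(round(3.0 * rate / pitch_range.floor))
    lag_min = max(int(np.floor(rate / pitch_range.ceiling)), 2)
    lag_max = int(np.ceil(rate / pitch_range.floor))
    hop = int(round(step * rate))
    n_frames = max((len(x) - window - lag_max) // hop + 1, 0)
    if n_frames <= 0:
        return F0Track(speaker_id, np.array([]), np.array([]),
                       np.array([], dtype=bool), step)

    times = (np.arange(n_frames) * hop + window / 2.0) / rate
    f0 = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    silence_floor = 1e-4 * (np.max(np.abs(x)) + 1e-300)
    energy = np.concatenate([[0.0], np.cumsum(x * x)])

    for i in range(n_frames):
        i0 = i * hop
        anchor = x[i0:i0 + window]
        e0 = energy[i0 + window] - energy[i0]
        if np.sqrt(e0 / window) < silence_floor:
            continue
        # cross-correlation of the anchor with lagged copies of itself
        segment = x[i0:i0 + window + lag_max]
        corr = np.correlate(segment, anchor, mode="valid")  # lags 0..lag_max
        lag_energy = energy[i0 + np.arange(lag_max + 1) + window] - energy[i0 + np.arange(lag_max + 1)]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = corr / np.sqrt(e0 * lag_energy)
        band = r[lag_min:lag_max + 1]
        if len(band) < 3:
            continue
        # interior local maxima only: a boundary ridge is not a pitch peak
        interior = (band[1:-1] >= band[:-2]) & (band[1:-1] > band[2:])
        candidates = np.flatnonzero(interior) + 1
        if len(candidates) == 0:
            continue
        strongest = np.max(band[candidates])
        if strongest < voicing_threshold:
            continue
        # a perfectly periodic signal peaks equally at every multiple of its
        # period: break near-ties toward the shortest lag to avoid
        # subharmonic (octave-down) errors
        best = candidates[band[candidates] >= strongest - 0.02][0]
        # parabolic refinement around the integer lag
        y0, y1, y2 = band[best - 1], band[best], band[best + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        lag = lag_min + best + np.clip(shift, -0.5, 0.5)
        f0[i] = rate / lag
        voiced[i] = True

    return F0Track(speaker_id, times, f0, voiced, step)


def third_features(
    track: F0Track,
    window: ThirdWindow,
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> ThirdSummary:
    """Mean f0 and f0 IQR over the voiced frames inside one third.

    The track must already be linguistic-filtered.  Quantiles use linear
    interpolation between order statistics.  Fewer than ``min_frames``
    voiced frames yields a flagged missing summary rather than an error.
    """
    in_window = (track.times >= window.start - TIME_TOL) & (track.times < window.end - TIME_TOL)
    values = track.f0[in_window & track.voiced]
    n = len(values)
    if n < min_frames:
        return ThirdSummary(np.nan, np.nan, n, missing=True)
    q1, q3 = np.percentile(values, [25.0, 75.0])
    return ThirdSummary(float(np.mean(values)), float(q3 - q1), n, missing=False)


def build_dyad_features(
    track_participant: F0Track,
    track_partner: F0Track,
    duration: float,
    dyad_id: str = "",
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> DyadFeatures:
    """Compose the thirds partition with per-speaker summaries.

    Axis 1 of every feature point is the participant, axis 2 the partner.
    A feature k is usable only when both speakers have enough voiced frames
    in both thirds; unusable dyads are flagged (and logged) so downstream
    statistics can exclude them.
    """
    first, last = partition_thirds(duration)
    summaries = {}
    for axis, track in ((1, track_participant), (2, track_partner)):
        for win in (first, last):
            summaries[(axis, win.label)] = third_features(track, win, min_frames)

    start, end, usable, n_frames = {}, {}, {}, {}
    for k, attr in ((1, "mean_f0"), (2, "iqr_f0")):
        s1, s2 = summaries[(1, "first")], summaries[(2, "first")]
        e1, e2 = summaries[(1, "last")], summaries[(2, "last")]
        ok = not any(s.missing for s in (s1, s2, e1, e2))
        start[k] = (getattr(s1, attr), getattr(s2, attr))
        end[k] = (getattr(e1, attr), getattr(e2, attr))
        usable[k] = ok
        if not ok:
            log.warning(
                "dyad %s: feature k=%d unusable (frames: %s)",
                dyad_id, k,
                {key: s.n_frames for key, s in summaries.items()},
            )
    for key, s in summaries.items():
        n_frames[key] = s.n_frames
    return DyadFeatures(dyad_id=dyad_id, start=start, end=end,
                        usable=usable, n_frames=n_frames)
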