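"""Core containers for dyadic prosodic-entrainment analysis.

The pipeline operates on two-speaker conversations annotated with Praat
TextGrid interval tiers, frame-wise fundamental-frequency (f0) tracks
sampled at a fixed step (10 ms by default), and a per-dyad metadata table.
All containers are plain dataclasses validated on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

SPEAKER_CLASSES = ("child", "teen_girl", "teen_boy", "adult_female", "adult_male")

#: frame membership in an interval uses half-open [start, end) at this tolerance
TIME_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass(frozen=True)
class Interval:
    """A labelled time interval on one speaker's tier.

    ``is_linguistic`` is assigned once, when the annotation is read or
    generated; downstream code never re-inspects the label string.
    """

    start: float
    end: float
    label: str
    is_linguistic: bool

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"interval [{self.start}, {self.end}] {self.label!r}: start must be < end"
            )

    def contains(self, t: float) -> bool:
        """Half-open membership: start <= t < end (tolerance ``TIME_TOL``)."""
        return self.start - TIME_TOL <= t < self.end - TIME_TOL


@dataclass
class SpeakerTier:
    """All annotated intervals produced by one speaker in a conversation."""

    speaker_id: str
    intervals: list[Interval]
    speaker_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.speaker_class is not None and self.speaker_class not in SPEAKER_CLASSES:
            raise ValidationError(
                f"unknown speaker_class {self.speaker_class!r}; expected one of {SPEAKER_CLASSES}"
            )
        prev_end = -np.inf
        for iv in self.intervals:
            if iv.start < prev_end - TIME_TOL:
                raise ValidationError(
                    f"tier {self.speaker_id!r}: intervals overlap or are out of order at {iv.start}"
                )
            prev_end = iv.end

    @property
    def linguistic_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.is_linguistic]


@dataclass
class AnnotatedConversation:
    """A two-speaker conversation: one interval tier per speaker.

    Tier order is (participant, partner).  Tiers from different speakers may
    overlap in time (simultaneous speech); intervals within a tier may not.
    """

    conversation_id: str
    duration: float
    tiers: list[SpeakerTier]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("conversation duration must be > 0")
        if len(self.tiers) != 2:
            raise ValidationError(
                f"conversation {self.conversation_id!r} needs exactly 2 speaker tiers, "
                f"got {len(self.tiers)}"
            )
        for tier in self.tiers:
            for iv in tier.intervals:
                if iv.start < -TIME_TOL or iv.end > self.duration + 1e-6:
                    raise ValidationError(
                        f"tier {tier.speaker_id!r}: interval [{iv.start}, {iv.end}] "
                        f"outside [0, {self.duration}]"
                    )

    @property
    def participant_tier(self) -> SpeakerTier:
        return self.tiers[0]

    @property
    def partner_tier(self) -> SpeakerTier:
        return self.tiers[1]

    def tier_for(self, speaker_id: str) -> SpeakerTier:
        for tier in self.tiers:
            if tier.speaker_id == speaker_id:
                return tier
        raise KeyError(f"no tier for speaker {speaker_id!r}")


@dataclass
class F0Track:
    """Frame-wise f0 samples with a voicing mask for one speaker.

    Frames are equally spaced at ``step`` seconds (10 ms default).  ``f0`` is
    in Hz and must be positive wherever ``voiced`` is True; unvoiced frames
    may carry any placeholder (conventionally 0).
    """

    speaker_id: str
    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray
    step: float = 0.010

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if not (len(self.times) == len(self.f0) == len(self.voiced)):
            raise ValidationError("times, f0 and voiced must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValidationError("frame times must be strictly increasing")
            if np.any(np.abs(dt - self.step) > 1e-6):
                raise ValidationError(
                    f"frame times must be equally spaced at step={self.step} s (tol 1e-6)"
                )
        if np.any(self.f0[self.voiced] <= 0):
            raise ValidationError("voiced frames must have f0 > 0")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())

    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]

    def copy(self) -> "F0Track":
        return F0Track(
            speaker_id=self.speaker_id,
            times=self.times.copy(),
            f0=self.f0.copy(),
            voiced=self.voiced.copy(),
            step=self.step,
        )


@dataclass
class DyadMetadata:
    """Participant-level covariates for one conversational dyad.

    ``group`` is the participant's diagnostic group (ASD or NT); the adult
    conversation partner carries no test scores.  Standard scores
    (CELF core language, KBIT non-verbal/composite IQ) have mean 100, SD 15
    in the norming population.
    """

    dyad_id: str
    participant_id: str
    partner_id: str
    group: str
    age: float
    gender: str
    celf_core: float
    nonverbal_iq: float
    participant_class: str
    partner_class: str
    composite_iq: Optional[float] = None
    age_range: tuple[float, float] = (9.0, 15.0)

    def __post_init__(self) -> None:
        if self.group not in ("ASD", "NT"):
            raise ValidationError(f"group must be ASD or NT, got {self.group!r}")
        if self.gender not in ("F", "M"):
            raise ValidationError(f"gender must be F or M, got {self.gender!r}")
        lo, hi = self.age_range
        if not lo <= self.age <= hi:
            raise ValidationError(f"age {self.age} outside plausible range [{lo}, {hi}]")
        for name in ("celf_core", "nonverbal_iq"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.composite_iq is not None and self.composite_iq <= 0:
            raise ValidationError("composite_iq must be positive")
        for name in ("participant_class", "partner_class"):
            if getattr(self, name) not in SPEAKER_CLASSES:
                raise ValidationError(f"unknown {name} {getattr(self, name)!r}")


@dataclass
class FeaturePoint:
    """One speaker's summary over one conversation third."""

    value: float
    n_frames: int
    missing: bool = False


@dataclass
class DyadFeatures:
    """Start/end feature points for a dyad.

    For each feature k (1 = mean f0, 2 = f0 interquartile range) the dyad is
    a point in (participant, partner) Hz space: ``start[k]`` from the first
    third of the conversation and ``end[k]`` from the last third.  Axis 1 is
    always the participant, axis 2 the partner.
    """

    dyad_id: str
    #: k -> (participant Hz, partner Hz) over the first third
    start: dict[int, tuple[float, float]]
    #: k -> (participant Hz, partner Hz) over the last third
    end: dict[int, tuple[float, float]]
    #: k -> whether both windows had enough voiced frames for both speakers
    usable: dict[int, bool]
    #: (speaker axis, window label) -> voiced frame count
    n_frames: dict[tuple[int, str], int] = field(default_factory=dict)

    def point_start(self, k: int) -> tuple[float, float]:
        return self.start[k]

    def point_end(self, k: int) -> tuple[float, float]:
        return self.end[k]


def feature_names() -> dict[int, str]:
    """The feature index -> name mapping used in exported tables."""
    return {1: "mean_f0", 2: "f0_iqr"}
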