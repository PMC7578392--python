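"""Distance-to-line entrainment scoring for a conversational dyad.

A dyad's joint f0 state is a point (participant, partner) in Hz space.
Perfect register matching lies on the line y = x; when the two speakers
naturally sit an octave apart (a teen boy talking to an adult woman) the
appropriate locus is the half-matching line, where the lower voice is one
octave below the higher.  Entrainment over a conversation is the reduction
in perpendicular distance to that line between the first and last third:

    delta_ent = d1 - d2            (positive = convergence, Hz)

Each speaker's responsibility is their share of the total along-axis
feature change, resp_i = d_i / (d3 + d4) with d3 = |participant change| and
d4 = |partner change|; the signed contribution carries the direction of
delta_ent, and the adjusted contribution scales responsibility by the
dyad-level delta_ent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .datatypes import DyadFeatures, ValidationError

#: |delta_ent| at or below this is maintenance (no entrainment), Hz
DEFAULT_MAINTENANCE_BAND = 1.0
#: a conversation counts as converging when delta_ent strictly exceeds this, Hz
DEFAULT_CONVERGE_THRESHOLD = 2.0

#: speaker-class pairs (unordered) whose natural registers sit an octave apart
OCTAVE_PAIRS = frozenset({frozenset({"teen_boy", "adult_female"})})

CONVERGENCE = "convergence"
MAINTENANCE = "maintenance"
DIVERGENCE = "divergence"


@dataclass(frozen=True)
class ReferenceLine:
    """The register-matching locus the dyad is scored against.

    ``slope`` is 1.0 for the matching line (equal f0) or 0.5 for the
    half-matching line (octave offset).  ``halved_axis`` records which axis
    holds the lower-register speaker when slope is 0.5, so callers never
    have to order the speakers themselves: the line in (participant,
    partner) space is partner = effective_slope * participant.
    """

    slope: float = 1.0
    selection_reason: str = ""
    halved_axis: Optional[str] = None  # None | "participant" | "partner"

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValidationError("line slope must be positive")
        if self.slope != 1.0 and self.halved_axis not in ("participant", "partner"):
            raise ValidationError("a non-unit slope must name the halved axis")

    @property
    def effective_slope(self) -> float:
        """Slope of the line with the participant on the x axis."""
        if self.slope == 1.0 or self.halved_axis == "partner":
            return self.slope
        return 1.0 / self.slope  # participant is the halved (lower) axis


def select_reference_line(
    participant_class: str,
    partner_class: str,
    override: Optional[float] = None,
) -> ReferenceLine:
    """Choose the matching (slope 1) or half-matching (slope 1/2) line.

    The half-matching line applies only to dyads pairing an adult female
    with a teenage boy — the one pairing whose comfortable registers sit
    roughly an octave apart; the teen boy is the halved (lower) axis.  A
    pre-voice-change child with an adult female partner stays on the
    matching line.  ``override`` forces an effective slope for sensitivity
    analyses.
    """
    if override is not None:
        return ReferenceLine(
            slope=override,
            selection_reason=f"override slope {override}",
            halved_axis="partner" if override != 1.0 else None,
        )
    if frozenset({participant_class, partner_class}) in OCTAVE_PAIRS:
        halved = "participant" if participant_class == "teen_boy" else "partner"
        return ReferenceLine(
            slope=0.5,
            selection_reason=f"octave-offset registers ({participant_class} with {partner_class})",
            halved_axis=halved,
        )
    return ReferenceLine(slope=1.0, selection_reason="register-matched classes")


def point_to_line_distance(point: tuple[float, float], line: ReferenceLine) -> float:
    """Perpendicular (minimum Euclidean) distance from a point to the line.

    The line passes through the origin with the dyad's effective slope m in
    (participant, partner) space: d = |m*x - y| / sqrt(m^2 + 1).
    """
    x, y = point
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValidationError(f"point must be finite, got {point}")
    m = line.effective_slope
    return abs(m * x - y) / np.hypot(m, 1.0)


def signed_line_offset(point: tuple[float, float], line: ReferenceLine) -> float:
    """Signed perpendicular offset (positive below the line in y)."""
    x, y = point
    m = line.effective_slope
    return (m * x - y) / np.hypot(m, 1.0)


def delta_entrainment(feat: DyadFeatures, line: ReferenceLine, k: int) -> float:
    """delta_ent = d1 - d2: distance-to-line at the start minus at the end."""
    if not feat.usable.get(k, False):
        raise ValidationError(f"dyad {feat.dyad_id!r}: feature k={k} not usable")
    d1 = point_to_line_distance(feat.point_start(k), line)
    d2 = point_to_line_distance(feat.point_end(k), line)
    return d1 - d2


def along_axis_changes(feat: DyadFeatures, k: int) -> tuple[float, float]:
    """(d3, d4): absolute per-speaker feature change start -> end, Hz."""
    s1, s2 = feat.point_start(k)
    e1, e2 = feat.point_end(k)
    return abs(e1 - s1), abs(e2 - s2)


def speaker_responsibility(feat: DyadFeatures, k: int) -> tuple[float, float, bool]:
    """Each speaker's share of the total along-axis change.

    Returns (resp_participant, resp_partner, degenerate).  When neither
    speaker moved at all (d3 + d4 = 0) responsibility is split evenly and
    flagged degenerate.
    """
    d3, d4 = along_axis_changes(feat, k)
    total = d3 + d4
    if total == 0:
        return 0.5, 0.5, True
    return d3 / total, d4 / total, False


def signed_contribution(delta_ent: float, resp: float) -> float:
    """sign(delta_ent) * resp: a fraction in [-1, 1], zero at delta_ent = 0."""
    if not 0.0 <= resp <= 1.0:
        raise ValidationError(f"responsibility must be in [0, 1], got {resp}")
    return float(np.sign(delta_ent)) * resp


def adjusted_contribution(delta_ent: float, resp: float) -> float:
    """delta_ent * resp: the speaker's Hz-scale share of the dyad's change."""
    if not 0.0 <= resp <= 1.0:
        raise ValidationError(f"responsibility must be in [0, 1], got {resp}")
    return delta_ent * resp


def classify_entrainment(
    delta_ent: float,
    maintenance_band: float = DEFAULT_MAINTENANCE_BAND,
) -> str:
    """Convergence / maintenance / divergence with an inclusive band.

    |delta_ent| of ``maintenance_band`` Hz or less counts as maintenance.
    """
    if not np.isfinite(delta_ent):
        raise ValidationError("delta_ent must be finite")
    if abs(delta_ent) <= maintenance_band:
        return MAINTENANCE
    return CONVERGENCE if delta_ent > 0 else DIVERGENCE


def gap_change(feat: DyadFeatures, k: int) -> float:
    """Auxiliary raw-gap metric: |S1-S2| at the start minus at the end.

    Positive when the raw between-speaker f0 gap shrank.  Exported next to
    the perpendicular-distance delta_ent because group-level Hz summaries
    can be read on either scale.
    """
    s1, s2 = feat.point_start(k)
    e1, e2 = feat.point_end(k)
    return abs(s1 - s2) - abs(e1 - e2)


@dataclass
class EntrainmentResult:
    """All dyad-level entrainment quantities for one feature k."""

    dyad_id: str
    k: int
    d1: float
    d2: float
    delta_ent: float
    d3: float
    d4: float
    resp1: float
    resp2: float
    contribution1: float
    contribution2: float
    adjusted1: float
    adjusted2: float
    classification: str
    gap_change: float
    line_slope: float
    degenerate_responsibility: bool = False


def compute_entrainment(
    feat: DyadFeatures,
    line: ReferenceLine,
    k: int,
    maintenance_band: float = DEFAULT_MAINTENANCE_BAND,
    min_over_lines: bool = False,
) -> EntrainmentResult:
    """Full entrainment scoring of one dyad for one feature.

    ``min_over_lines`` is a sensitivity option that scores against the
    closer of the matching and half-matching lines at each end instead of
    the single class-selected line.
    """
    if min_over_lines:
        lines = [
            ReferenceLine(1.0, "min-over-lines"),
            ReferenceLine(0.5, "min-over-lines", halved_axis=line.halved_axis or "partner"),
        ]
        d1 = min(point_to_line_distance(feat.point_start(k), l) for l in lines)
        d2 = min(point_to_line_distance(feat.point_end(k), l) for l in lines)
    else:
        d1 = point_to_line_distance(feat.point_start(k), line)
        d2 = point_to_line_distance(feat.point_end(k), line)
    delta = d1 - d2
    resp1, resp2, degenerate = speaker_responsibility(feat, k)
    d3, d4 = along_axis_changes(feat, k)
    return EntrainmentResult(
        dyad_id=feat.dyad_id,
        k=k,
        d1=d1,
        d2=d2,
        delta_ent=delta,
        d3=d3,
        d4=d4,
        resp1=resp1,
        resp2=resp2,
        contribution1=signed_contribution(delta, resp1),
        contribution2=signed_contribution(delta, resp2),
        adjusted1=adjusted_contribution(delta, resp1),
        adjusted2=adjusted_contribution(delta, resp2),
        classification=classify_entrainment(delta, maintenance_band),
        gap_change=gap_change(feat, k),
        line_slope=line.effective_slope,
        degenerate_responsibility=degenerate,
    )


def count_converging(
    deltas: Iterable[float],
    threshold: float = DEFAULT_CONVERGE_THRESHOLD,
) -> tuple[int, float]:
    """How many dyads converged by strictly more than ``threshold`` Hz."""
    values = list(deltas)
    if not values:
        raise ValidationError("need at least one dyad")
    count = sum(1 for d in values if d > threshold)
    return count, count / len(values)
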