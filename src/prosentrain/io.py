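"""Readers and writers for the formats the pipeline touches.

Praat TextGrid (long and short text dialects) for utterance annotations,
Praat PitchTier or plain CSV for frame-wise pitch tracks, and CSV for the
participant-metadata table.  The linguistic/non-linguistic decision is made
once, at parse time, from a configurable label-exclusion rule and stored as
an explicit flag on each interval.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .datatypes import (
    TIME_TOL,
    AnnotatedConversation,
    DyadMetadata,
    F0Track,
    Interval,
    SpeakerTier,
    ValidationError,
)

#: labels treated as non-linguistic by default (case-insensitive, stripped);
#: covers laughter, humming, vocal stereotypy, noise and silence markers
DEFAULT_EXCLUDED_LABELS = frozenset(
    {"laughter", "hum", "stereotypy", "noise", "sil", "sp", ""}
)

METADATA_COLUMNS = [
    "dyad_id",
    "participant_id",
    "partner_id",
    "group",
    "age",
    "gender",
    "celf_core",
    "nonverbal_iq",
    "composite_iq",
    "participant_class",
    "partner_class",
]


class TextGridParseError(ValueError):
    """Malformed TextGrid content; the message names the offending line."""


class TextGridStructureError(ValueError):
    """Structurally valid TextGrid that does not fit the two-speaker layout."""


def default_linguistic_rule(label: str, excluded: Iterable[str] = DEFAULT_EXCLUDED_LABELS):
    """True when ``label`` marks a linguistically meaningful utterance."""
    excluded = {e.strip().lower() for e in excluded}
    return label.strip().lower() not in excluded


# ---------------------------------------------------------------------------
# TextGrid
# ---------------------------------------------------------------------------

def _tokenize_textgrid(text: str) -> list[tuple[object, int]]:
    """Reduce a TextGrid (either dialect) to its (value, line) token stream.

    Both dialects carry the same ordered sequence of quoted strings and bare
    numbers; keys, ``item [i]:`` headers and ``<exists>`` flags are
    punctuation around it.  Bracketed indices are skipped so they are not
    mistaken for data.
    """
    tokens: list[tuple[object, int]] = []
    i, n, line = 0, len(text), 1
    while i < n:
        c = text[i]
        if c == "\n":
            line += 1
            i += 1
        elif c == '"':
            start_line = line
            i += 1
            buf = []
            while True:
                if i >= n:
                    raise TextGridParseError(f"line {start_line}: unterminated string")
                if text[i] == '"':
                    if i + 1 < n and text[i + 1] == '"':  # doubled-quote escape
                        buf.append('"')
                        i += 2
                        continue
                    i += 1
                    break
                if text[i] == "\n":
                    line += 1
                buf.append(text[i])
                i += 1
            tokens.append(("".join(buf), start_line))
        elif c == "[":
            while i < n and text[i] != "]":
                if text[i] == "\n":
                    line += 1
                i += 1
            i += 1
        elif c.isdigit() or (c in "+-." and i + 1 < n and (text[i + 1].isdigit() or text[i + 1] == ".")):
            j = i
            while j < n and (text[j].isdigit() or text[j] in "+-.eE"):
                j += 1
            try:
                value = float(text[i:j])
            except ValueError:
                raise TextGridParseError(f"line {line}: bad number {text[i:j]!r}")
            tokens.append((value, line))
            i = j
        else:
            i += 1
    return tokens


class _TokenStream:
    def __init__(self, tokens: list[tuple[object, int]]):
        self._tokens = tokens
        self._pos = 0

    def _take(self) -> tuple[object, int]:
        if self._pos >= len(self._tokens):
            last_line = self._tokens[-1][1] if self._tokens else 0
            raise TextGridParseError(f"line {last_line}: unexpected end of file")
        tok = self._tokens[self._pos]
        self._pos += 1
        return tok

    def number(self) -> float:
        value, line = self._take()
        if not isinstance(value, float):
            raise TextGridParseError(f"line {line}: expected a number, got {value!r}")
        return value

    def string(self) -> str:
        value, line = self._take()
        if not isinstance(value, str):
            raise TextGridParseError(f"line {line}: expected a string, got {value!r}")
        return value


def parse_textgrid(
    text: Union[str, bytes],
    linguistic_rule=default_linguistic_rule,
    conversation_id: str = "",
) -> AnnotatedConversation:
    """Parse a TextGrid (long or short dialect) into an AnnotatedConversation.

    The first interval tier becomes the participant, the second the partner;
    any further interval tiers are rejected only if fewer than two exist.
    ``linguistic_rule(label) -> bool`` assigns the is_linguistic flag; the
    default excludes empty labels and common non-speech markers (laughter,
    humming, stereotypy, noise, silence).
    """
    if isinstance(text, bytes):
        text = decode_praat_bytes(text)
    stream = _TokenStream(_tokenize_textgrid(text))
    file_type = stream.string()
    object_class = stream.string()
    if file_type != "ooTextFile" or object_class != "TextGrid":
        raise TextGridParseError(
            f"line 1: not a TextGrid (File type {file_type!r}, class {object_class!r})"
        )
    stream.number()  # global xmin
    xmax = stream.number()
    n_tiers = int(stream.number())
    tiers: list[SpeakerTier] = []
    for _ in range(n_tiers):
        tier_class = stream.string()
        name = stream.string()
        stream.number()  # tier xmin
        stream.number()  # tier xmax
        size = int(stream.number())
        if tier_class == "IntervalTier":
            intervals = []
            for _ in range(size):
                ivl_xmin = stream.number()
                ivl_xmax = stream.number()
                label = stream.string()
                intervals.append(
                    Interval(ivl_xmin, ivl_xmax, label, bool(linguistic_rule(label)))
                )
            tiers.append(SpeakerTier(speaker_id=name, intervals=intervals))
        elif tier_class == "TextTier":  # point tier: skip its (time, mark) pairs
            for _ in range(size):
                stream.number()
                stream.string()
        else:
            raise TextGridParseError(f"unknown tier class {tier_class!r}")
    if len(tiers) < 2:
        raise TextGridStructureError(
            f"need at least 2 interval tiers (one per speaker), found {len(tiers)}"
        )
    return AnnotatedConversation(
        conversation_id=conversation_id or tiers[0].speaker_id,
        duration=xmax,
        tiers=tiers[:2],
    )


def decode_praat_bytes(raw: bytes) -> str:
    """Decode Praat text output: UTF-8 first, UTF-16 (BOM) fallback."""
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("utf-16")


def _q(label: str) -> str:
    return '"' + label.replace('"', '""') + '"'


def write_textgrid(conv: AnnotatedConversation) -> str:
    """Serialize to the long TextGrid dialect (times at 1e-6 s precision)."""
    out = _io.StringIO()
    w = out.write
    w('File type = "ooTextFile"\n')
    w('Object class = "TextGrid"\n\n')
    w("xmin = 0\n")
    w(f"xmax = {conv.duration:.6f}\n")
    w("tiers? <exists>\n")
    w(f"size = {len(conv.tiers)}\n")
    w("item []:\n")
    for t, tier in enumerate(conv.tiers, start=1):
        w(f"    item [{t}]:\n")
        w('        class = "IntervalTier"\n')
        w(f"        name = {_q(tier.speaker_id)}\n")
        w("        xmin = 0\n")
        w(f"        xmax = {conv.duration:.6f}\n")
        w(f"        intervals: size = {len(tier.intervals)}\n")
        for i, iv in enumerate(tier.intervals, start=1):
            w(f"        intervals [{i}]:\n")
            w(f"            xmin = {iv.start:.6f}\n")
            w(f"            xmax = {iv.end:.6f}\n")
            w(f"            text = {_q(iv.label)}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Pitch tracks
# ---------------------------------------------------------------------------

def read_f0_track(
    source: Union[str, Path],
    speaker_id: str = "",
    step: float = 0.010,
) -> F0Track:
    """Read a pitch track from CSV text/path (columns time,f0,voiced) or
    PitchTier text.

    CSV rows must be time-sorted and equally spaced at ``step``; unvoiced
    rows may carry f0 = 0 or empty.  A PitchTier stores voiced points only,
    so its points are snapped onto a regular ``step`` grid and the remaining
    frames are marked unvoiced.
    """
    text = None
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        if "\n" in source or "," in source:
            text = source
        else:
            text = Path(source).read_text()
    if text is None:
        raise TypeError("source must be CSV/PitchTier text or a path")
    if "PitchTier" in text[:200]:
        return _read_pitchtier(text, speaker_id=speaker_id, step=step)
    table = pd.read_csv(_io.StringIO(text), comment="#")
    missing = {"time", "f0", "voiced"} - set(table.columns)
    if missing:
        raise ValidationError(f"pitch-track CSV missing columns: {sorted(missing)}")
    if len(table) == 0:
        return F0Track(speaker_id, np.array([]), np.array([]), np.array([], dtype=bool), step)
    times = table["time"].to_numpy(dtype=float)
    f0 = pd.to_numeric(table["f0"], errors="coerce").fillna(0.0).to_numpy(dtype=float)
    voiced = table["voiced"].astype(bool).to_numpy()
    if np.any(np.diff(times) <= 0):
        raise ValidationError("pitch-track times must be strictly increasing")
    if np.any(f0[voiced] <= 0):
        raise ValidationError("voiced frames must have positive f0")
    return F0Track(speaker_id, times, f0, voiced, step)


def _read_pitchtier(text: str, speaker_id: str, step: float) -> F0Track:
    stream = _TokenStream(_tokenize_textgrid(text))
    file_type = stream.string()
    object_class = stream.string()
    if file_type != "ooTextFile" or object_class != "PitchTier":
        raise TextGridParseError(f"not a PitchTier (class {object_class!r})")
    xmin = stream.number()
    xmax = stream.number()
    size = int(stream.number())
    n_frames = max(int(round((xmax - xmin) / step)), size)
    times = xmin + step * np.arange(n_frames)
    f0 = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    for _ in range(size):
        t = stream.number()
        value = stream.number()
        idx = int(round((t - xmin) / step))
        if 0 <= idx < n_frames and value > 0:
            f0[idx] = value
            voiced[idx] = True
    return F0Track(speaker_id, times, f0, voiced, step)


def write_f0_track(track: F0Track, path: Optional[Union[str, Path]] = None) -> str:
    """Write a pitch track as CSV (time,f0,voiced); returns the text."""
    frame = pd.DataFrame(
        {
            "time": np.round(track.times, 6),
            "f0": np.round(track.f0, 4),
            "voiced": track.voiced.astype(int),
        }
    )
    text = frame.to_csv(index=False)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Linguistic filtering
# ---------------------------------------------------------------------------

def filter_linguistic(track: F0Track, tier: SpeakerTier) -> F0Track:
    """Silence every frame outside the union of linguistic intervals.

    Frame membership is half-open [start, end): a frame exactly at an
    interval's end belongs to the next interval (or to silence).  The
    operation only ever clears voicing, so it is monotone and idempotent.
    """
    keep = np.zeros(len(track), dtype=bool)
    for iv in tier.linguistic_intervals:
        keep |= (track.times >= iv.start - TIME_TOL) & (track.times < iv.end - TIME_TOL)
    out = track.copy()
    out.voiced &= keep
    return out


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(source: Union[str, Path]) -> list[DyadMetadata]:
    """Read the participant-metadata CSV into DyadMetadata records."""
    if isinstance(source, str) and "\n" in source:
        table = pd.read_csv(_io.StringIO(source))
    else:
        table = pd.read_csv(source)
    missing = set(METADATA_COLUMNS) - {"composite_iq"} - set(table.columns)
    if missing:
        raise ValidationError(f"metadata CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        composite = row.get("composite_iq")
        records.append(
            DyadMetadata(
                dyad_id=str(row["dyad_id"]),
                participant_id=str(row["participant_id"]),
                partner_id=str(row["partner_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
                celf_core=float(row["celf_core"]),
                nonverbal_iq=float(row["nonverbal_iq"]),
                composite_iq=None if pd.isna(composite) else float(composite),
                participant_class=str(row["participant_class"]),
                partner_class=str(row["partner_class"]),
            )
        )
    return records


def write_metadata(records: list[DyadMetadata], path: Optional[Union[str, Path]] = None) -> str:
    rows = []
    for m in records:
        rows.append(
            {
                "dyad_id": m.dyad_id,
                "participant_id": m.participant_id,
                "partner_id": m.partner_id,
                "group": m.group,
                "age": round(m.age, 2),
                "gender": m.gender,
                "celf_core": round(m.celf_core, 1),
                "nonverbal_iq": round(m.nonverbal_iq, 1),
                "composite_iq": "" if m.composite_iq is None else round(m.composite_iq, 1),
                "participant_class": m.participant_class,
                "partner_class": m.partner_class,
            }
        )
    text = pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(index=False)
    if path is not None:
        Path(path).write_text(text)
    return text
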