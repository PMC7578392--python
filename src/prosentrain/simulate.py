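"""Synthetic dyadic conversations with known ground-truth entrainment.

The generator emulates the structure of a goal-directed child/teen vs.
adult-assistant conversation: two speakers in distinct f0 registers taking
alternating turns, frame-wise pitch tracks at 10 ms, TextGrid-style
utterance annotations, and a participant-metadata table whose covariate
distributions follow the study cohort (12 ASD and 12 matched neurotypical
participants aged 9-15).

Entrainment is programmed in feature space: each speaker's third-wise mean
f0 targets are constructed so that the dyad's (start, end) points yield
exactly the requested perpendicular-distance change toward (or away from)
the dyad's reference line, with the along-axis movement split between the
speakers by a responsibility fraction.  Frames are then rendered as target
plus Gaussian noise, which keeps the ground truth exact at zero noise and
unbiased otherwise.  ASD participants additionally emit occasional
non-linguistic vocalizations (laughter, humming, stereotypy) at twice
their register, so a pipeline that skips the linguistic filter is
measurably biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as pio
from .datatypes import (
    AnnotatedConversation,
    DyadMetadata,
    F0Track,
    Interval,
    SpeakerTier,
)
from .entrainment import ReferenceLine, select_reference_line, signed_line_offset
from .features import DEFAULT_PITCH_RANGES

NONSPEECH_LABELS = ("laughter", "hum", "stereotypy")

#: normal-distribution IQR per unit SD
_IQR_PER_SD = 1.3489795003921634


class InfeasibleDriftError(ValueError):
    """The programmed drift cannot be realised in the drawn registers."""


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the study conditions: 12 dyads per group, ten-minute
    conversations, group mean drifts of -6 Hz (ASD, dis-entrainment) and
    +4 Hz (NT, convergence), and covariate distributions calibrated to the
    cohort table (CELF-5 core 88 +/- 12.43 vs 109 +/- 11.56, non-verbal IQ
    107 +/- 9.8 vs 110 +/- 9.05, ages 9-15, 3 girls and 9 boys per group).
    """

    n_per_group: int = 12
    duration: float = 600.0
    registers: dict = field(default_factory=lambda: {
        "child": 230.0, "teen_girl": 220.0, "teen_boy": 140.0,
        "adult_female": 200.0, "adult_male": 120.0,
    })
    register_sd: float = 10.0
    frame_noise_sd: float = 5.0
    utterance_range: tuple[float, float] = (1.0, 5.0)
    pause_range: tuple[float, float] = (0.5, 2.0)
    drift_delta: dict = field(default_factory=lambda: {"ASD": -6.0, "NT": 4.0})
    responsibility_split: float = 0.5
    iqr_drift: float = 0.0
    celf_effect: float = -0.26  # Hz of extra dyad drift per CELF point above group mean
    celf: dict = field(default_factory=lambda: {"ASD": (88.0, 12.43), "NT": (109.0, 11.56)})
    nonverbal_iq: dict = field(default_factory=lambda: {"ASD": (107.0, 9.8), "NT": (110.0, 9.05)})
    composite_iq: dict = field(default_factory=lambda: {"ASD": (99.0, 16.76), "NT": (112.0, 12.57)})
    age_range: tuple[float, float] = (9.0, 15.0)
    female_fraction: float = 0.25
    nonspeech_rate: float = 0.5  # expected non-linguistic intervals per minute, ASD only
    partner_pool: int = 9
    step: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.n_per_group <= 0:
            raise ValueError("duration and n_per_group must be positive")
        if not 0.0 <= self.responsibility_split <= 1.0:
            raise ValueError("responsibility_split must be in [0, 1]")
        if self.nonspeech_rate < 0:
            raise ValueError("nonspeech_rate must be >= 0")


def study_preset() -> SimConfig:
    """The calibrated study preset: 12 dyads per group, ASD drift -6 Hz,
    NT drift +4 Hz, cohort-table covariates."""
    return SimConfig()


@dataclass
class GroundTruth:
    """What the generator programmed for one dyad, for recovery tests."""

    dyad_id: str
    group: str
    delta_ent_k1: float
    delta_ent_k2: float
    resp1: float
    resp2: float
    line_slope: float
    register_participant: float
    register_partner: float
    seed: int


@dataclass
class SimulatedDyad:
    conversation: AnnotatedConversation
    track_participant: F0Track
    track_partner: F0Track
    metadata: DyadMetadata
    truth: GroundTruth


@dataclass
class Cohort:
    dyads: list[SimulatedDyad]
    config: SimConfig

    @property
    def metadata(self) -> list[DyadMetadata]:
        return [d.metadata for d in self.dyads]

    def ground_truth_table(self) -> pd.DataFrame:
        """One row per speaker role per dyad."""
        rows = []
        for d in self.dyads:
            t, m = d.truth, d.metadata
            for role, resp in (("participant", t.resp1), ("partner", t.resp2)):
                rows.append({
                    "dyad_id": t.dyad_id, "role": role, "group": t.group,
                    "delta_ent_k1": t.delta_ent_k1, "delta_ent_k2": t.delta_ent_k2,
                    "responsibility": resp, "line_slope": t.line_slope,
                    "age": m.age, "gender": m.gender, "celf_core": m.celf_core,
                    "nonverbal_iq": m.nonverbal_iq, "seed": t.seed,
                })
        return pd.DataFrame(rows)


def _speaker_class(age: float, gender: str) -> str:
    # pre-voice-change children up to ~12; teens split by gender
    if age < 13.0:
        return "child"
    return "teen_girl" if gender == "F" else "teen_boy"


def _draw_registers(
    rng: np.random.Generator,
    cfg: SimConfig,
    class_p: str,
    class_q: str,
    line: ReferenceLine,
    drift: float,
    max_tries: int = 200,
) -> tuple[float, float]:
    """Draw register means whose start point leaves room for the drift.

    A convergence drift must not carry the dyad across the line, and the
    end-of-conversation targets must stay above the speaker-class pitch
    floor; register pairs violating either are redrawn.
    """
    floor_p = DEFAULT_PITCH_RANGES[class_p][0]
    floor_q = DEFAULT_PITCH_RANGES[class_q][0]
    margin = 2.0
    for _ in range(max_tries):
        mu_p = rng.normal(cfg.registers[class_p], cfg.register_sd)
        mu_q = rng.normal(cfg.registers[class_q], cfg.register_sd)
        s0 = signed_line_offset((mu_p, mu_q), line)
        if abs(s0) < max(drift, 0.0) + margin:
            continue
        if mu_p - abs(drift) < floor_p + 20.0 or mu_q - abs(drift) < floor_q + 20.0:
            continue
        return mu_p, mu_q
    raise InfeasibleDriftError(
        f"no feasible registers for drift {drift} Hz with classes "
        f"({class_p}, {class_q}); target means would fall below the pitch floor "
        f"or cross the reference line"
    )


def _drift_moves(line: ReferenceLine, s0: float, drift: float, split: float) -> tuple[float, float]:
    """Along-axis moves (participant, partner) realising the drift exactly.

    With m the effective slope and n = sqrt(m^2 + 1), the signed offset of a
    point (x, y) is s = (m x - y) / n.  Moving the offset from s0 to
    s0 - sign(s0) * drift changes the perpendicular distance by exactly
    ``drift``; the total along-axis movement is split ``split`` to the
    participant, with both speakers moving coherently.
    """
    m = line.effective_slope
    n = np.hypot(m, 1.0)
    target_change = -np.sign(s0) * drift * n  # required m*dx - dy
    if target_change == 0.0:
        return 0.0, 0.0
    sgn = np.sign(target_change)
    total = abs(target_change) / (m * split + (1.0 - split))
    dx = sgn * split * total
    dy = -sgn * (1.0 - split) * total
    return float(dx), float(dy)


def _third_targets(duration: float, mu: float, delta: float, times: np.ndarray) -> np.ndarray:
    """Piecewise mean-f0 target: flat thirds, linear ramp in between."""
    t1, t2 = duration / 3.0, 2.0 * duration / 3.0
    targets = np.full_like(times, mu)
    ramp = (times >= t1) & (times < t2)
    targets[ramp] = mu + delta * (times[ramp] - t1) / (t2 - t1)
    targets[times >= t2] = mu + delta
    return targets


def _build_tiers(
    rng: np.random.Generator,
    cfg: SimConfig,
    participant_id: str,
    partner_id: str,
    group: str,
) -> tuple[SpeakerTier, SpeakerTier]:
    """Alternating utterance/pause turn structure tiling the timeline.

    ASD participants get occasional non-linguistic vocalizations inserted
    into the pause after their own utterances.
    """
    u_lo, u_hi = cfg.utterance_range
    p_lo, p_hi = cfg.pause_range
    mean_cycle = (u_lo + u_hi) / 2.0 + (p_lo + p_hi) / 2.0
    # probability that any given participant turn is followed by a vocalization
    p_ns = 0.0
    if group == "ASD" and cfg.nonspeech_rate > 0:
        p_ns = min(1.0, cfg.nonspeech_rate * (2.0 * mean_cycle) / 60.0)

    events: dict[str, list[Interval]] = {participant_id: [], partner_id: []}
    speaker = participant_id if rng.random() < 0.5 else partner_id
    t = float(rng.uniform(*cfg.pause_range))
    while t < cfg.duration - u_hi - p_hi:
        u = float(rng.uniform(u_lo, u_hi))
        events[speaker].append(Interval(t, t + u, "speech", True))
        t += u
        pause = float(rng.uniform(p_lo, p_hi))
        if speaker == participant_id and pause >= 0.8 and rng.random() < p_ns:
            ns_len = float(rng.uniform(0.3, min(1.0, pause - 0.2)))
            label = NONSPEECH_LABELS[int(rng.integers(len(NONSPEECH_LABELS)))]
            events[participant_id].append(Interval(t + 0.1, t + 0.1 + ns_len, label, False))
        t += pause
        speaker = partner_id if speaker == participant_id else participant_id

    tiers = []
    for sid in (participant_id, partner_id):
        intervals, cursor = [], 0.0
        for iv in events[sid]:
            if iv.start > cursor + 1e-9:
                intervals.append(Interval(cursor, iv.start, "", False))
            intervals.append(iv)
            cursor = iv.end
        if cursor < cfg.duration - 1e-9:
            intervals.append(Interval(cursor, cfg.duration, "", False))
        tiers.append(SpeakerTier(speaker_id=sid, intervals=intervals))
    return tiers[0], tiers[1]


def _render_track(
    rng: np.random.Generator,
    cfg: SimConfig,
    tier: SpeakerTier,
    mu: float,
    delta: float,
    iqr_drift: float,
    speaker_id: str,
    register: float,
) -> F0Track:
    times = np.arange(int(round(cfg.duration / cfg.step))) * cfg.step
    targets = _third_targets(cfg.duration, mu, delta, times)
    sd = np.full_like(times, cfg.frame_noise_sd)
    if iqr_drift != 0.0:
        # widen last-third noise so the f0 IQR grows by ~iqr_drift Hz
        sd[times >= 2.0 * cfg.duration / 3.0] += iqr_drift / _IQR_PER_SD
    f0 = targets + rng.normal(0.0, 1.0, size=len(times)) * sd
    voiced = np.zeros(len(times), dtype=bool)
    for iv in tier.intervals:
        if not iv.label:
            continue
        mask = (times >= iv.start) & (times < iv.end)
        voiced |= mask
        if not iv.is_linguistic:
            # out-of-register burst: stresses the linguistic filter downstream
            f0[mask] = 2.0 * register + rng.normal(0.0, cfg.frame_noise_sd, size=mask.sum())
    f0 = np.maximum(f0, 1.0)
    f0[~voiced] = 0.0
    return F0Track(speaker_id, times, f0, voiced, cfg.step)


def _draw_covariates(rng: np.random.Generator, cfg: SimConfig, group: str, index: int,
                     n_in_group: int) -> dict:
    n_female = int(round(cfg.female_fraction * n_in_group))
    gender = "F" if index < n_female else "M"
    age = float(rng.uniform(*cfg.age_range))
    celf = float(np.clip(rng.normal(*cfg.celf[group]), 40.0, 160.0))
    nviq = float(np.clip(rng.normal(*cfg.nonverbal_iq[group]), 85.0, 160.0))
    ciq = float(np.clip(rng.normal(*cfg.composite_iq[group]), 76.0, 160.0))
    return {"age": age, "gender": gender, "celf_core": celf,
            "nonverbal_iq": nviq, "composite_iq": ciq}


def simulate_dyad(
    cfg: SimConfig,
    group: str,
    seed: int,
    dyad_id: str = "",
    covariates: Optional[dict] = None,
    partner_id: str = "P01",
) -> SimulatedDyad:
    """Generate one complete dyad: annotation, two pitch tracks, metadata
    and the programmed ground truth.

    The dyad-level drift is the group drift plus the CELF modulation
    ``celf_effect * (celf - group mean)``; the per-speaker moves realise it
    exactly (at zero noise) against the dyad's reference line.
    """
    if group not in cfg.drift_delta:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    dyad_id = dyad_id or f"{group}_{seed:08d}"
    participant_id = f"{dyad_id}_S1"

    cov = covariates or _draw_covariates(rng, cfg, group, 0, cfg.n_per_group)
    class_p = _speaker_class(cov["age"], cov["gender"])
    class_q = "adult_female"
    line = select_reference_line(class_p, class_q)

    celf_mean = cfg.celf[group][0]
    drift = cfg.drift_delta[group] + cfg.celf_effect * (cov["celf_core"] - celf_mean)
    mu_p, mu_q = _draw_registers(rng, cfg, class_p, class_q, line, drift)
    s0 = signed_line_offset((mu_p, mu_q), line)
    dx, dy = _drift_moves(line, s0, drift, cfg.responsibility_split)

    tier_p, tier_q = _build_tiers(rng, cfg, participant_id, f"{dyad_id}_S2", group)
    conv = AnnotatedConversation(dyad_id, cfg.duration, [tier_p, tier_q])
    track_p = _render_track(rng, cfg, tier_p, mu_p, dx, cfg.iqr_drift, participant_id, mu_p)
    track_q = _render_track(rng, cfg, tier_q, mu_q, dy, 0.0, f"{dyad_id}_S2", mu_q)

    total = abs(dx) + abs(dy)
    resp1 = cfg.responsibility_split if total > 0 else 0.5
    meta = DyadMetadata(
        dyad_id=dyad_id,
        participant_id=participant_id,
        partner_id=partner_id,
        group=group,
        age=cov["age"],
        gender=cov["gender"],
        celf_core=cov["celf_core"],
        nonverbal_iq=cov["nonverbal_iq"],
        composite_iq=cov.get("composite_iq"),
        participant_class=class_p,
        partner_class=class_q,
        age_range=cfg.age_range,
    )
    truth = GroundTruth(
        dyad_id=dyad_id, group=group,
        delta_ent_k1=drift, delta_ent_k2=cfg.iqr_drift,
        resp1=resp1, resp2=1.0 - resp1,
        line_slope=line.effective_slope,
        register_participant=mu_p, register_partner=mu_q,
        seed=seed,
    )
    return SimulatedDyad(conv, track_p, track_q, meta, truth)


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate ``n_per_group`` dyads per group with drawn covariates."""
    master = np.random.default_rng(cfg.seed)
    dyads = []
    counter = 0
    for group in ("ASD", "NT"):
        for i in range(cfg.n_per_group):
            counter += 1
            dyad_seed = int(master.integers(0, 2**31 - 1))
            cov_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
            cov = _draw_covariates(cov_rng, cfg, group, i, cfg.n_per_group)
            partner = f"P{(counter - 1) % cfg.partner_pool + 1:02d}"
            dyads.append(
                simulate_dyad(cfg, group, dyad_seed,
                              dyad_id=f"{group}{i + 1:02d}",
                              covariates=cov, partner_id=partner)
            )
    return Cohort(dyads, cfg)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort in the formats the readers accept.

    Per dyad: <id>.TextGrid and <id>_{S1,S2}.f0.csv; plus metadata.csv and
    ground_truth.csv.  Every file records the master seed in a header
    comment where the format allows one.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_note = f"# seed = {cohort.config.seed}\n"
    for d in cohort.dyads:
        (outdir / f"{d.metadata.dyad_id}.TextGrid").write_text(
            pio.write_textgrid(d.conversation)
        )
        for suffix, track in (("S1", d.track_participant), ("S2", d.track_partner)):
            path = outdir / f"{d.metadata.dyad_id}_{suffix}.f0.csv"
            path.write_text(seed_note + pio.write_f0_track(track))
    (outdir / "metadata.csv").write_text(pio.write_metadata(cohort.metadata))
    truth = cohort.ground_truth_table()
    (outdir / "ground_truth.csv").write_text(truth.to_csv(index=False))


def render_waveform(track: F0Track, rate: int = 16000, n_harmonics: int = 8) -> np.ndarray:
    """Render a phase-continuous harmonic-complex waveform from a pitch track.

    Used for end-to-end tests of the pitch estimator: the waveform's
    instantaneous f0 follows the track; unvoiced frames are silent.
    """
    n = int(round(track.times[-1] * rate)) if len(track) else 0
    if n == 0:
        return np.zeros(0)
    t = np.arange(n) / rate
    inst_f0 = np.interp(t, track.times, np.where(track.voiced, track.f0, 0.0))
    phase = 2.0 * np.pi * np.cumsum(inst_f0) / rate
    out = np.zeros(n)
    for h in range(1, n_harmonics + 1):
        out += np.sin(h * phase) / h
    out[inst_f0 <= 0] = 0.0
    return out / np.max(np.abs(out) + 1e-12)
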