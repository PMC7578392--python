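"""End-to-end orchestration: simulate/load -> features -> entrainment -> stats.

A single PipelineConfig (YAML-backed) drives every stage; all thresholds
are echoed into the output header so results are traceable to settings.
Outputs are plain CSV and text: features.csv, entrainment.csv,
models/*.csv, summary.txt and run.log.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .datatypes import AnnotatedConversation, DyadFeatures, DyadMetadata, F0Track
from .entrainment import (
    DEFAULT_CONVERGE_THRESHOLD,
    DEFAULT_MAINTENANCE_BAND,
    EntrainmentResult,
    compute_entrainment,
    count_converging,
    select_reference_line,
)
from .features import DEFAULT_MIN_FRAMES, build_dyad_features
from .simulate import Cohort, SimConfig, simulate_cohort, write_cohort
from .stats import RegressionResult, run_model_family

log = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "entrain", "stats")
DEFAULT_FAMILIES = (
    "conversation_level",
    "contribution_level",
    "adjusted_level",
    "f0_range_family",
)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything one run needs: data source, knobs, output location."""

    output_dir: str = "prosentrain_out"
    seed: int = 0
    simulate: Optional[SimConfig] = None
    data_dir: Optional[str] = None
    metadata: Optional[str] = None
    min_frames: int = DEFAULT_MIN_FRAMES
    maintenance_band: float = DEFAULT_MAINTENANCE_BAND
    converge_threshold: float = DEFAULT_CONVERGE_THRESHOLD
    min_over_lines: bool = False
    line_override: Optional[float] = None
    model_families: Sequence[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    apply_linguistic_filter: bool = True

    def validate(self) -> None:
        if self.simulate is None and (self.data_dir is None or self.metadata is None):
            raise ConfigError(
                "config needs either a 'simulate' block or both 'data_dir' and 'metadata'"
            )
        if self.simulate is None:
            if not Path(self.data_dir).is_dir():
                raise ConfigError(f"data_dir does not exist: {self.data_dir}")
            if not Path(self.metadata).is_file():
                raise ConfigError(f"metadata file does not exist: {self.metadata}")
        if self.min_frames < 1:
            raise ConfigError("min_frames must be >= 1")
        if self.maintenance_band < 0 or self.converge_threshold < 0:
            raise ConfigError("thresholds must be non-negative")
        unknown = set(self.model_families) - {
            "conversation_level", "contribution_level", "adjusted_level", "f0_range_family",
        }
        if unknown:
            raise ConfigError(f"unknown model families: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(sim) - sim_known
            if bad:
                raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = SimConfig(**sim)
        return cfg


@dataclass
class DyadData:
    conversation: AnnotatedConversation
    track_participant: F0Track
    track_partner: F0Track
    metadata: DyadMetadata


@dataclass
class RunReport:
    features: pd.DataFrame
    entrainment: pd.DataFrame
    analysis: pd.DataFrame
    models: dict[str, dict[str, RegressionResult]]
    summary_text: str
    excluded: list[str]
    output_dir: Optional[Path] = None


# ---------------------------------------------------------------------------
# Data acquisition
# ---------------------------------------------------------------------------

def load_dyads(data_dir, metadata_path) -> tuple[list[DyadData], list[str]]:
    """Load TextGrid + pitch-track + metadata triples from a directory.

    Expects <dyad_id>.TextGrid and <dyad_id>_{S1,S2}.f0.csv per dyad.
    Dyads with missing files are excluded (returned in the second element)
    rather than aborting the run.
    """
    data_dir = Path(data_dir)
    dyads, excluded = [], []
    for meta in pio.read_metadata(metadata_path):
        tg = data_dir / f"{meta.dyad_id}.TextGrid"
        f1 = data_dir / f"{meta.dyad_id}_S1.f0.csv"
        f2 = data_dir / f"{meta.dyad_id}_S2.f0.csv"
        if not (tg.is_file() and f1.is_file() and f2.is_file()):
            excluded.append(f"{meta.dyad_id}: missing input files")
            continue
        conv = pio.parse_textgrid(tg.read_text(), conversation_id=meta.dyad_id)
        dyads.append(
            DyadData(
                conversation=conv,
                track_participant=pio.read_f0_track(f1, speaker_id=conv.tiers[0].speaker_id),
                track_partner=pio.read_f0_track(f2, speaker_id=conv.tiers[1].speaker_id),
                metadata=meta,
            )
        )
    return dyads, excluded


def cohort_to_dyads(cohort: Cohort) -> list[DyadData]:
    return [
        DyadData(d.conversation, d.track_participant, d.track_partner, d.metadata)
        for d in cohort.dyads
    ]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def extract_features(
    dyads: Sequence[DyadData],
    min_frames: int = DEFAULT_MIN_FRAMES,
    apply_filter: bool = True,
) -> tuple[list[DyadFeatures], pd.DataFrame]:
    """Linguistic-filter every track and summarise the conversation thirds."""
    feats, rows = [], []
    for d in dyads:
        tp, tq = d.track_participant, d.track_partner
        if apply_filter:
            tp = pio.filter_linguistic(tp, d.conversation.participant_tier)
            tq = pio.filter_linguistic(tq, d.conversation.partner_tier)
        feat = build_dyad_features(
            tp, tq, d.conversation.duration,
            dyad_id=d.metadata.dyad_id, min_frames=min_frames,
        )
        feats.append(feat)
        for k, name in ((1, "mean_f0"), (2, "f0_iqr")):
            for window, point in (("first", feat.start[k]), ("last", feat.end[k])):
                for axis, speaker in ((1, "participant"), (2, "partner")):
                    rows.append({
                        "dyad_id": feat.dyad_id, "speaker": speaker, "k": k,
                        "feature": name, "window": window,
                        "value": point[axis - 1],
                        "n_frames": feat.n_frames.get((axis, window), 0),
                    })
    return feats, pd.DataFrame(rows)


def score_entrainment(
    dyads: Sequence[DyadData],
    feats: Sequence[DyadFeatures],
    maintenance_band: float = DEFAULT_MAINTENANCE_BAND,
    min_over_lines: bool = False,
    line_override: Optional[float] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Score every usable dyad x feature; unusable ones are excluded and
    reported."""
    rows, excluded = [], []
    for d, feat in zip(dyads, feats):
        line = select_reference_line(
            d.metadata.participant_class, d.metadata.partner_class, override=line_override
        )
        for k in (1, 2):
            if not feat.usable[k]:
                excluded.append(
                    f"{feat.dyad_id}: feature k={k} unusable "
                    f"(insufficient voiced frames in a third)"
                )
                continue
            res = compute_entrainment(
                feat, line, k,
                maintenance_band=maintenance_band,
                min_over_lines=min_over_lines,
            )
            row = dataclasses.asdict(res)
            rows.append(row)
    return pd.DataFrame(rows), excluded


def build_analysis_table(entrainment: pd.DataFrame, metadata: Sequence[DyadMetadata]) -> pd.DataFrame:
    """Join dyad-level entrainment to participant covariates.

    One row per dyad per feature k, from the participant's perspective:
    ``contribution``/``adjusted_contribution`` are the participant's.
    """
    meta_rows = [
        {
            "dyad_id": m.dyad_id, "group": m.group, "age": m.age,
            "gender": m.gender, "celf_core": m.celf_core,
            "nonverbal_iq": m.nonverbal_iq, "partner_id": m.partner_id,
        }
        for m in metadata
    ]
    meta_df = pd.DataFrame(meta_rows)
    if entrainment.empty:
        return pd.DataFrame()
    table = entrainment.rename(
        columns={"contribution1": "contribution", "adjusted1": "adjusted_contribution"}
    )[["dyad_id", "k", "delta_ent", "contribution", "adjusted_contribution",
       "classification", "gap_change"]]
    return table.merge(meta_df, on="dyad_id", how="inner")


def summarise(
    analysis: pd.DataFrame,
    cfg: PipelineConfig,
    excluded: Sequence[str],
) -> str:
    """Human-readable run summary; group means computed from the analysis
    table rows so the summary is internally consistent with entrainment.csv."""
    lines = [
        "prosentrain run summary",
        f"  maintenance_band = {cfg.maintenance_band} Hz, "
        f"converge_threshold = {cfg.converge_threshold} Hz, "
        f"min_frames = {cfg.min_frames}, min_over_lines = {cfg.min_over_lines}, "
        f"line_override = {cfg.line_override}, seed = {cfg.seed}",
        "",
    ]
    for k, name in ((1, "mean f0"), (2, "f0 IQR")):
        sub = analysis[analysis["k"] == k]
        if sub.empty:
            continue
        lines.append(f"feature k={k} ({name}): n = {len(sub)} dyads")
        for group, part in sub.groupby("group"):
            deltas = part["delta_ent"]
            n_conv, prop = count_converging(deltas, cfg.converge_threshold)
            counts = part["classification"].value_counts().to_dict()
            lines.append(
                f"  {group}: mean delta_ent = {deltas.mean():+.2f} Hz "
                f"(SD {deltas.std(ddof=1):.2f}), "
                f"converging >{cfg.converge_threshold:g} Hz: {n_conv}/{len(part)} "
                f"({100 * prop:.0f}%), classes: {counts}"
            )
        lines.append("")
    if excluded:
        lines.append("excluded dyads:")
        lines += [f"  {e}" for e in excluded]
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig, stage: str = "stats") -> RunReport:
    """Run the pipeline up to ``stage`` and write outputs to cfg.output_dir.

    Stages are cumulative: simulate < extract < entrain < stats.  With a
    ``simulate`` block the synthetic cohort is generated (and written);
    otherwise inputs are read from ``data_dir``/``metadata``.
    """
    cfg.validate()
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGES}")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("prosentrain")
    root.addHandler(handler)
    try:
        excluded: list[str] = []
        if cfg.simulate is not None:
            cohort = simulate_cohort(cfg.simulate)
            write_cohort(cohort, outdir / "simulated")
            dyads = cohort_to_dyads(cohort)
        else:
            dyads, excluded = load_dyads(cfg.data_dir, cfg.metadata)
            for e in excluded:
                log.warning("excluded %s", e)
        if stage == "simulate":
            return RunReport(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(),
                             {}, "", excluded, outdir)

        feats, features_df = extract_features(
            dyads, cfg.min_frames, apply_filter=cfg.apply_linguistic_filter
        )
        features_df.to_csv(outdir / "features.csv", index=False)
        if stage == "extract":
            return RunReport(features_df, pd.DataFrame(), pd.DataFrame(),
                             {}, "", excluded, outdir)

        entrainment_df, ent_excluded = score_entrainment(
            dyads, feats,
            maintenance_band=cfg.maintenance_band,
            min_over_lines=cfg.min_over_lines,
            line_override=cfg.line_override,
        )
        excluded += ent_excluded
        for e in ent_excluded:
            log.warning("excluded %s", e)
        entrainment_df.to_csv(outdir / "entrainment.csv", index=False)
        analysis = build_analysis_table(entrainment_df, [d.metadata for d in dyads])
        analysis.to_csv(outdir / "analysis.csv", index=False)
        summary = summarise(analysis, cfg, excluded)
        (outdir / "summary.txt").write_text(summary)
        if stage == "entrain":
            return RunReport(features_df, entrainment_df, analysis, {},
                             summary, excluded, outdir)

        models: dict[str, dict[str, RegressionResult]] = {}
        models_dir = outdir / "models"
        models_dir.mkdir(exist_ok=True)
        for family in cfg.model_families:
            models[family] = run_model_family(analysis, family)
            for which, res in models[family].items():
                res.terms.to_csv(models_dir / f"{family}_{which}.csv", index=False)
                (models_dir / f"{family}_{which}.txt").write_text(res.summary_text() + "\n")
        return RunReport(features_df, entrainment_df, analysis, models,
                         summary, excluded, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
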