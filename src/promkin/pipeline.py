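"""Pipeline orchestration: per-trial extraction and study-level analysis.

Chains the stages — envelope and f0 extraction, syllable cues, prominence
nomination, apex detection, asynchrony — over a dataset (in memory or on
disk) into the tidy trial table, then fits the study's mixed models.
Per-trial quality issues (unvoiced syllables, apex at a window edge, no
movement detected in a movement block) become flags in the trial table, not
silently dropped rows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acoustic import amplitude_envelope, envelope_peak_time, extract_syllable_cues, f0_track
from .errors import PromkinError
from .io_formats import (
    PoseTrack,
    UtteranceRecording,
    read_pose_track,
    read_syllable_tier,
    read_wav,
    write_trial_table,
)
from .kinematics import (
    DEFAULT_MOVEMENT_THRESHOLD,
    SmoothConfig,
    detect_max_extension,
    movement_present,
    preprocess_track,
)
from .models import (
    DEFAULT_ALPHA,
    MixedFitResults,
    accuracy_by_movement_test,
    fit_condition_model,
    fit_gradient_model,
    movement_boost_test,
)
from .prominence import ProminenceWeights, prominence_analysis
from .trials import (
    CognateItem,
    TrialRecord,
    classify_production,
    compute_asynchrony,
    label_condition,
    read_item_table,
    verification_agreement,
)

__all__ = ["PipelineConfig", "analyze_trial", "extract_study", "analyze_study",
           "load_disk_study", "run_verification"]


@dataclass
class PipelineConfig:
    """All pipeline parameters plus the input/output paths.

    Serialized as YAML for the command line; every module-level knob is
    exposed here with its module default.
    """

    # paths (used by the CLI subcommands)
    data_dir: str = "data"
    out_dir: str = "out"
    # io
    tier_name: str = "syllables"
    pose_time_column: str = "time_s"
    pose_y_column: str = "y"
    pose_y_down: bool = True
    # acoustics
    envelope_cutoff_hz: float = 12.0
    envelope_rate_hz: float = 100.0
    f0_min_hz: float = 75.0
    f0_max_hz: float = 500.0
    # prominence
    weights: tuple[float, float, float] = (0.33, 0.33, 0.33)  # (W_F, W_I, W_D)
    # kinematics
    pose_out_rate_hz: float = 50.0
    pose_smooth_cutoff_hz: float = 10.0
    movement_threshold: float = DEFAULT_MOVEMENT_THRESHOLD
    reference_length: float | None = None
    search_margin_s: float = 0.5
    restrict_window_to_speech: bool = False
    # analysis
    alpha: float = DEFAULT_ALPHA
    re_speaker: bool = True
    re_item: bool = True
    # simulation / global seed
    seed: int = 0

    def prominence_weights(self) -> ProminenceWeights:
        w_f, w_i, w_d = self.weights
        return ProminenceWeights(W_F=w_f, W_I=w_i, W_D=w_d)

    def smooth_config(self) -> SmoothConfig:
        return SmoothConfig(
            cutoff_hz=self.pose_smooth_cutoff_hz,
            reference_length=self.reference_length,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["weights"] = list(d["weights"])
        Path(path).write_text(yaml.safe_dump(d), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "weights" in d:
            d["weights"] = tuple(d["weights"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PromkinError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def analyze_trial(
    rec: UtteranceRecording,
    pose: PoseTrack | None,
    item: CognateItem,
    cfg: PipelineConfig = PipelineConfig(),
) -> TrialRecord:
    """Run the full per-trial measurement chain and return one record."""
    env = amplitude_envelope(
        rec, cutoff_hz=cfg.envelope_cutoff_hz, out_rate=cfg.envelope_rate_hz
    )
    pitch = f0_track(rec, fmin=cfg.f0_min_hz, fmax=cfg.f0_max_hz)
    cues = extract_syllable_cues(env, pitch, rec.syllables)
    prom = prominence_analysis(
        cues, rec.syllables, env, w=cfg.prominence_weights()
    )
    flags = list(prom.flags)

    pclass = classify_production(prom.nominated, item)
    cond = label_condition(item, pclass)
    t_peak_target = envelope_peak_time(env, rec.syllables[item.target_idx])

    asyn = phon_asyn = apex_t = None
    if pose is not None:
        prep = preprocess_track(
            pose, out_rate=cfg.pose_out_rate_hz, smooth_cfg=cfg.smooth_config()
        )
        window = None
        if cfg.restrict_window_to_speech:
            window = (
                rec.syllables[0].start - cfg.search_margin_s,
                rec.syllables[-1].end + cfg.search_margin_s,
            )
        if not movement_present(prep, threshold=cfg.movement_threshold):
            flags.append("no_movement_detected")
        else:
            event = detect_max_extension(prep, window=window)
            if event.flags:
                flags.extend(event.flags)
            apex_t = event.t_ext
            asyn = compute_asynchrony(event.t_ext, prom.peak_env_time)
            phon_asyn = compute_asynchrony(event.t_ext, t_peak_target)
    elif rec.movement_block:
        flags.append("no_pose_track_in_movement_block")

    return TrialRecord(
        speaker_id=rec.speaker_id,
        item_id=item.item_id,
        movement=bool(rec.movement_block),
        n_syll=item.n_syll,
        nominated=prom.nominated,
        production_class=pclass,
        condition=cond,
        distance=item.distance,
        asynchrony_ms=asyn,
        phon_asynchrony_ms=phon_asyn,
        peak_intensity=cues[prom.nominated].I,
        peak_env_time=prom.peak_env_time,
        apex_time=apex_t,
        flags=";".join(flags),
    )


def extract_study(study, cfg: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Trial table for a synthetic (in-memory) or disk-loaded study."""
    records = []
    for tr in study.trials:
        records.append(analyze_trial(tr.rec, tr.pose, tr.item, cfg))
    return pd.DataFrame([vars(r) for r in records])


@dataclass
class DiskTrial:
    speaker_id: str
    item: CognateItem
    movement: bool
    rec: UtteranceRecording
    pose: PoseTrack | None


@dataclass
class DiskStudy:
    items: list[CognateItem]
    trials: list[DiskTrial]


def load_disk_study(data_dir: str | Path,
                    cfg: PipelineConfig = PipelineConfig()) -> DiskStudy:
    """Load a dataset directory (manifest + items + audio/tiers/pose)."""
    data_dir = Path(data_dir)
    if not data_dir.exists():
        raise FileNotFoundError(f"data directory not found: {data_dir}")
    items = read_item_table(data_dir / "items.csv")
    by_id = {it.item_id: it for it in items}
    manifest = pd.read_csv(data_dir / "manifest.csv")
    trials = []
    for row in manifest.itertuples():
        wave, sr = read_wav(data_dir / row.audio)
        ivs = read_syllable_tier(data_dir / row.tier, cfg.tier_name)
        rec = UtteranceRecording(
            waveform=wave,
            sample_rate=sr,
            syllables=ivs,
            item_id=str(row.item_id),
            speaker_id=str(row.speaker_id),
            movement_block=bool(row.movement),
        )
        pose = None
        if isinstance(row.pose, str) and row.pose:
            pose = read_pose_track(
                data_dir / row.pose,
                y_down=cfg.pose_y_down,
                time_column=cfg.pose_time_column,
                y_column=cfg.pose_y_column,
            )
        trials.append(
            DiskTrial(str(row.speaker_id), by_id[str(row.item_id)],
                      bool(row.movement), rec, pose)
        )
    return DiskStudy(items=items, trials=trials)


def analyze_study(
    trial_table: pd.DataFrame, cfg: PipelineConfig = PipelineConfig()
) -> dict[str, MixedFitResults]:
    """Fit the study's four mixed models on a trial table."""
    kw = dict(alpha=cfg.alpha, re_speaker=cfg.re_speaker, re_item=cfg.re_item)
    return {
        "condition": fit_condition_model(trial_table, **kw),
        "gradient": fit_gradient_model(trial_table, **kw),
        "intensity_boost": movement_boost_test(trial_table, **kw),
        "accuracy_by_movement": accuracy_by_movement_test(
            trial_table, alpha=cfg.alpha
        ),
    }


def run_verification(
    trial_table: pd.DataFrame, items: list[CognateItem]
) -> float:
    """Nomination–phonological-stress agreement over a trial table."""
    annotation = {it.item_id: it.target_idx for it in items}
    return verification_agreement(trial_table, annotation)
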