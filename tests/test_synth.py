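"""Generator determinism, design fidelity at small scale, and truth round-trips."""

import numpy as np
import pandas as pd
import pytest

from promkin.acoustic import amplitude_envelope, extract_syllable_cues, f0_track
from promkin.errors import ParameterError
from promkin.io_formats import UtteranceRecording, read_pose_track, read_syllable_tier, read_wav
from promkin.kinematics import detect_max_extension, preprocess_track
from promkin.prominence import prominence_analysis
from promkin.synth import (
    CueBoosts,
    SynthConfig,
    am_peak_time,
    default_items,
    synth_pose_track,
    synth_study,
    synth_utterance_audio,
)

SR = 16000.0


def small_config(**kw):
    defaults = dict(n_speakers=2, seed=7)
    defaults.update(kw)
    return SynthConfig(**defaults)


def test_default_item_table_composition(items):
    assert len(items) == 96
    matching = [it for it in items if it.matching]
    mism = [it for it in items if not it.matching]
    assert len(matching) == 48 and len(mism) == 48
    assert sum(it.accent_mark for it in matching) == 24
    assert sum(it.accent_mark for it in mism) == 24
    assert all(2 <= it.n_syll <= 5 for it in items)
    # mismatching items keep a residual syllable for "other" productions
    assert all(it.n_syll >= 3 for it in mism)
    assert sorted({np.sign(it.distance) for it in mism}) == [-1, 1]


def test_requested_boundaries_emitted_exactly(mismatch_item):
    wave, ivs = synth_utterance_audio(mismatch_item, 0, seed=0)
    assert len(ivs) == mismatch_item.n_syll
    # boundaries are contiguous and on the sample grid
    for a, b in zip(ivs, ivs[1:]):
        assert b.start == pytest.approx(a.end, abs=1e-12)
        assert (a.end * SR) == pytest.approx(round(a.end * SR), abs=1e-9)
    assert ivs[-1].end < len(wave) / SR + 1e-9


def test_audio_deterministic_under_seed(mismatch_item):
    w1, iv1 = synth_utterance_audio(mismatch_item, 1, seed=123)
    w2, iv2 = synth_utterance_audio(mismatch_item, 1, seed=123)
    np.testing.assert_array_equal(w1, w2)
    assert [(a.start, a.end) for a in iv1] == [(a.start, a.end) for a in iv2]


def test_invalid_produced_index_rejected(mismatch_item):
    with pytest.raises(ParameterError):
        synth_utterance_audio(mismatch_item, mismatch_item.n_syll, seed=0)


def test_produced_stress_wins_composite_score(items):
    """End-to-end Monte Carlo: the pipeline nominates the generated stress
    in at least 95% of 200 words at default boosts."""
    rng = np.random.default_rng(5)
    hits = 0
    n = 200
    for _ in range(n):
        item = items[int(rng.integers(len(items)))]
        produced = int(rng.integers(item.n_syll))
        wave, ivs = synth_utterance_audio(item, produced, CueBoosts(), rng)
        rec = UtteranceRecording(wave, SR, ivs)
        env = amplitude_envelope(rec)
        cues = extract_syllable_cues(env, f0_track(rec), ivs)
        hits += prominence_analysis(cues, ivs, env).nominated == produced
    assert hits / n >= 0.95


def test_pose_track_deterministic_and_apex_placed():
    tr1 = synth_pose_track(1.20, 0.0, seed=9, noise_px=0.0)
    tr2 = synth_pose_track(1.20, 0.0, seed=9, noise_px=0.0)
    np.testing.assert_array_equal(tr1.y, tr2.y)
    ev = detect_max_extension(preprocess_track(tr1))
    assert abs(ev.t_ext - 1.20) <= 0.020


def test_pose_apex_outside_span_rejected():
    with pytest.raises(ParameterError):
        synth_pose_track(0.1, -500.0, span=(0.0, 2.0), seed=0)


def test_generated_vs_measured_asynchrony_correlation():
    rng = np.random.default_rng(11)
    gen, meas = [], []
    for _ in range(100):
        anchor = 1.0
        asyn = float(rng.normal(-50, 120))
        asyn = float(np.clip(asyn, -700, 900))
        tr = synth_pose_track(anchor, asyn, seed=rng, span=(0.0, 2.2))
        ev = detect_max_extension(preprocess_track(tr))
        gen.append(asyn)
        meas.append((ev.t_ext - anchor) * 1000.0)
    assert np.corrcoef(gen, meas)[0, 1] > 0.99


def test_study_design_counts_and_blocks():
    cfg = small_config()
    study = synth_study(cfg)
    truth = study.truth
    # every item appears exactly once per movement condition per speaker
    assert len(study.trials) == 2 * 96 * 2
    per = truth.groupby(["speaker_id", "item_id"])["movement"].agg(["count", "sum"])
    assert (per["count"] == 2).all()
    assert (per["sum"] == 1).all()
    # blocked: movement flag switches every 6 trials within a speaker
    for _, g in truth.groupby("speaker_id", sort=False):
        mv = g["movement"].to_numpy()
        blocks = mv.reshape(-1, cfg.block_len)
        per_block = blocks.mean(axis=1)
        assert set(per_block) <= {0.0, 1.0}  # condition constant within block
        assert (per_block[:-1] != per_block[1:]).all()  # switches every block


def test_study_reproducible_and_truth_consistent(tmp_path):
    cfg = small_config(n_speakers=1, items=default_items()[:8], seed=3)
    s1 = synth_study(cfg)
    s2 = synth_study(cfg)
    np.testing.assert_array_equal(s1.trials[0].rec.waveform, s2.trials[0].rec.waveform)
    pd.testing.assert_frame_equal(s1.truth, s2.truth)
    # emitted files agree with the in-memory dataset and the truth ledger
    out = tmp_path / "study"
    s3 = synth_study(cfg, out_dir=out)
    manifest = pd.read_csv(out / "manifest.csv")
    assert len(manifest) == len(s3.trials)
    row = manifest.iloc[0]
    tr = s3.trials[0]
    wave, sr = read_wav(out / row.audio)
    assert sr == cfg.sample_rate
    np.testing.assert_allclose(wave, tr.rec.waveform, atol=2.0 / 32767)
    ivs = read_syllable_tier(out / row.tier)
    assert len(ivs) == len(tr.rec.syllables)
    for a, b in zip(ivs, tr.rec.syllables):
        assert a.start == pytest.approx(b.start, abs=1e-6)
        assert a.end == pytest.approx(b.end, abs=1e-6)
    mv_rows = manifest[manifest.movement]
    pose_row = mv_rows.iloc[0]
    tr_mv = s3.trials[int(pose_row.trial)]
    pose = read_pose_track(out / pose_row.pose)
    np.testing.assert_allclose(pose.y, tr_mv.pose.y, atol=1e-6)
    # truth ledger: apex really sits at anchor + asynchrony
    t = s3.truth
    mv = t[t.movement]
    np.testing.assert_allclose(
        mv.apex_time, mv.anchor_time + mv.asynchrony_true_ms / 1000.0, atol=1e-9
    )


def test_realized_class_proportions_within_binomial_ci():
    """Realized production classes stay inside 99% binomial CIs of the presets."""
    cfg = small_config(n_speakers=6, seed=21)
    truth = synth_study(cfg).truth
    items = {it.item_id: it for it in cfg.items}
    truth["matching"] = truth.item_id.map(lambda i: items[i].matching)

    def ci(p, n):
        half = 2.576 * np.sqrt(p * (1 - p) / n)
        return p - half, p + half

    m = truth[truth.matching]
    p_hat = (m.production_class_true == "correct_L2").mean()
    lo, hi = ci(cfg.accuracy["matching_correct"], len(m))
    assert lo <= p_hat <= hi
    x = truth[~truth.matching]
    for cls, key in [("correct_L2", "mismatching_correct"),
                     ("incorrect_L1", "mismatching_competitor"),
                     ("other", "mismatching_other")]:
        p_hat = (x.production_class_true == cls).mean()
        lo, hi = ci(cfg.accuracy[key], len(x))
        assert lo <= p_hat <= hi, (cls, p_hat, lo, hi)


def test_generated_condition_asynchrony_means():
    """Per-condition mean generated asynchronies sit near the configured
    truths within Monte-Carlo error (random intercepts + trial noise)."""
    cfg = small_config(n_speakers=8, seed=33, speaker_sd_ms=0.0, item_sd_ms=0.0)
    truth = synth_study(cfg).truth
    mv = truth[truth.movement & (truth.condition_true != "excluded")]
    for cond, g in mv.groupby("condition_true"):
        mu = cfg.asynchrony_ms[cond]
        se = cfg.noise_sd_ms / np.sqrt(len(g))
        assert abs(g.asynchrony_true_ms.mean() - mu) < 4 * se, cond
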