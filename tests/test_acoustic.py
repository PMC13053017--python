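"""Envelope, f0 tracking and syllable-cue extraction against known signals."""

import numpy as np
import pytest

from promkin.acoustic import (
    EnvelopeTrack,
    amplitude_envelope,
    envelope_peak_time,
    extract_syllable_cues,
    f0_track,
)
from promkin.errors import AlignmentError, InsufficientDataError, ParameterError
from promkin.io_formats import SyllableInterval
from promkin.synth import CueBoosts, am_peak_time, synth_utterance_audio
from promkin.io_formats import UtteranceRecording

from conftest import make_recording

SR = 16000.0


def test_envelope_of_constant_tone(tone_recording):
    env = amplitude_envelope(tone_recording)
    interior = (env.t > 0.1) & (env.t < 0.9)
    assert np.all(np.abs(env.value[interior] - 0.5) < 0.05 * 0.5)
    assert np.all(env.value >= 0)
    assert env.rate == 100.0


def test_envelope_of_silence():
    env = amplitude_envelope(make_recording(np.zeros(int(SR))))
    assert np.max(env.value) < 1e-9


def test_envelope_cutoff_above_nyquist_rejected(tone_recording):
    with pytest.raises(ParameterError):
        amplitude_envelope(tone_recording, cutoff_hz=60.0, out_rate=100.0)


def test_am_tone_envelope_peaks_track_the_modulator():
    # full-depth 4 Hz AM on a 200 Hz carrier: modulator maxima at
    # t = (k + 0.5) / 4 s (raised-cosine peaks)
    t = np.arange(int(SR)) / SR
    mod = 0.5 * (1 - np.cos(2 * np.pi * 4.0 * t))
    x = mod * np.sin(2 * np.pi * 200.0 * t)
    env = amplitude_envelope(make_recording(x))
    for k in range(4):
        t_true = (k + 0.5) / 4.0
        seg = (env.t > t_true - 0.1) & (env.t < t_true + 0.1)
        t_peak = env.t[seg][np.argmax(env.value[seg])]
        assert abs(t_peak - t_true) <= 1.0 / env.rate


def test_envelope_scale_equivariance_and_peak_time_invariance():
    # AM tone with a genuine peak so the argmax is well-defined
    t = np.arange(int(SR)) / SR
    mod = 0.5 * (1 - np.cos(2 * np.pi * 1.0 * t))  # single peak at 0.5 s
    x = mod * np.sin(2 * np.pi * 200.0 * t)
    rec1 = make_recording(x)
    rec2 = make_recording(0.6 * x)
    env1 = amplitude_envelope(rec1)
    env2 = amplitude_envelope(rec2)
    np.testing.assert_allclose(env2.value, env1.value * 0.6, atol=1e-9)
    iv = SyllableInterval(0.2, 0.9, "a")
    assert envelope_peak_time(env1, iv) == envelope_peak_time(env2, iv)


def test_f0_of_pure_sine(tone_recording):
    pit = f0_track(tone_recording)
    voiced = pit.f0[pit.voiced]
    assert voiced.size > 0
    assert abs(np.median(voiced) - 200.0) < 1.0


def test_f0_of_white_noise_mostly_unvoiced():
    rng = np.random.default_rng(0)
    pit = f0_track(make_recording(0.3 * rng.standard_normal(int(SR))))
    assert np.mean(pit.voiced) < 0.5


def test_f0_ramp_endpoints():
    # harmonic complex with f0 ramping linearly 150 -> 250 Hz
    t = np.arange(int(SR)) / SR
    f0 = 150.0 + 100.0 * t
    phase = 2 * np.pi * np.cumsum(f0) / SR
    x = sum(np.sin(h * phase) / h for h in range(1, 6)) / 2.0
    pit = f0_track(make_recording(x))
    first = pit.f0[pit.voiced & (pit.t < 0.2)]
    last = pit.f0[pit.voiced & (pit.t > 0.8)]
    # generator truth: mean f0 over the window centers
    assert abs(np.mean(first) - np.mean(150 + 100 * pit.t[pit.voiced & (pit.t < 0.2)])) < 5.0
    assert abs(np.mean(last) - np.mean(150 + 100 * pit.t[pit.voiced & (pit.t > 0.8)])) < 5.0


def test_empty_waveform_rejected_at_construction():
    # the recording type itself enforces that syllables fit the waveform,
    # so an empty waveform can never reach the extractors
    from promkin.errors import FormatError

    with pytest.raises((FormatError, InsufficientDataError)):
        make_recording(np.zeros(0))


def test_f0_range_must_fit_under_nyquist(tone_recording):
    with pytest.raises(ParameterError):
        f0_track(tone_recording, fmin=500.0, fmax=100.0)


def test_syllable_durations_are_boundary_determined(tone_recording):
    env = amplitude_envelope(tone_recording)
    pit = f0_track(tone_recording)
    cues = extract_syllable_cues(env, pit, tone_recording.syllables)
    assert [c.D for c in cues] == pytest.approx([0.2, 0.3, 0.4])
    assert all(c.I >= 0 for c in cues)


def test_boosted_syllable_holds_all_three_cue_maxima(mismatch_item):
    wave, ivs = synth_utterance_audio(
        mismatch_item, mismatch_item.target_idx, CueBoosts(), seed=5
    )
    rec = UtteranceRecording(wave, SR, ivs)
    env = amplitude_envelope(rec)
    pit = f0_track(rec)
    cues = extract_syllable_cues(env, pit, ivs)
    tgt = mismatch_item.target_idx
    assert np.argmax([c.D for c in cues]) == tgt
    assert np.nanargmax([c.F for c in cues]) == tgt
    assert np.argmax([c.I for c in cues]) == tgt


def test_wholly_unvoiced_syllable_flags_missing_f0():
    # noise burst in the middle syllable, tones elsewhere
    rng = np.random.default_rng(1)
    # the unvoiced stretch overreaches the middle syllable's boundaries by a
    # bit more than the analysis window, so no voiced frame leaks in
    t1 = np.arange(int(0.17 * SR)) / SR
    t2 = np.arange(int(0.36 * SR)) / SR
    t3 = np.arange(int(0.37 * SR)) / SR
    x = np.concatenate([
        0.4 * np.sin(2 * np.pi * 180 * t1),
        0.05 * rng.standard_normal(len(t2)),
        0.4 * np.sin(2 * np.pi * 220 * t3),
    ])
    rec = make_recording(x)
    cues = extract_syllable_cues(
        amplitude_envelope(rec), f0_track(rec), rec.syllables
    )
    assert cues[1].f0_missing
    assert np.isnan(cues[1].F)
    assert not cues[0].f0_missing and not cues[2].f0_missing


def test_interval_outside_track_is_alignment_error(tone_recording):
    env = amplitude_envelope(tone_recording)
    pit = f0_track(tone_recording)
    bad = [SyllableInterval(5.0, 5.5, "x"), SyllableInterval(5.5, 6.0, "y")]
    with pytest.raises(AlignmentError):
        extract_syllable_cues(env, pit, bad)


def test_envelope_peak_time_parabola():
    t = np.arange(0, 1.0, 0.01)
    v = 1.0 - (t - 0.35) ** 2
    env = EnvelopeTrack(t=t, value=v, rate=100.0)
    assert envelope_peak_time(env, SyllableInterval(0.2, 0.5, "a")) == pytest.approx(0.35)


def test_envelope_peak_time_monotone_rise_hits_interval_end():
    t = np.arange(0, 1.0, 0.01)
    env = EnvelopeTrack(t=t, value=t.copy(), rate=100.0)
    assert envelope_peak_time(env, SyllableInterval(0.2, 0.5, "a")) == pytest.approx(0.5)


def test_envelope_peak_time_empty_overlap():
    t = np.arange(0, 1.0, 0.01)
    env = EnvelopeTrack(t=t, value=t.copy(), rate=100.0)
    with pytest.raises(AlignmentError):
        envelope_peak_time(env, SyllableInterval(2.0, 2.5, "a"))


def test_synth_stressed_syllable_envelope_peak_near_am_peak(mismatch_item):
    for seed in range(5):
        wave, ivs = synth_utterance_audio(
            mismatch_item, mismatch_item.target_idx, CueBoosts(), seed=seed
        )
        rec = UtteranceRecording(wave, SR, ivs)
        env = amplitude_envelope(rec)
        t_peak = envelope_peak_time(env, ivs[mismatch_item.target_idx])
        assert abs(t_peak - am_peak_time(ivs[mismatch_item.target_idx])) <= 0.020


def test_time_shift_moves_cue_peaks():
    # prepend 100 ms of silence: the envelope peak shifts by +0.1 s
    t = np.arange(int(SR)) / SR
    mod = 0.5 * (1 - np.cos(2 * np.pi * 1.0 * t))
    x = mod * np.sin(2 * np.pi * 200.0 * t)
    rec0 = make_recording(x)
    rec1 = make_recording(
        np.concatenate([np.zeros(int(0.1 * SR)), x]),
        bounds=(0.1, 0.3, 0.6, 1.0),
    )
    env0 = amplitude_envelope(rec0)
    env1 = amplitude_envelope(rec1)
    p0 = envelope_peak_time(env0, rec0.syllables[1])
    p1 = envelope_peak_time(env1, rec1.syllables[1])
    assert p1 - p0 == pytest.approx(0.1, abs=1.0 / env0.rate + 1e-9)
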