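"""Acoustic feature extraction: amplitude envelope, f0 track, syllable cues.

The prominence metric consumes three cues per syllable: duration D (from the
boundary tier), peak f0 F (from the pitch track) and peak envelope amplitude
I.  The envelope is the magnitude of the analytic signal, low-passed with a
zero-phase 4th-order Butterworth filter (default cutoff 12 Hz) and resampled
to 100 Hz — the standard smooth-envelope recipe in gesture–speech coupling
work.  f0 comes from a frame-wise normalized-autocorrelation tracker with
parabolic peak interpolation (default search range 75–500 Hz, 10 ms hop).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .errors import AlignmentError, InsufficientDataError, ParameterError
from .io_formats import SyllableInterval, UtteranceRecording

__all__ = [
    "EnvelopeTrack",
    "PitchTrack",
    "SyllableCues",
    "amplitude_envelope",
    "f0_track",
    "extract_syllable_cues",
    "envelope_peak_time",
]


@dataclass
class EnvelopeTrack:
    """Uniformly sampled amplitude envelope (arbitrary units >= 0)."""

    t: np.ndarray
    value: np.ndarray
    rate: float


@dataclass
class PitchTrack:
    """Frame-wise f0 in Hz; NaN where the frame is unvoiced."""

    t: np.ndarray
    f0: np.ndarray
    rate: float

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)


@dataclass
class SyllableCues:
    """Raw per-syllable cues the prominence score is built from.

    D is exactly the boundary-tier duration; F is the maximum voiced f0
    inside the interval (NaN and ``f0_missing`` set if no frame is voiced);
    I is the maximum envelope amplitude inside the interval.
    """

    index: int
    D: float
    F: float
    I: float
    f0_missing: bool = False


def amplitude_envelope(
    rec: UtteranceRecording,
    cutoff_hz: float = 12.0,
    out_rate: float = 100.0,
) -> EnvelopeTrack:
    """Smooth amplitude envelope of the utterance waveform.

    Magnitude of the analytic (Hilbert) signal, zero-phase low-passed at
    ``cutoff_hz`` (4th-order Butterworth, applied forward and backward), then
    sampled on a uniform grid at ``out_rate``.
    """
    x = np.asarray(rec.waveform, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty waveform")
    if cutoff_hz >= out_rate / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz >= Nyquist of output rate {out_rate} Hz"
        )
    sr = rec.sample_rate
    n_fast = sp_fft.next_fast_len(len(x))
    analytic = signal.hilbert(x, N=n_fast)[: len(x)]
    env = np.abs(analytic)
    sos = signal.butter(4, cutoff_hz, btype="low", fs=sr, output="sos")
    env = signal.sosfiltfilt(sos, env)
    env = np.maximum(env, 0.0)  # filtering may undershoot slightly

    t_out = np.arange(0.0, len(x) / sr, 1.0 / out_rate)
    t_in = np.arange(len(x)) / sr
    v_out = np.interp(t_out, t_in, env)
    return EnvelopeTrack(t=t_out, value=v_out, rate=out_rate)


def f0_track(
    rec: UtteranceRecording,
    fmin: float = 75.0,
    fmax: float = 500.0,
    hop_s: float = 0.010,
    window_s: float = 0.040,
    voicing_threshold: float = 0.45,
    silence_rms: float = 1e-3,
) -> PitchTrack:
    """Autocorrelation f0 tracker with a per-frame voicing decision.

    A frame is voiced when its normalized autocorrelation peak within the
    candidate lag range exceeds ``voicing_threshold`` and its RMS exceeds
    ``silence_rms`` relative to the utterance peak.  Parabolic interpolation
    refines the lag of the autocorrelation maximum.
    """
    x = np.asarray(rec.waveform, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty waveform")
    sr = rec.sample_rate
    if not (fmin < fmax < sr / 2):
        raise ParameterError(f"need fmin < fmax < Nyquist, got [{fmin}, {fmax}]")

    win = int(round(window_s * sr))
    hop = int(round(hop_s * sr))
    if len(x) < win:
        x = np.pad(x, (0, win - len(x)))
    n_frames = 1 + (len(x) - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)

    # FFT-based autocorrelation, biased normalization by lag-0 energy
    nfft = sp_fft.next_fast_len(2 * win)
    spec = sp_fft.rfft(frames, nfft, axis=1)
    ac = sp_fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :win]
    e0 = ac[:, 0].copy()
    e0[e0 <= 0] = np.inf
    ac = ac / e0[:, None]

    lag_min = max(2, int(np.floor(sr / fmax)))
    lag_max = min(win - 2, int(np.ceil(sr / fmin)))
    if lag_max <= lag_min:
        raise ParameterError("f0 search range empty for this window length")
    band = ac[:, lag_min : lag_max + 1]
    peak_rel = np.argmax(band, axis=1)
    peak_lag = peak_rel + lag_min
    peak_val = band[np.arange(n_frames), peak_rel]

    # parabolic interpolation around the integer lag
    l0 = peak_lag
    y0 = ac[np.arange(n_frames), l0]
    ym = ac[np.arange(n_frames), l0 - 1]
    yp = ac[np.arange(n_frames), np.minimum(l0 + 1, win - 1)]
    denom = ym - 2 * y0 + yp
    safe = np.abs(denom) > 1e-12
    shift = np.zeros_like(denom)
    np.divide(0.5 * (ym - yp), denom, out=shift, where=safe)
    shift = np.clip(shift, -1.0, 1.0)
    lag = l0 + shift

    rms = np.sqrt(np.mean(frames**2, axis=1))
    rms_floor = silence_rms * max(np.max(np.abs(x)), 1e-12)
    voiced = (peak_val >= voicing_threshold) & (rms >= rms_floor)

    f0 = np.where(voiced, sr / lag, np.nan)
    # reject out-of-range refined estimates
    bad = voiced & ((f0 < fmin) | (f0 > fmax))
    f0[bad] = np.nan

    t = (np.arange(n_frames) * hop + win / 2) / sr
    return PitchTrack(t=t, f0=f0, rate=1.0 / hop_s)


def _in_interval(t: np.ndarray, interval: SyllableInterval) -> np.ndarray:
    return (t >= interval.start - 1e-9) & (t <= interval.end + 1e-9)


def extract_syllable_cues(
    env: EnvelopeTrack,
    pitch: PitchTrack,
    syllables: Sequence[SyllableInterval],
) -> list[SyllableCues]:
    """Aggregate D, F, I for each syllable interval.

    D is the boundary duration exactly; F the maximum voiced f0 whose frame
    center lies inside the interval; I the maximum envelope sample inside.
    A syllable with no voiced frame gets ``F = NaN`` and ``f0_missing=True``
    (the downstream z-scoring applies the missing-f0 policy).
    """
    t_env_max = env.t[-1]
    cues: list[SyllableCues] = []
    for i, syl in enumerate(syllables):
        if syl.start > t_env_max + 1e-6 or syl.end < env.t[0] - 1e-6:
            raise AlignmentError(
                f"syllable [{syl.start}, {syl.end}] outside envelope extent"
            )
        env_mask = _in_interval(env.t, syl)
        if not env_mask.any():
            raise AlignmentError(
                f"no envelope samples inside syllable [{syl.start}, {syl.end}]"
            )
        I = float(np.max(env.value[env_mask]))

        pit_mask = _in_interval(pitch.t, syl) & pitch.voiced
        if pit_mask.any():
            F = float(np.nanmax(pitch.f0[pit_mask]))
            missing = False
        else:
            F = float("nan")
            missing = True
        cues.append(
            SyllableCues(index=i, D=syl.duration, F=F, I=I, f0_missing=missing)
        )
    return cues


def envelope_peak_time(env: EnvelopeTrack, interval: SyllableInterval) -> float:
    """Time of the maximum envelope sample within one syllable interval.

    This is a local maximum of the word's envelope — it need not be the
    word-global maximum.  Flat maxima resolve to the earliest sample.
    """
    mask = _in_interval(env.t, interval)
    if not mask.any():
        raise AlignmentError(
            f"interval [{interval.start}, {interval.end}] does not overlap "
            "the envelope"
        )
    sub_t = env.t[mask]
    sub_v = env.value[mask]
    return float(sub_t[int(np.argmax(sub_v))])
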