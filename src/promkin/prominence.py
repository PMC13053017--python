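"""Composite prominence scoring and syllable nomination.

Each cue (duration, peak f0, peak envelope amplitude) is z-normalized across
the syllables of one utterance so the three become comparable, then combined
as a weighted sum

    S_i = W_F * z_F[i] + W_I * z_I[i] + W_D * z_D[i]

with equal weights 0.33 by default.  The syllable with the highest composite
score is nominated as the acoustically most prominent one; its envelope peak
time anchors all gesture–speech timing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .acoustic import EnvelopeTrack, SyllableCues, envelope_peak_time
from .errors import InsufficientDataError, ParameterError
from .io_formats import SyllableInterval

__all__ = [
    "ProminenceWeights",
    "ProminenceResult",
    "z_normalize",
    "cue_z_scores",
    "score_syllables",
    "nominate",
    "prominence_analysis",
]


@dataclass(frozen=True)
class ProminenceWeights:
    """Cue weights (W_F, W_I, W_D); all >= 0, not all zero.

    Nomination is invariant to scaling all weights by a common positive
    constant, so 0.33 and 1/3 give identical nominations.
    """

    W_F: float = 0.33
    W_I: float = 0.33
    W_D: float = 0.33

    def __post_init__(self) -> None:
        if min(self.W_F, self.W_I, self.W_D) < 0:
            raise ParameterError("prominence weights must be non-negative")
        if self.W_F == self.W_I == self.W_D == 0:
            raise ParameterError("prominence weights must not all be zero")


@dataclass
class ProminenceResult:
    """Per-syllable z-scores, composite scores, and the nominated index."""

    z_F: np.ndarray
    z_I: np.ndarray
    z_D: np.ndarray
    S: np.ndarray
    nominated: int
    peak_env_time: float | None = None
    flags: list[str] = field(default_factory=list)


def z_normalize(values: Sequence[float]) -> np.ndarray:
    """z-score a cue across the syllables of one utterance.

    Uses the sample (n-1) standard deviation.  A zero-variance cue maps to
    all zeros: it then contributes nothing to any syllable's score instead of
    propagating undefined values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("z-normalization needs at least 2 values")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not math.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def cue_z_scores(
    cues: Sequence[SyllableCues],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """z-score D, F, I across syllables, applying the missing-f0 policy.

    A wholly unvoiced syllable has no peak f0; its f0 z-score is set to the
    minimum z-score among the voiced syllables (absence of voicing must not
    win prominence), and the utterance is flagged ``f0_missing``.  If no
    syllable is voiced the f0 cue is neutral (all zeros).
    """
    D = np.array([c.D for c in cues], dtype=float)
    I = np.array([c.I for c in cues], dtype=float)
    F = np.array([c.F for c in cues], dtype=float)
    flags: list[str] = []

    z_D = z_normalize(D)
    z_I = z_normalize(I)

    voiced = ~np.isnan(F)
    if voiced.all():
        z_F = z_normalize(F)
    elif voiced.sum() >= 2:
        z_F = np.empty_like(F)
        z_voiced = z_normalize(F[voiced])
        z_F[voiced] = z_voiced
        z_F[~voiced] = z_voiced.min()
        flags.append("f0_missing")
    elif voiced.sum() == 1:
        # one voiced syllable: no spread to normalize against; it gets 0 and
        # the unvoiced ones sit at 0 too (neutral cue), but flag the trial
        z_F = np.zeros_like(F)
        flags.append("f0_missing")
    else:
        z_F = np.zeros_like(F)
        flags.append("f0_all_missing")
    return z_F, z_I, z_D, flags


def score_syllables(
    cues: Sequence[SyllableCues],
    w: ProminenceWeights = ProminenceWeights(),
) -> np.ndarray:
    """Composite prominence scores S_i for one utterance."""
    if len(cues) < 2:
        raise InsufficientDataError("scoring needs at least 2 syllables")
    z_F, z_I, z_D, _ = cue_z_scores(cues)
    return w.W_F * z_F + w.W_I * z_I + w.W_D * z_D


def nominate(scores: Sequence[float]) -> int:
    """Index of the highest-scoring syllable; exact ties go to the earliest."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise InsufficientDataError("nomination needs at least 2 scores")
    return int(np.argmax(s))  # np.argmax returns the first maximum


def prominence_analysis(
    cues: Sequence[SyllableCues],
    syllables: Sequence[SyllableInterval],
    env: EnvelopeTrack,
    w: ProminenceWeights = ProminenceWeights(),
) -> ProminenceResult:
    """Full nomination for one utterance.

    z-scores all cues, computes composite scores, nominates the argmax
    syllable, and locates the envelope peak inside the nominated syllable's
    interval (the speech anchor for asynchrony).
    """
    z_F, z_I, z_D, flags = cue_z_scores(cues)
    S = w.W_F * z_F + w.W_I * z_I + w.W_D * z_D
    nom = nominate(S)
    t_peak = envelope_peak_time(env, syllables[nom])
    return ProminenceResult(
        z_F=z_F, z_I=z_I, z_D=z_D, S=S, nominated=nom,
        peak_env_time=t_peak, flags=flags,
    )
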