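"""Hand-movement kinematics: displacement preprocessing and apex detection.

The kinematic variable is the change in the vertical position of the index
finger.  Preprocessing resamples the raw track to a uniform rate (default
50 Hz), orients it so that extension — the downward motion of the lower arm —
is a positive displacement from the trial's starting baseline, and smooths it
with a zero-phase low-pass filter (default 10 Hz; the biphasic beat's energy
sits well below that).  The apex is the global maximum of the extension
displacement inside the search window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import AlignmentError, InsufficientDataError
from .io_formats import PoseTrack

__all__ = [
    "SmoothConfig",
    "MovementEvent",
    "preprocess_track",
    "detect_max_extension",
    "movement_present",
]

#: Default displacement threshold separating movement from no-movement trials
#: (same units as the preprocessed track: pixels, or body-scaled if a
#: reference length is supplied).
DEFAULT_MOVEMENT_THRESHOLD = 0.3


@dataclass(frozen=True)
class SmoothConfig:
    """Smoothing/baseline parameters for :func:`preprocess_track`."""

    cutoff_hz: float = 10.0
    order: int = 4
    baseline_window_s: float = 0.2  # initial span averaged as the baseline
    reference_length: float | None = None  # body-scaling divisor, optional


@dataclass
class MovementEvent:
    """Detected maximum-extension apex of the biphasic movement."""

    t_ext: float
    extension_peak: float
    present: bool = True
    flags: list[str] | None = None


def preprocess_track(
    track: PoseTrack,
    out_rate: float = 50.0,
    smooth_cfg: SmoothConfig = SmoothConfig(),
) -> PoseTrack:
    """Uniformly resampled, oriented, baseline-subtracted, smoothed track.

    Orientation: with image coordinates (``y_down=True``) larger y is lower,
    so downward extension is already positive; otherwise the sign is flipped.
    The baseline is the mean of the first ``baseline_window_s`` seconds and is
    subtracted so the track starts near zero.  Optional body-scaling divides
    by ``reference_length`` (timing is scale-invariant; this only changes
    amplitude units).
    """
    t0, t1 = float(track.t[0]), float(track.t[-1])
    n_out = int(np.floor((t1 - t0) * out_rate)) + 1
    if n_out < 2:
        raise InsufficientDataError("track too short to resample")
    t_new = t0 + np.arange(n_out) / out_rate
    y_new = np.interp(t_new, track.t, track.y)

    sign = 1.0 if track.y_down else -1.0
    disp = sign * y_new

    n_base = max(1, int(round(smooth_cfg.baseline_window_s * out_rate)))
    disp = disp - float(np.mean(disp[:n_base]))

    if smooth_cfg.cutoff_hz < out_rate / 2:
        sos = signal.butter(
            smooth_cfg.order, smooth_cfg.cutoff_hz, btype="low",
            fs=out_rate, output="sos",
        )
        padlen = 3 * (2 * smooth_cfg.order + 1)
        if n_out <= padlen:
            raise InsufficientDataError(
                f"track of {n_out} samples shorter than filter warm-up "
                f"({padlen} samples)"
            )
        disp = signal.sosfiltfilt(sos, disp)

    if smooth_cfg.reference_length:
        disp = disp / smooth_cfg.reference_length

    return PoseTrack(t=t_new, y=disp, y_down=True, nominal_rate=out_rate)


def detect_max_extension(
    track: PoseTrack,
    window: tuple[float, float] | None = None,
) -> MovementEvent:
    """Apex = time of the global maximum extension displacement in ``window``.

    ``window`` defaults to the full track.  An apex landing on the window
    edge is flagged (``apex_at_window_edge``) rather than rejected, so
    truncated recordings stay inspectable.  Flat maxima resolve to the
    earliest sample.
    """
    if window is None:
        window = (float(track.t[0]), float(track.t[-1]))
    t0, t1 = window
    mask = (track.t >= t0 - 1e-9) & (track.t <= t1 + 1e-9)
    if not mask.any():
        raise AlignmentError(
            f"search window [{t0}, {t1}] does not overlap the track"
        )
    t_sub = track.t[mask]
    y_sub = track.y[mask]
    k = int(np.argmax(y_sub))
    flags = []
    if k == 0 or k == len(y_sub) - 1:
        flags.append("apex_at_window_edge")
    return MovementEvent(
        t_ext=float(t_sub[k]),
        extension_peak=float(y_sub[k]),
        present=True,
        flags=flags,
    )


def movement_present(
    track: PoseTrack,
    threshold: float = DEFAULT_MOVEMENT_THRESHOLD,
) -> bool:
    """True iff the track's peak extension reaches ``threshold``.

    Quality control for the blocked design: no-movement trials should show
    only tracking noise far below the threshold.
    """
    event = detect_max_extension(track)
    return bool(event.extension_peak >= threshold)
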