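"""Reading and writing the external data formats.

Three formats come from outside the pipeline: mono WAV audio of single spoken
words, Praat TextGrid files carrying syllable boundaries (as produced by
forced aligners), and delimited pose tables with the vertical index-finger
position over time (as produced by video-based motion trackers).  The tidy
per-trial table the analysis layer consumes is also written here.

All times are seconds internally; asynchronies are converted to milliseconds
only at reporting time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import (
    FormatError,
    InsufficientDataError,
    MissingTierError,
)

DEFAULT_TIER_NAME = "syllables"

__all__ = [
    "SyllableInterval",
    "UtteranceRecording",
    "PoseTrack",
    "read_wav",
    "write_wav",
    "read_syllable_tier",
    "write_syllable_tier",
    "read_pose_track",
    "write_pose_track",
    "write_trial_table",
    "read_trial_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyllableInterval:
    """One syllable's time interval, in seconds, with its label."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise FormatError(
                f"syllable interval must have end > start, got "
                f"[{self.start}, {self.end}]"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class UtteranceRecording:
    """A single spoken word: waveform plus its syllable segmentation.

    ``waveform`` holds amplitude samples in [-1, 1]; ``syllables`` is
    time-ordered and non-overlapping.  Multisyllabic words only (>=2
    syllables) — prominence is relative by definition.
    """

    waveform: np.ndarray
    sample_rate: float
    syllables: list[SyllableInterval]
    item_id: str = ""
    speaker_id: str = ""
    movement_block: bool = False

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if len(self.syllables) < 2:
            raise InsufficientDataError(
                "an utterance must contain at least two syllables"
            )
        _check_intervals(self.syllables)
        if self.syllables[-1].end > self.duration + 1e-9:
            raise FormatError(
                f"last syllable ends at {self.syllables[-1].end:.4f} s but the "
                f"waveform lasts only {self.duration:.4f} s"
            )

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.sample_rate


@dataclass
class PoseTrack:
    """Vertical position of the index finger over time.

    ``y`` is in input units (pixels or body-scaled units).  ``y_down`` marks
    image-style coordinates in which larger y means lower on screen.
    ``nominal_rate`` is the sampling rate implied by the median time step.
    """

    t: np.ndarray
    y: np.ndarray
    y_down: bool = True
    nominal_rate: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise FormatError("pose track t and y must be 1-D and equal-length")
        if len(self.t) < 2:
            raise InsufficientDataError("pose track needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise FormatError("pose track time must be strictly increasing")
        if self.nominal_rate is None:
            rate = float(1.0 / np.median(np.diff(self.t)))
            # snap to the integer rate when the difference is float noise
            if abs(rate - round(rate)) < 1e-6 * rate:
                rate = float(round(rate))
            self.nominal_rate = rate


def _check_intervals(intervals: Sequence[SyllableInterval]) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if b.start < a.end - 1e-9:
            raise FormatError(
                f"overlapping or unordered intervals: "
                f"[{a.start}, {a.end}] then [{b.start}, {b.end}]"
            )


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono PCM WAV file; returns (float waveform in [-1, 1], rate)."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, float(rate)


def write_wav(path: str | Path, waveform: np.ndarray, rate: float) -> None:
    """Write a float waveform in [-1, 1] as 16-bit PCM."""
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(round(rate)), (x * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# Praat TextGrid (long and short text formats)
# ---------------------------------------------------------------------------

_NUM = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def _textgrid_tokens(text: str) -> list[str]:
    """Flatten a TextGrid body into a token stream of numbers and strings.

    Works for both the long (``xmin = 0``) and short (bare values) dialects:
    we only ever consume quoted strings and numbers, in document order, so the
    surrounding keywords of the long format are ignored.
    """
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == '"':
            j = i + 1
            buf = []
            while j < n:
                if text[j] == '"':
                    if j + 1 < n and text[j + 1] == '"':  # escaped quote
                        buf.append('"')
                        j += 2
                        continue
                    break
                buf.append(text[j])
                j += 1
            tokens.append('"' + "".join(buf))
            i = j + 1
        elif ch.isdigit() or (
            ch == "-" and i + 1 < n and text[i + 1].isdigit()
        ):
            m = _NUM.match(text, i)
            assert m is not None
            tokens.append(m.group(0))
            i = m.end()
        else:
            i += 1
    return tokens


def _parse_textgrid(text: str) -> list[dict]:
    """Parse a TextGrid into a list of tiers.

    Each tier is ``{"class", "name", "xmin", "xmax", "entries"}`` where
    entries are (xmin, xmax, label) for interval tiers and (time, label) for
    point tiers.
    """
    header = text.lstrip()
    if not header.startswith('File type = "ooTextFile"'):
        raise FormatError("not a Praat TextGrid (missing ooTextFile header)")
    if "TextGrid" not in header[: header.find("\n", header.find("\n") + 1) + 40]:
        raise FormatError("not a Praat TextGrid (missing object class)")
    # drop the two header lines; strip long-format index brackets ("item [1]:",
    # "intervals [2]:") so their digits don't pollute the number stream
    body = text.split("\n", 2)[2] if text.count("\n") >= 2 else ""
    body = re.sub(r"\[\s*\d*\s*\]", "", body)
    toks = _textgrid_tokens(body)
    pos = 0

    def num() -> float:
        nonlocal pos
        while pos < len(toks) and toks[pos].startswith('"'):
            pos += 1  # tolerate stray strings (e.g. "<exists>" variants)
        if pos >= len(toks):
            raise FormatError("truncated TextGrid")
        v = float(toks[pos])
        pos += 1
        return v

    def string() -> str:
        nonlocal pos
        while pos < len(toks) and not toks[pos].startswith('"'):
            pos += 1
        if pos >= len(toks):
            raise FormatError("truncated TextGrid")
        v = toks[pos][1:]
        pos += 1
        return v

    num()  # global xmin
    num()  # global xmax
    n_tiers = int(num())
    tiers: list[dict] = []
    for _ in range(n_tiers):
        klass = string()
        name = string()
        t0, t1 = num(), num()
        size = int(num())
        entries = []
        if klass == "IntervalTier":
            for _ in range(size):
                a, b = num(), num()
                entries.append((a, b, string()))
        elif klass == "TextTier":
            for _ in range(size):
                entries.append((num(), string()))
        else:
            raise FormatError(f"unknown tier class {klass!r}")
        tiers.append(
            {"class": klass, "name": name, "xmin": t0, "xmax": t1,
             "entries": entries}
        )
    return tiers


def read_syllable_tier(
    path: str | Path, tier_name: str = DEFAULT_TIER_NAME
) -> list[SyllableInterval]:
    """Read one interval tier from a Praat TextGrid (long or short format).

    Returns only intervals with a non-empty, non-whitespace label (silences
    excluded), time-ordered, times in seconds.

    Raises :class:`MissingTierError` if no interval tier of that name exists
    and :class:`FormatError` on overlapping intervals or unparsable files.
    """
    text = Path(path).read_text(encoding="utf-8")
    tiers = _parse_textgrid(text)
    for tier in tiers:
        if tier["class"] == "IntervalTier" and tier["name"] == tier_name:
            out = [
                SyllableInterval(a, b, lab)
                for a, b, lab in tier["entries"]
                if lab.strip()
            ]
            out.sort(key=lambda s: s.start)
            _check_intervals(out)
            return out
    available = [t["name"] for t in tiers]
    raise MissingTierError(
        f"no interval tier named {tier_name!r} in {path} "
        f"(available: {available})"
    )


def write_syllable_tier(
    path: str | Path,
    intervals: Sequence[SyllableInterval],
    tier_name: str = DEFAULT_TIER_NAME,
    xmax: float | None = None,
) -> None:
    """Write intervals as a single-tier long-format TextGrid.

    Gaps between labeled syllables (and before/after the word) are filled
    with empty intervals, as aligners do.
    """
    ivs = sorted(intervals, key=lambda s: s.start)
    _check_intervals(ivs)
    if xmax is None:
        xmax = ivs[-1].end
    full: list[tuple[float, float, str]] = []
    cursor = 0.0
    for iv in ivs:
        if iv.start > cursor + 1e-9:
            full.append((cursor, iv.start, ""))
        full.append((iv.start, iv.end, iv.label))
        cursor = iv.end
    if xmax > cursor + 1e-9:
        full.append((cursor, xmax, ""))

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {xmax:.6f}",
        f"        intervals: size = {len(full)}",
    ]
    for k, (a, b, lab) in enumerate(full, start=1):
        lines += [
            f"        intervals [{k}]:",
            f"            xmin = {a:.6f}",
            f"            xmax = {b:.6f}",
            f'            text = "{lab}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

def read_pose_track(
    path: str | Path,
    y_down: bool = True,
    time_column: str = "time_s",
    y_column: str = "y",
) -> PoseTrack:
    """Read a delimited pose table into a :class:`PoseTrack`.

    The table must carry a time column (seconds) and a vertical-position
    column; trackers that emit one column per landmark are handled by naming
    the column to use.  The nominal sampling rate is inferred from the median
    time step.
    """
    df = pd.read_csv(path)
    for col in (time_column, y_column):
        if col not in df.columns:
            raise FormatError(
                f"pose table {path} lacks column {col!r} "
                f"(has {list(df.columns)})"
            )
    if len(df) < 2:
        raise InsufficientDataError(
            f"pose table {path} has {len(df)} rows; need at least 2"
        )
    t = df[time_column].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"pose table {path} time is not strictly increasing")
    return PoseTrack(t=t, y=df[y_column].to_numpy(dtype=float), y_down=y_down)


def write_pose_track(path: str | Path, track: PoseTrack) -> None:
    pd.DataFrame({"time_s": track.t, "y": track.y}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trial table
# ---------------------------------------------------------------------------

#: Column order of the tidy trial table; missing values are written empty.
TRIAL_COLUMNS = [
    "speaker_id",
    "item_id",
    "movement",
    "n_syll",
    "nominated",
    "production_class",
    "condition",
    "distance",
    "asynchrony_ms",
    "phon_asynchrony_ms",
    "peak_intensity",
    "peak_env_time",
    "apex_time",
    "flags",
]


def write_trial_table(records, path: str | Path) -> None:
    """Write trial records as a comma-delimited table, one row per trial.

    ``records`` may be a DataFrame or a list of dicts/dataclass-like objects
    sharing one schema.  Missing values are encoded as empty fields.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if isinstance(r, dict):
                rows.append(r)
            else:
                rows.append(vars(r))
        df = pd.DataFrame(rows, columns=TRIAL_COLUMNS if not rows else None)
    cols = [c for c in TRIAL_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in TRIAL_COLUMNS
    ]
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=TRIAL_COLUMNS)
        cols = TRIAL_COLUMNS
    df[cols].to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
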