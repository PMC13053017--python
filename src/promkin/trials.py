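"""Trial-level joining, classification, and asynchrony.

A trial is one speaker producing one cognate item once, with or without the
instructed up-and-down hand movement.  The item table fixes, per cognate, the
L2 (Spanish) target stress position and the L1 (Dutch) competitor position.
From the nominated prominent syllable we classify the production
(correct_L2 / incorrect_L1 / other), attach the timing condition, and compute
the gesture–speech asynchrony: apex time minus envelope-peak time, in ms
(negative = the hand leads speech).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "CognateItem",
    "TrialRecord",
    "PRODUCTION_CLASSES",
    "CONDITIONS",
    "classify_production",
    "compute_asynchrony",
    "label_condition",
    "verification_agreement",
    "phonological_anchor_asynchrony",
    "read_item_table",
    "write_item_table",
    "filter_medial_stress_items",
]

PRODUCTION_CLASSES = ("correct_L2", "incorrect_L1", "other")
CONDITIONS = (
    "matching_correct",
    "precede_correct",
    "follow_correct",
    "precede_incorrect",
    "follow_incorrect",
    "excluded",
)


@dataclass(frozen=True)
class CognateItem:
    """One Dutch–Spanish cognate and its stress geometry.

    ``target_idx`` is the correctly stressed syllable in L2 Spanish,
    ``competitor_idx`` the stressed syllable of the L1 Dutch counterpart;
    both 0-based.  ``distance`` = competitor − target in signed syllables
    (negative: competitor precedes the target).
    """

    item_id: str
    word: str
    n_syll: int
    target_idx: int
    competitor_idx: int
    accent_mark: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.target_idx < self.n_syll):
            raise FormatError(f"{self.item_id}: target_idx out of range")
        if not (0 <= self.competitor_idx < self.n_syll):
            raise FormatError(f"{self.item_id}: competitor_idx out of range")

    @property
    def matching(self) -> bool:
        return self.target_idx == self.competitor_idx

    @property
    def distance(self) -> int:
        return self.competitor_idx - self.target_idx


@dataclass
class TrialRecord:
    """Joined unit of analysis; one row of the tidy trial table."""

    speaker_id: str
    item_id: str
    movement: bool
    n_syll: int
    nominated: int
    production_class: str
    condition: str
    distance: int
    asynchrony_ms: float | None = None
    phon_asynchrony_ms: float | None = None
    peak_intensity: float | None = None
    peak_env_time: float | None = None
    apex_time: float | None = None
    flags: str = ""


def classify_production(nominated: int, item: CognateItem) -> str:
    """Production class of a trial from its nominated prominent syllable.

    correct_L2 if the nominated syllable is the L2 target; incorrect_L1 if it
    is the (distinct) L1 competitor; otherwise "other".
    """
    if nominated == item.target_idx:
        return "correct_L2"
    if nominated == item.competitor_idx:
        return "incorrect_L1"
    return "other"


def compute_asynchrony(t_ext: float, t_peak_env: float) -> float:
    """Gesture–speech asynchrony in ms: (apex − envelope peak) × 1000.

    Positive: the hand movement follows speech; negative: it precedes.
    """
    return (t_ext - t_peak_env) * 1000.0


def label_condition(item: CognateItem, production_class: str) -> str:
    """Timing condition from the item's stress geometry and the production.

    The attractor syllable is always the one NOT acoustically produced: for
    correct L2 productions it is the L1 competitor, for incorrect (competitor
    -stressed) productions it is the L2 target.  "precede"/"follow" say where
    the attractor sits relative to the produced (anchor) syllable.  Matching
    items with correct productions are the baseline; everything else
    (residual productions, matching-incorrect) is excluded from the timing
    models but kept in the trial table.
    """
    if production_class == "other":
        return "excluded"
    if item.matching:
        return "matching_correct" if production_class == "correct_L2" else "excluded"
    if production_class == "correct_L2":
        return "precede_correct" if item.competitor_idx < item.target_idx else "follow_correct"
    # incorrect_L1 on a mismatching item: attractor is the target
    return "precede_incorrect" if item.target_idx < item.competitor_idx else "follow_incorrect"


def verification_agreement(
    records: Sequence[TrialRecord] | pd.DataFrame,
    stress_annotation: Mapping[str, int],
) -> float:
    """Fraction of trials whose nominated syllable matches the annotated
    phonologically stressed syllable.

    Used to verify the acoustic metric against speakers assumed to stress
    correctly (native speakers).
    """
    if isinstance(records, pd.DataFrame):
        items = records["item_id"].tolist()
        noms = records["nominated"].tolist()
    else:
        items = [r.item_id for r in records]
        noms = [r.nominated for r in records]
    if not items:
        raise DataError("no trials to score agreement on")
    hits = 0
    for item_id, nom in zip(items, noms):
        if item_id not in stress_annotation:
            raise DataError(f"no stress annotation for item {item_id!r}")
        hits += int(nom == stress_annotation[item_id])
    return hits / len(items)


def phonological_anchor_asynchrony(
    apex_time: float,
    env,
    target_interval,
) -> float:
    """Asynchrony anchored at the L2 target syllable, ignoring nomination.

    The speech anchor is the envelope peak inside the phonologically stressed
    (target) syllable's interval regardless of which syllable the speaker
    acoustically emphasized — the acoustics-independent robustness analysis.
    """
    from .acoustic import envelope_peak_time

    t_peak = envelope_peak_time(env, target_interval)
    return compute_asynchrony(apex_time, t_peak)


# ---------------------------------------------------------------------------
# item table I/O and filters
# ---------------------------------------------------------------------------

ITEM_COLUMNS = ["item_id", "word", "n_syll", "target_idx", "competitor_idx",
                "accent_mark"]


def read_item_table(path: str | Path) -> list[CognateItem]:
    df = pd.read_csv(path)
    missing = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"item table {path} lacks columns {missing}")
    return [
        CognateItem(
            item_id=str(r.item_id),
            word=str(r.word),
            n_syll=int(r.n_syll),
            target_idx=int(r.target_idx),
            competitor_idx=int(r.competitor_idx),
            accent_mark=bool(r.accent_mark),
        )
        for r in df.itertuples()
    ]


def write_item_table(items: Iterable[CognateItem], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "item_id": it.item_id,
                "word": it.word,
                "n_syll": it.n_syll,
                "target_idx": it.target_idx,
                "competitor_idx": it.competitor_idx,
                "accent_mark": it.accent_mark,
            }
            for it in items
        ]
    ).to_csv(path, index=False)


def filter_medial_stress_items(items: Sequence[CognateItem]) -> list[CognateItem]:
    """Items whose L2 target stress is neither word-initial nor word-final.

    The robustness subset: excluding initial- and final-stress items checks
    that timing effects are not driven by stress sitting at a word edge.
    """
    return [
        it for it in items
        if 0 < it.target_idx < it.n_syll - 1
    ]
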