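"""Mechanical characterization of disagreements between two label sets.

Mirrors the machine-checkable part of a disagreement validity assessment:
each position where two raters' labels differ is extracted and annotated
with the features that recur in disagreement analyses — very short duration,
reliance on a probable diagnosis, the triptan rule, and aura involvement.
Attributing a disagreement to human error requires human review and is
deliberately out of scope; only raw (label_a, label_b) pair counts are
reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .engine import ClassificationResult
from .events import HeadacheEvent, HeadacheLabel


@dataclass(frozen=True)
class DisagreementCase:
    """One event the two raters labelled differently."""

    event_id: str
    label_a: HeadacheLabel
    label_b: HeadacheLabel
    short_duration: bool
    probable_based: bool
    triptan_based: bool
    aura_involved: bool

    def __post_init__(self):
        if self.label_a == self.label_b:
            raise ValueError("not a disagreement: labels are equal")


def find_disagreements(
    events: Sequence[HeadacheEvent],
    results_a: Sequence[ClassificationResult],
    labels_b: Sequence[HeadacheLabel],
    short_duration_h: float = 0.5,
) -> list[DisagreementCase]:
    """All positions where rater A's and rater B's labels differ.

    ``results_a`` supplies the provenance flags for the A side; ``labels_b``
    is the other rater's bare labels.  Collections must be aligned.
    """
    if not len(events) == len(results_a) == len(labels_b):
        raise ValueError(
            "events, results_a and labels_b must be aligned: lengths "
            f"{len(events)}, {len(results_a)}, {len(labels_b)}"
        )
    cases = []
    for event, res, label_b in zip(events, results_a, labels_b):
        label_b = HeadacheLabel(label_b)
        if res.label == label_b:
            continue
        cases.append(
            DisagreementCase(
                event_id=event.event_id,
                label_a=res.label,
                label_b=label_b,
                short_duration=event.duration_h < short_duration_h,
                probable_based=res.probable_based,
                triptan_based=res.triptan_based,
                aura_involved=event.aura,
            )
        )
    return cases


def pair_counts(cases: Sequence[DisagreementCase]) -> dict[tuple[str, str], int]:
    """Counts of disagreements per (label_a, label_b) pair."""
    return dict(Counter((c.label_a.value, c.label_b.value) for c in cases))


def proportion_probable(results: Sequence[ClassificationResult]) -> float:
    """Fraction of classifications that rest on a probable diagnosis."""
    if len(results) == 0:
        raise ValueError("empty results collection")
    return sum(r.probable_based for r in results) / len(results)


def cases_to_frame(cases: Sequence[DisagreementCase]) -> pd.DataFrame:
    """Tabulate disagreement cases for reporting."""
    return pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "label_a": c.label_a.value,
                "label_b": c.label_b.value,
                "short_duration": c.short_duration,
                "probable_based": c.probable_based,
                "triptan_based": c.triptan_based,
                "aura_involved": c.aura_involved,
            }
            for c in cases
        ],
        columns=[
            "event_id",
            "label_a",
            "label_b",
            "short_duration",
            "probable_based",
            "triptan_based",
            "aura_involved",
        ],
    )
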