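"""ICHD-3 rule engine for single headache attacks.

Operationalizes the ICHD-3 criteria B-D for migraine (1.1) and for
tension-type headache (2.x), the probable-diagnosis relaxation (all criteria
but exactly one fulfilled), and the decision cascade that merges both
evaluations into one label per attack:

1. a triptan that relieved the attack ⇒ migraine (MA if aura else MO);
2. attacks shorter than 30 min are set aside as not classifiable (too many
   short-lasting differential diagnoses — TACs, other primary headaches);
3. definite migraine;
4. definite TTH (a definite diagnosis trumps any probable one);
5. probable migraine, counted as migraine when the patient has a migraine
   history;
6. probable TTH, when the patient has a TTH history;
7. otherwise not classifiable.

Duration windows: migraine 4-72 h (waived for triptan-responsive attacks,
since the ICHD-3 window applies only to untreated or unsuccessfully treated
attacks), TTH 30 min - 7 days.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .events import Certainty, HeadacheEvent, HeadacheLabel, PatientHistory


class VrsIntensity(enum.IntEnum):
    """ICHD-3 verbal rating scale for pain intensity, ordered."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


class Disorder(str, enum.Enum):
    MIGRAINE = "MIGRAINE"
    TTH = "TTH"


class CriteriaStatus(str, enum.Enum):
    DEFINITE = "DEFINITE"
    PROBABLE = "PROBABLE"
    NOT_MET = "NOT_MET"


class RuleConfig(BaseModel):
    """Numeric constants of the rule engine.

    ``migraine_duration_h`` / ``tth_duration_h`` are the closed criterion-B
    windows in hours; ``short_duration_h`` is the not-classifiable cutoff
    (attacks strictly shorter are set aside); ``nrs_breaks`` are the inclusive
    upper NRS bounds of the none / mild / moderate verbal bands (everything
    above the last break is severe).
    """

    model_config = ConfigDict(frozen=True)

    migraine_duration_h: tuple[float, float] = (4.0, 72.0)
    tth_duration_h: tuple[float, float] = (0.5, 168.0)
    short_duration_h: float = 0.5
    nrs_breaks: tuple[int, int, int] = (0, 3, 6)

    @model_validator(mode="after")
    def _check(self) -> "RuleConfig":
        for name in ("migraine_duration_h", "tth_duration_h"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: empty interval [{lo}, {hi}]")
        if self.short_duration_h > self.tth_duration_h[0]:
            raise ValueError(
                "short_duration_h must not exceed the lower TTH duration bound"
            )
        b0, b1, b2 = self.nrs_breaks
        if not 0 <= b0 < b1 < b2 <= 10:
            raise ValueError("nrs_breaks must be strictly increasing within 0..10")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "migraine_duration_h": list(self.migraine_duration_h),
                    "tth_duration_h": list(self.tth_duration_h),
                    "short_duration_h": self.short_duration_h,
                    "nrs_breaks": list(self.nrs_breaks),
                },
                fh,
            )


DEFAULT_CONFIG = RuleConfig()


class CriteriaEvaluation(BaseModel):
    """Trace of ICHD-3 criteria B-D for one disorder on one event."""

    model_config = ConfigDict(frozen=True)

    disorder: Disorder
    b_met: bool
    c_count: int
    c_met: bool
    d_met: bool
    status: CriteriaStatus

    @model_validator(mode="after")
    def _check(self) -> "CriteriaEvaluation":
        if not 0 <= self.c_count <= 4:
            raise ValueError("c_count must be in 0..4")
        if self.c_met != (self.c_count >= 2):
            raise ValueError("c_met must equal (c_count >= 2)")
        if self.status != _status(self.b_met, self.c_met, self.d_met):
            raise ValueError("status inconsistent with b/c/d")
        return self


class ClassificationResult(BaseModel):
    """Final label for one event plus provenance of how it was reached."""

    model_config = ConfigDict(frozen=True)

    event_id: str
    label: HeadacheLabel
    certainty: Certainty
    short_duration_flag: bool = False
    triptan_based: bool = False
    probable_based: bool = False
    migraine_eval: Optional[CriteriaEvaluation] = None
    tth_eval: Optional[CriteriaEvaluation] = None
    rationale: str = ""

    @model_validator(mode="after")
    def _check(self) -> "ClassificationResult":
        if self.short_duration_flag and not (
            self.label is HeadacheLabel.NOT_CLASSIFIABLE
            and self.certainty is Certainty.NONE
        ):
            raise ValueError(
                "short_duration_flag requires label NOT_CLASSIFIABLE and certainty NONE"
            )
        if self.triptan_based and self.label not in (HeadacheLabel.MO, HeadacheLabel.MA):
            raise ValueError("triptan_based requires a migraine label")
        return self


def _status(b: bool, c: bool, d: bool) -> CriteriaStatus:
    n_false = (not b) + (not c) + (not d)
    if n_false == 0:
        return CriteriaStatus.DEFINITE
    if n_false == 1:
        # Probable regardless of how badly the single failed criterion fails
        # (in particular c_count may be 0).
        return CriteriaStatus.PROBABLE
    return CriteriaStatus.NOT_MET


def map_nrs_to_vrs(pain_nrs: int, breaks: tuple[int, int, int] = (0, 3, 6)) -> VrsIntensity:
    """Map an NRS-11 pain rating to the ICHD-3 verbal rating scale.

    Default bands: 0 → none, 1-3 → mild, 4-6 → moderate, 7-10 → severe.
    """
    if not isinstance(pain_nrs, (int,)) or isinstance(pain_nrs, bool):
        raise TypeError("pain_nrs must be an integer")
    if not 0 <= pain_nrs <= 10:
        raise ValueError(f"pain_nrs out of range 0..10: {pain_nrs}")
    b0, b1, b2 = breaks
    if pain_nrs <= b0:
        return VrsIntensity.NONE
    if pain_nrs <= b1:
        return VrsIntensity.MILD
    if pain_nrs <= b2:
        return VrsIntensity.MODERATE
    return VrsIntensity.SEVERE


def evaluate_migraine(
    event: HeadacheEvent, config: RuleConfig = DEFAULT_CONFIG
) -> CriteriaEvaluation:
    """Evaluate ICHD-3 migraine criteria B-D on one attack.

    B: duration within the migraine window, or a triptan relieved the attack
    (the window holds only for untreated/unsuccessfully treated attacks).
    C (≥2 of 4): one-sided, pulsating, moderate-or-severe pain, aggravation by
    routine physical activity.
    D: nausea or vomiting, or photophobia together with phonophobia.
    """
    lo, hi = config.migraine_duration_h
    b = (lo <= event.duration_h <= hi) or event.triptan_taken_and_effective is True
    vrs = map_nrs_to_vrs(event.pain_nrs, config.nrs_breaks)
    c_items = (
        event.one_sided,
        event.pulsating,
        vrs >= VrsIntensity.MODERATE,
        event.aggravated_by_activity,
    )
    c_count = sum(c_items)
    d = (event.nausea or event.vomiting) or (event.photophobia and event.phonophobia)
    return CriteriaEvaluation(
        disorder=Disorder.MIGRAINE,
        b_met=b,
        c_count=c_count,
        c_met=c_count >= 2,
        d_met=d,
        status=_status(b, c_count >= 2, d),
    )


def evaluate_tth(
    event: HeadacheEvent, config: RuleConfig = DEFAULT_CONFIG
) -> CriteriaEvaluation:
    """Evaluate ICHD-3 tension-type headache criteria B-D on one attack.

    B: duration 30 min to 7 days.
    C (≥2 of 4): both-sided, pressing/tightening, mild-or-moderate pain, NOT
    aggravated by routine physical activity.
    D: no nausea or vomiting, and not both photophobia and phonophobia —
    the logical complement of the migraine D criterion.
    """
    lo, hi = config.tth_duration_h
    b = lo <= event.duration_h <= hi
    vrs = map_nrs_to_vrs(event.pain_nrs, config.nrs_breaks)
    c_items = (
        event.both_sided,
        event.pressing,
        vrs in (VrsIntensity.MILD, VrsIntensity.MODERATE),
        not event.aggravated_by_activity,
    )
    c_count = sum(c_items)
    d = not (event.nausea or event.vomiting) and not (
        event.photophobia and event.phonophobia
    )
    return CriteriaEvaluation(
        disorder=Disorder.TTH,
        b_met=b,
        c_count=c_count,
        c_met=c_count >= 2,
        d_met=d,
        status=_status(b, c_count >= 2, d),
    )


def _migraine_label(event: HeadacheEvent) -> HeadacheLabel:
    return HeadacheLabel.MA if event.aura else HeadacheLabel.MO


def classify_event(
    event: HeadacheEvent,
    history: PatientHistory | None = None,
    config: RuleConfig = DEFAULT_CONFIG,
) -> ClassificationResult:
    """Classify one attack through the decision cascade (see module docstring).

    Pure and deterministic in (event, history, config).
    """
    if history is None:
        history = PatientHistory()
    mig = evaluate_migraine(event, config)
    tth = evaluate_tth(event, config)
    common = dict(event_id=event.event_id, migraine_eval=mig, tth_eval=tth)

    # 1. Triptan response is treated as positive evidence for migraine and is
    # checked before the short-duration rule: a successfully aborted short
    # attack still counts as migraine.
    if event.triptan_taken_and_effective is True:
        certainty = (
            Certainty.DEFINITE
            if mig.status is CriteriaStatus.DEFINITE
            else Certainty.PROBABLE
        )
        return ClassificationResult(
            label=_migraine_label(event),
            certainty=certainty,
            triptan_based=True,
            rationale="Triptan relieved the attack; counted as migraine.",
            **common,
        )

    # 2. Short attacks have too many differential diagnoses to classify.
    if event.duration_h < config.short_duration_h:
        return ClassificationResult(
            label=HeadacheLabel.NOT_CLASSIFIABLE,
            certainty=Certainty.NONE,
            short_duration_flag=True,
            rationale=(
                f"Duration {event.duration_h:.2f} h below the "
                f"{config.short_duration_h:.2f} h cutoff; set aside as not classified."
            ),
            **common,
        )

    # 3./4. Definite diagnoses trump probable ones; migraine before TTH.
    if mig.status is CriteriaStatus.DEFINITE:
        return ClassificationResult(
            label=_migraine_label(event),
            certainty=Certainty.DEFINITE,
            rationale="All migraine criteria B-D fulfilled.",
            **common,
        )
    if tth.status is CriteriaStatus.DEFINITE:
        return ClassificationResult(
            label=HeadacheLabel.TTH,
            certainty=Certainty.DEFINITE,
            rationale="All TTH criteria B-D fulfilled (definite trumps probable).",
            **common,
        )

    # 5./6. Probable diagnoses require the corresponding history (criterion A).
    if mig.status is CriteriaStatus.PROBABLE and history.has_migraine_history:
        return ClassificationResult(
            label=_migraine_label(event),
            certainty=Certainty.PROBABLE,
            probable_based=True,
            rationale=(
                "Probable migraine (one criterion missed) with a migraine "
                "history; counted as migraine."
            ),
            **common,
        )
    if tth.status is CriteriaStatus.PROBABLE and history.has_tth_history:
        return ClassificationResult(
            label=HeadacheLabel.TTH,
            certainty=Certainty.PROBABLE,
            probable_based=True,
            rationale="Probable TTH (one criterion missed) with a TTH history.",
            **common,
        )

    # 7./8. Nothing applies.
    if mig.status is CriteriaStatus.PROBABLE:
        why = "Probable migraine but no migraine history; not classifiable."
    elif tth.status is CriteriaStatus.PROBABLE:
        why = "Probable TTH but no TTH history; not classifiable."
    else:
        why = "Neither migraine nor TTH criteria sufficiently fulfilled."
    return ClassificationResult(
        label=HeadacheLabel.NOT_CLASSIFIABLE,
        certainty=Certainty.NONE,
        rationale=why,
        **common,
    )


def classify_diary(
    events: Iterable[HeadacheEvent],
    history: PatientHistory | None = None,
    config: RuleConfig = DEFAULT_CONFIG,
) -> list[ClassificationResult]:
    """Classify a diary (ordered collection of attacks) element-wise."""
    return [classify_event(e, history, config) for e in events]


def summarize_labels(results: Sequence[ClassificationResult]) -> dict[str, int]:
    """Counts per label, in canonical category order."""
    counts = {label.value: 0 for label in HeadacheLabel}
    for r in results:
        counts[r.label.value] += 1
    return counts
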