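"""Domain types for electronic headache-diary events.

A diary event is one self-reported headache attack: start/end clock times,
pain intensity on the 11-point numeric rating scale (NRS-11, 0-10), yes/no
symptom flags, and medication information.  These are the raw inputs to the
ICHD-3 rule engine.
"""

from __future__ import annotations

import enum
from datetime import datetime
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class HeadacheLabel(str, enum.Enum):
    """The four output categories of the attack classifier.

    MO: migraine without aura; MA: migraine with aura; TTH: tension-type
    headache; NOT_CLASSIFIABLE: neither migraine nor TTH criteria apply (or
    the attack was too short to classify).
    """

    MO = "MO"
    MA = "MA"
    TTH = "TTH"
    NOT_CLASSIFIABLE = "NOT_CLASSIFIABLE"


class Certainty(str, enum.Enum):
    """Diagnostic certainty attached to a label.

    DEFINITE: all of ICHD-3 criteria B-D fulfilled; PROBABLE: all but exactly
    one fulfilled; NONE: the event carries no migraine/TTH diagnosis.
    """

    DEFINITE = "DEFINITE"
    PROBABLE = "PROBABLE"
    NONE = "NONE"


class HeadacheEvent(BaseModel):
    """One diary entry describing a single headache attack.

    Timestamps are naive local clock times; duration is their difference in
    fractional hours.  ``triptan_taken_and_effective`` is three-valued:
    ``True`` (a triptan was taken and relieved the attack), ``False`` (taken
    without relief, or a non-triptan drug), or ``None`` (unknown); it may be
    present only when ``medication_taken`` is true.
    """

    model_config = ConfigDict(frozen=True)

    event_id: str
    start_time: datetime
    end_time: datetime
    pain_nrs: int = Field(ge=0, le=10)
    pulsating: bool
    pressing: bool
    one_sided: bool
    both_sided: bool
    aggravated_by_activity: bool
    aura: bool
    nausea: bool
    vomiting: bool
    photophobia: bool
    phonophobia: bool
    medication_taken: bool
    triptan_taken_and_effective: Optional[bool] = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "HeadacheEvent":
        if self.end_time < self.start_time:
            raise ValueError("end_time: must not precede start_time")
        if self.one_sided and self.both_sided:
            raise ValueError(
                "one_sided: contradicts both_sided (pain cannot be one-sided "
                "and on both sides)"
            )
        if self.pulsating and self.pressing:
            raise ValueError(
                "pulsating: contradicts pressing (pain quality cannot be both)"
            )
        if self.triptan_taken_and_effective is not None and not self.medication_taken:
            raise ValueError(
                "triptan_taken_and_effective: present but medication_taken is false"
            )
        return self

    @property
    def duration_h(self) -> float:
        """Attack duration in fractional hours (end − start)."""
        return (self.end_time - self.start_time).total_seconds() / 3600.0


class PatientHistory(BaseModel):
    """Prior-diagnosis flags standing in for ICHD-3 criterion A.

    Criterion A (minimum number of previous attacks) cannot be assessed from a
    single diary entry, so it is represented by whether the patient already
    carries a migraine and/or TTH diagnosis.  The validation setting treats
    every patient as having both, hence both default to ``True``.
    """

    model_config = ConfigDict(frozen=True)

    has_migraine_history: bool = True
    has_tth_history: bool = True
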