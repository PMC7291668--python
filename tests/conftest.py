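from datetime import datetime, timedelta

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from ichd3kit import HeadacheEvent

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=150,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASE_TIME = datetime(2017, 1, 1, 8, 0)


def make_event(
    duration_h: float = 10.0,
    pain_nrs: int = 7,
    pulsating: bool = True,
    pressing: bool = False,
    one_sided: bool = True,
    both_sided: bool = False,
    aggravated: bool = True,
    aura: bool = False,
    nausea: bool = True,
    vomiting: bool = False,
    photophobia: bool = False,
    phonophobia: bool = False,
    medication: bool = False,
    triptan: bool | None = None,
    event_id: str = "ev-test",
) -> HeadacheEvent:
    """Compact constructor: a definite migraine-without-aura by default."""
    return HeadacheEvent(
        event_id=event_id,
        start_time=BASE_TIME,
        end_time=BASE_TIME + timedelta(hours=duration_h),
        pain_nrs=pain_nrs,
        pulsating=pulsating,
        pressing=pressing,
        one_sided=one_sided,
        both_sided=both_sided,
        aggravated_by_activity=aggravated,
        aura=aura,
        nausea=nausea,
        vomiting=vomiting,
        photophobia=photophobia,
        phonophobia=phonophobia,
        medication_taken=medication,
        triptan_taken_and_effective=triptan,
    )


_EXCLUSIVE_PAIR = st.sampled_from([(True, False), (False, True), (False, False)])


@st.composite
def event_strategy(draw, min_nrs: int = 0, min_minutes: int = 1, max_minutes: int = 200 * 60):
    """Random valid diary events (invariant-respecting)."""
    pulsating, pressing = draw(_EXCLUSIVE_PAIR)
    one_sided, both_sided = draw(_EXCLUSIVE_PAIR)
    medication = draw(st.booleans())
    triptan = draw(st.sampled_from([None, True, False])) if medication else None
    return make_event(
        duration_h=draw(st.integers(min_minutes, max_minutes)) / 60.0,
        pain_nrs=draw(st.integers(min_nrs, 10)),
        pulsating=pulsating,
        pressing=pressing,
        one_sided=one_sided,
        both_sided=both_sided,
        aggravated=draw(st.booleans()),
        aura=draw(st.booleans()),
        nausea=draw(st.booleans()),
        vomiting=draw(st.booleans()),
        photophobia=draw(st.booleans()),
        phonophobia=draw(st.booleans()),
        medication=medication,
        triptan=triptan,
    )


@pytest.fixture
def definite_mo_event():
    return make_event()


@pytest.fixture
def definite_tth_event():
    return make_event(
        duration_h=6,
        pain_nrs=2,
        pulsating=False,
        pressing=True,
        one_sided=False,
        both_sided=True,
        aggravated=False,
        nausea=False,
        photophobia=True,
    )
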