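"""The ICHD-3 rule engine: intensity mapping, criteria B-D, decision cascade."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ichd3kit import (
    Certainty,
    CriteriaStatus,
    HeadacheLabel,
    PatientHistory,
    RuleConfig,
    VrsIntensity,
    classify_diary,
    classify_event,
    evaluate_migraine,
    evaluate_tth,
    map_nrs_to_vrs,
    summarize_labels,
)

from ._oracle import oracle_label
from .conftest import event_strategy, make_event


class TestNrsToVrs:
    @pytest.mark.parametrize(
        "nrs,expected",
        [
            (0, VrsIntensity.NONE),
            (1, VrsIntensity.MILD),
            (3, VrsIntensity.MILD),
            (4, VrsIntensity.MODERATE),
            (6, VrsIntensity.MODERATE),
            (7, VrsIntensity.SEVERE),
            (10, VrsIntensity.SEVERE),
        ],
    )
    def test_band_mapping(self, nrs, expected):
        assert map_nrs_to_vrs(nrs) is expected

    @pytest.mark.parametrize("bad", [-1, 11])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            map_nrs_to_vrs(bad)

    def test_monotone_nondecreasing(self):
        values = [map_nrs_to_vrs(n) for n in range(11)]
        assert values == sorted(values)


class TestMigraineCriteria:
    def test_full_house_is_definite(self, definite_mo_event):
        ev = evaluate_migraine(definite_mo_event)
        assert ev.b_met and ev.c_count == 4 and ev.d_met
        assert ev.status is CriteriaStatus.DEFINITE

    def test_failed_d_is_probable(self):
        event = make_event(nausea=False, photophobia=True, phonophobia=False)
        ev = evaluate_migraine(event)
        assert ev.c_count == 4 and not ev.d_met
        assert ev.status is CriteriaStatus.PROBABLE

    def test_nothing_fulfilled_is_not_met(self):
        event = make_event(
            duration_h=1, pain_nrs=0, pulsating=False, one_sided=False,
            aggravated=False, nausea=False,
        )
        ev = evaluate_migraine(event)
        assert not ev.b_met and ev.c_count == 0 and not ev.d_met
        assert ev.status is CriteriaStatus.NOT_MET

    def test_triptan_waives_duration_criterion(self):
        event = make_event(duration_h=1, medication=True, triptan=True)
        assert evaluate_migraine(event).b_met
        untreated = make_event(duration_h=1)
        assert not evaluate_migraine(untreated).b_met


class TestTthCriteria:
    def test_typical_tth_is_definite(self, definite_tth_event):
        ev = evaluate_tth(definite_tth_event)
        assert ev.status is CriteriaStatus.DEFINITE

    def test_zero_c_items_is_still_probable(self):
        # a migraine-shaped attack misses only TTH criterion C, even at count 0
        event = make_event(duration_h=6, nausea=False)
        ev = evaluate_tth(event)
        assert ev.c_count == 0 and ev.b_met and ev.d_met
        assert ev.status is CriteriaStatus.PROBABLE

    def test_associated_symptoms_fail_d(self, definite_tth_event):
        event = definite_tth_event.model_copy(update={"nausea": True})
        ev = evaluate_tth(event)
        assert not ev.d_met and ev.status is CriteriaStatus.PROBABLE


class TestCascade:
    def test_definite_mo(self, definite_mo_event):
        res = classify_event(definite_mo_event)
        assert res.label is HeadacheLabel.MO
        assert res.certainty is Certainty.DEFINITE
        assert not (res.probable_based or res.triptan_based or res.short_duration_flag)

    def test_definite_ma_with_aura(self):
        event = make_event(
            duration_h=8, aura=True, pain_nrs=6, nausea=False,
            photophobia=True, phonophobia=True,
        )
        res = classify_event(event)
        assert res.label is HeadacheLabel.MA and res.certainty is Certainty.DEFINITE

    def test_short_attack_set_aside(self):
        res = classify_event(make_event(duration_h=20 / 60))
        assert res.label is HeadacheLabel.NOT_CLASSIFIABLE
        assert res.short_duration_flag and res.certainty is Certainty.NONE

    def test_probable_migraine_beats_probable_tth_with_history(self):
        # migraine probable (D fails), TTH probable (C fails): migraine wins
        event = make_event(nausea=False, photophobia=True)
        res = classify_event(event, PatientHistory())
        assert res.label is HeadacheLabel.MO
        assert res.certainty is Certainty.PROBABLE and res.probable_based

    def test_triptan_rule_fires_before_short_duration(self):
        event = make_event(duration_h=1, nausea=False, pain_nrs=2,
                           medication=True, triptan=True)
        res = classify_event(event)
        assert res.label is HeadacheLabel.MO and res.triptan_based
        short = make_event(duration_h=0.25, medication=True, triptan=True)
        assert classify_event(short).label is HeadacheLabel.MO

    def test_definite_tth_trumps_probable_migraine(self):
        # duration outside the migraine window but strong TTH: definite TTH
        event = make_event(
            duration_h=100, pain_nrs=2, pulsating=False, pressing=True,
            one_sided=False, both_sided=True, aggravated=False, nausea=False,
        )
        res = classify_event(event)
        assert res.label is HeadacheLabel.TTH
        assert res.certainty is Certainty.DEFINITE

    def test_probable_migraine_without_history_not_classifiable(self):
        event = make_event(nausea=False, photophobia=True, pain_nrs=8)
        history = PatientHistory(has_migraine_history=False, has_tth_history=False)
        res = classify_event(event, history)
        assert res.label is HeadacheLabel.NOT_CLASSIFIABLE

    def test_probable_tie_with_only_tth_history_goes_to_tth(self):
        event = make_event(nausea=False, photophobia=True)
        history = PatientHistory(has_migraine_history=False, has_tth_history=True)
        res = classify_event(event, history)
        assert res.label is HeadacheLabel.TTH and res.probable_based


class TestClassifyDiary:
    def test_empty_diary(self):
        assert classify_diary([]) == []

    def test_elementwise_and_order_preserving(self, definite_mo_event):
        results = classify_diary([definite_mo_event] * 3)
        assert [r.label for r in results] == [HeadacheLabel.MO] * 3
        assert summarize_labels(results) == {
            "MO": 3, "MA": 0, "TTH": 0, "NOT_CLASSIFIABLE": 0,
        }

    def test_mixed_diary_matches_per_event_labels(self):
        events = [
            make_event(),
            make_event(duration_h=20 / 60),
            make_event(nausea=False, photophobia=True),
            make_event(duration_h=1, medication=True, triptan=True),
            make_event(duration_h=8, aura=True, pain_nrs=6, nausea=False,
                       photophobia=True, phonophobia=True),
        ]
        labels = [r.label for r in classify_diary(events)]
        assert labels == [
            HeadacheLabel.MO,
            HeadacheLabel.NOT_CLASSIFIABLE,
            HeadacheLabel.MO,
            HeadacheLabel.MO,
            HeadacheLabel.MA,
        ]


class TestEngineProperties:
    @given(event_strategy())
    def test_definite_migraine_and_tth_mutually_exclusive(self, event):
        # their D criteria are logical complements
        assert not (
            evaluate_migraine(event).status is CriteriaStatus.DEFINITE
            and evaluate_tth(event).status is CriteriaStatus.DEFINITE
        )

    @given(event_strategy())
    def test_classification_deterministic(self, event):
        assert classify_event(event) == classify_event(event)

    @given(event_strategy(min_nrs=1), st.integers(0, 9))
    def test_intensity_monotonicity(self, event, bump):
        # over the observed pain range 1-10: more pain never loses a migraine
        # C item and never gains a TTH C item
        raised = event.model_copy(update={"pain_nrs": min(10, event.pain_nrs + bump)})
        assert evaluate_migraine(raised).c_count >= evaluate_migraine(event).c_count
        assert evaluate_tth(raised).c_count <= evaluate_tth(event).c_count

    @given(event_strategy(min_nrs=0), st.integers(0, 10))
    def test_migraine_intensity_monotone_over_full_scale(self, event, bump):
        raised = event.model_copy(update={"pain_nrs": min(10, event.pain_nrs + bump)})
        assert evaluate_migraine(raised).c_count >= evaluate_migraine(event).c_count

    @given(event_strategy(max_minutes=29))
    def test_short_duration_totality(self, event):
        if event.triptan_taken_and_effective is True:
            return  # triptan rule precedes the short-duration rule
        res = classify_event(event)
        assert res.label is HeadacheLabel.NOT_CLASSIFIABLE and res.short_duration_flag

    @given(event_strategy())
    def test_probable_iff_exactly_one_criterion_false(self, event):
        for ev in (evaluate_migraine(event), evaluate_tth(event)):
            n_false = (not ev.b_met) + (not ev.c_met) + (not ev.d_met)
            assert (ev.status is CriteriaStatus.PROBABLE) == (n_false == 1)
            assert (ev.status is CriteriaStatus.DEFINITE) == (n_false == 0)

    @given(event_strategy())
    def test_agrees_with_independent_oracle(self, event):
        expected = oracle_label(
            event.duration_h, event.pain_nrs, event.pulsating, event.pressing,
            event.one_sided, event.both_sided, event.aggravated_by_activity,
            event.aura, event.nausea, event.vomiting, event.photophobia,
            event.phonophobia, event.triptan_taken_and_effective,
        )
        assert classify_event(event).label.value == expected


class TestRuleConfig:
    def test_yaml_round_trip(self, tmp_path):
        config = RuleConfig(short_duration_h=0.25, tth_duration_h=(0.25, 168.0))
        path = tmp_path / "rules.yaml"
        config.to_yaml(path)
        assert RuleConfig.from_yaml(path) == config

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(migraine_duration_h=(72.0, 4.0)),
            dict(short_duration_h=1.0),  # exceeds TTH lower bound
            dict(nrs_breaks=(3, 3, 6)),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RuleConfig(**kwargs)

    def test_custom_short_duration_threshold(self):
        config = RuleConfig(short_duration_h=0.2, tth_duration_h=(0.2, 168.0))
        event = make_event(duration_h=0.3)
        assert classify_event(event, config=config).label is not HeadacheLabel.NOT_CLASSIFIABLE
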