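import itertools

import pytest
from hypothesis import given, strategies as st

from lipidcea.pathway import (
    EZETIMIBE,
    GP_VISIT,
    INCLISIRAN,
    LDL,
    LIPID_TEST,
    NON_HDL,
    OUTPATIENT_VISIT,
    PCSK9,
    STATIN,
    EscalationPolicy,
    TreatmentState,
    apply_adherence,
    default_therapies,
    effective_ldl,
    escalate,
    monitoring_schedule,
)
from lipidcea.states import ConfigurationError


@pytest.fixture(scope="module")
def catalogue():
    return default_therapies(
        inclisiran_annual_cost=1000.0,
        pcsk9_annual_cost=1200.0,
        ezetimibe_annual_cost=19.0,
        statin_annual_cost=18.0,
    )


class TestEffectiveLdl:
    def test_statin_background_is_the_reference(self, catalogue):
        assert effective_ldl(2.5, [catalogue[STATIN]]) == 2.5

    def test_ezetimibe_point_effect(self, catalogue):
        assert effective_ldl(2.5, [catalogue[EZETIMIBE]]) == pytest.approx(2.055)

    def test_double_escalation_composition(self, catalogue):
        level = effective_ldl(2.5, [catalogue[EZETIMIBE], catalogue[INCLISIRAN]])
        assert level == pytest.approx(2.5 * 0.822 * 0.487, abs=1e-9)
        assert level == pytest.approx(1.001, abs=1e-3)

    def test_order_independent(self, catalogue):
        drugs = [catalogue[EZETIMIBE], catalogue[INCLISIRAN], catalogue[PCSK9]]
        values = {
            round(effective_ldl(3.0, perm), 12) for perm in itertools.permutations(drugs)
        }
        assert len(values) == 1

    def test_nonhdl_uses_its_own_effects(self, catalogue):
        assert effective_ldl(3.0, [catalogue[EZETIMIBE]], NON_HDL) == pytest.approx(3.0 * 0.8)

    def test_unknown_measure_rejected(self, catalogue):
        with pytest.raises(ConfigurationError):
            effective_ldl(2.0, [catalogue[EZETIMIBE]], "HDL")


class TestEscalate:
    def policy(self, threshold, **kw):
        return EscalationPolicy(threshold=threshold, sequence=(EZETIMIBE, INCLISIRAN), **kw)

    def test_below_threshold_no_change(self, catalogue):
        state = TreatmentState(active=frozenset({STATIN}))
        new, events = escalate(state, 1.9, self.policy(2.0), catalogue, cycle=0)
        assert new == state
        assert events == []

    def test_double_escalation_when_first_line_insufficient(self, catalogue):
        state = TreatmentState(active=frozenset({STATIN}))
        new, events = escalate(state, 2.5, self.policy(2.0), catalogue, cycle=0)
        # Ezetimibe alone gives 2.055 (> 2.0), so inclisiran is added too.
        assert new.active == frozenset({STATIN, EZETIMIBE, INCLISIRAN})
        assert new.last_initiations == (EZETIMIBE, INCLISIRAN)
        assert events == [(GP_VISIT, EZETIMIBE), (GP_VISIT, INCLISIRAN)]

    def test_cheaper_drug_preferred_when_it_suffices(self, catalogue):
        state = TreatmentState(active=frozenset({STATIN}))
        new, events = escalate(state, 2.6, self.policy(2.5), catalogue, cycle=0)
        # Ezetimibe brings 2.6 to 2.137, just below 2.5: stop there.
        assert new.active == frozenset({STATIN, EZETIMIBE})
        assert events == [(GP_VISIT, EZETIMIBE)]

    def test_single_escalation_mode(self, catalogue):
        state = TreatmentState(active=frozenset({STATIN}))
        new, _ = escalate(
            state, 2.5, self.policy(2.0, allow_double_escalation=False), catalogue, 0
        )
        assert new.active == frozenset({STATIN, EZETIMIBE})

    def test_exhausted_sequence_is_not_an_error(self, catalogue):
        state = TreatmentState(
            initiated=frozenset({EZETIMIBE, INCLISIRAN}),
            active=frozenset({STATIN, EZETIMIBE, INCLISIRAN}),
        )
        new, events = escalate(state, 3.0, self.policy(2.0), catalogue, cycle=4)
        assert new == state and events == []

    def test_pcsk9_absolute_trigger(self, catalogue):
        import dataclasses

        cat = dict(catalogue)
        cat[PCSK9] = dataclasses.replace(cat[PCSK9], trigger_threshold=3.5, line=3)
        policy = EscalationPolicy(threshold=2.0, sequence=(EZETIMIBE, INCLISIRAN, PCSK9))
        state = TreatmentState(
            initiated=frozenset({EZETIMIBE, INCLISIRAN}),
            active=frozenset({STATIN, EZETIMIBE, INCLISIRAN}),
        )
        # Above the escalation threshold but below the PCSK9 trigger: no change.
        new, _ = escalate(state, 2.6, policy, cat, cycle=1)
        assert new == state
        # Above the 3.5 mmol/L trigger: PCSK9 added with an outpatient visit.
        new, events = escalate(state, 3.8, policy, cat, cycle=1)
        assert PCSK9 in new.active
        assert events == [(OUTPATIENT_VISIT, PCSK9)]


class TestAdherence:
    def test_full_adherence_single_branch(self, catalogue):
        assert apply_adherence(catalogue[EZETIMIBE], 1.0) == [(1.0, True)]

    def test_partial_split(self, catalogue):
        branches = apply_adherence(catalogue[EZETIMIBE], 0.8)
        assert branches == [(pytest.approx(0.8), True), (pytest.approx(0.2), False)]

    def test_zero_adherence(self, catalogue):
        assert apply_adherence(catalogue[EZETIMIBE], 0.0) == [(1.0, False)]

    @given(a=st.floats(0, 1))
    def test_branches_partition_the_cohort(self, catalogue, a):
        branches = apply_adherence(catalogue[EZETIMIBE], a)
        assert sum(f for f, _ in branches) == pytest.approx(1.0)


class TestMonitoring:
    def test_routine_cycle_has_one_lipid_test(self, catalogue):
        state = TreatmentState(active=frozenset({STATIN}))
        assert monitoring_schedule(state, 3, catalogue) == [(LIPID_TEST, 1)]

    def test_initiation_cycle_adds_retest_and_visit(self, catalogue):
        state = TreatmentState(
            initiated=frozenset({EZETIMIBE}),
            active=frozenset({STATIN, EZETIMIBE}),
            cycle_of_last_initiation=2,
            last_initiations=(EZETIMIBE,),
        )
        events = monitoring_schedule(state, 2, catalogue)
        assert events == [(LIPID_TEST, 1), (LIPID_TEST, 1), (GP_VISIT, 1)]
        # The extra test applies only in the initiation cycle itself.
        assert monitoring_schedule(state, 3, catalogue) == [(LIPID_TEST, 1)]

    def test_pcsk9_initiation_uses_outpatient_visit(self, catalogue):
        state = TreatmentState(
            initiated=frozenset({PCSK9}),
            active=frozenset({STATIN, PCSK9}),
            cycle_of_last_initiation=0,
            last_initiations=(PCSK9,),
        )
        events = monitoring_schedule(state, 0, catalogue)
        assert (OUTPATIENT_VISIT, 1) in events
        assert sum(n for r, n in events if r == LIPID_TEST) == 2
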