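"""Treatment controllers: measurement, classification, the six decision rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptherapy import (
    ControllerState,
    DoseDecision,
    Protocol,
    ProtocolConfig,
    Response,
    apply_vacation_and_clamp,
    classify_response,
    controller_update,
    measure_burden,
)
from adaptherapy.protocols import (
    decide_dm_cocktail,
    decide_dm_pingpong_alternate,
    decide_dm_pingpong_progression,
    decide_fd_doseskip,
    decide_fd_intermittent,
    decide_st,
)


def started_state(protocol, initiation=5000.0, rng=None):
    """A state just after treatment initiation at the given measured burden."""
    cfg = ProtocolConfig(protocol=protocol, measurement_noise_sd=0.0)
    state = ControllerState()
    decision, state = controller_update(state, initiation, cfg, rng or np.random.default_rng(0))
    return cfg, state, decision


class TestMeasureBurden:
    def test_zero_sd_identity(self, rng):
        assert measure_burden(4321, 0.0, rng) == 4321

    def test_clamped_at_zero(self, rng):
        assert all(measure_burden(0, 5.0, rng) >= 0 for _ in range(2000))

    def test_unbiased(self, rng):
        draws = [measure_burden(5000, 5.0, rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(5000, abs=0.1)

    def test_negative_count_rejected(self, rng):
        with pytest.raises(ValueError):
            measure_burden(-1, 5.0, rng)


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "prev, cur, expected",
        [
            (5000, 5600, Response.GREW),  # +12% > 10%
            (5000, 4500, Response.SHRANK),  # -10% meets "by at least"
            (5000, 5200, Response.STABLE),
            (5000, 5500, Response.STABLE),  # +10% does not exceed the threshold
        ],
    )
    def test_examples(self, prev, cur, expected):
        assert classify_response(prev, cur, 0.10) is expected

    def test_zero_previous_rejected(self):
        with pytest.raises(ValueError):
            classify_response(0, 100, 0.10)


class TestStandardTreatment:
    def test_full_mtd_cocktail_forever(self):
        cfg, state, decision = started_state(Protocol.ST)
        assert decision == DoseDecision(3.0, 3.0)
        rng = np.random.default_rng(1)
        # dosing continues at MTD whatever the burden does afterwards
        for burden in [9000, 200, 9900, 50]:
            decision, state = controller_update(state, burden, cfg, rng)
            assert decision == DoseDecision(3.0, 3.0)

    def test_no_dose_before_initiation(self):
        cfg = ProtocolConfig(protocol=Protocol.ST, measurement_noise_sd=0.0)
        state = ControllerState()
        decision, state = controller_update(state, 4990, cfg, np.random.default_rng(0))
        assert decision == DoseDecision(0.0, 0.0)
        assert not state.treatment_started
        assert decide_st(state, cfg) == DoseDecision(0.0, 0.0)


class TestDMCocktail:
    def test_growth_scales_both_doses_up(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        state.last_dose = [1.0, 1.0]
        decision, state = decide_dm_cocktail(state, 5600 + 5000, cfg)  # above max -> grew anyway
        state.last_dose = [1.0, 1.0]
        state.last_measured = 5000
        decision, _ = decide_dm_cocktail(state, 5600, cfg)
        assert decision == DoseDecision(1.5, 1.5)

    def test_shrinkage_scales_down_to_min_dose_floor(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        state.last_measured = 5000
        state.last_dose = [1.0, 1.0]
        decision, _ = decide_dm_cocktail(state, 4500, cfg)
        assert decision == DoseDecision(0.5, 0.5)

    def test_min_dose_floor_not_crossed(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        state.last_measured = 5000
        state.last_dose = [0.8, 0.8]
        decision, _ = decide_dm_cocktail(state, 4400, cfg)
        assert decision == DoseDecision(0.5, 0.5)  # not 0.4

    def test_stable_keeps_dose(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        state.last_measured = 5000
        state.last_dose = [1.5, 1.5]
        decision, _ = decide_dm_cocktail(state, 5100, cfg)
        assert decision == DoseDecision(1.5, 1.5)

    def test_max_burden_override_optional(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        cfg_ov = ProtocolConfig(
            protocol=Protocol.DM_COCKTAIL, measurement_noise_sd=0.0, max_burden_override=True
        )
        state.last_measured = 6000
        state.max_burden = 6000
        state.last_dose = [1.0, 1.0]
        # +3% growth above the running max: STABLE without the override
        decision, _ = decide_dm_cocktail(state, 6180, cfg)
        assert decision == DoseDecision(1.0, 1.0)
        state.last_measured = 6000
        state.last_dose = [1.0, 1.0]
        decision, _ = decide_dm_cocktail(state, 6180, cfg_ov)
        assert decision == DoseDecision(1.5, 1.5)

    def test_vacation_zeroes_administration_but_memory_updates(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        state.last_measured = 5000
        state.last_dose = [2.0, 2.0]
        decision, state = decide_dm_cocktail(state, 2400, cfg)
        assert decision == DoseDecision(0.0, 0.0)
        assert state.on_vacation
        assert state.last_dose == [1.0, 1.0]  # shrank: memory halves

    def test_cocktail_doses_always_equal(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        rng = np.random.default_rng(5)
        for burden in rng.integers(100, 9000, size=40):
            decision, state = controller_update(state, int(burden), cfg, rng)
            assert decision.dose1 == decision.dose2

    def test_deterministic_shrink_reaches_min_in_closed_form_cycles(self):
        # dose halves per shrinking cycle: ceil(log(start/min)/log 2) = 3
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL, initiation=10000)
        cfg = ProtocolConfig(
            protocol=Protocol.DM_COCKTAIL,
            measurement_noise_sd=0.0,
            vacation_threshold=2500,
            initiation_threshold=5000,
        )
        expected_cycles = math.ceil(math.log(3.0 / 0.5) / math.log(1 / (1 - 0.5)))
        burden, doses = 10000, []
        rng = np.random.default_rng(0)
        while burden > 2600:
            decision, state = controller_update(state, burden, cfg, rng)
            doses.append(decision.dose1)
            burden = int(burden * 0.8)
        assert all(b >= a for a, b in zip(doses[1:], doses))  # non-increasing
        assert doses[expected_cycles] == 0.5


class TestPingPongAlternate:
    def test_alternates_starting_at_mtd(self):
        cfg, state, decision = started_state(Protocol.DM_PP_ALT)
        assert decision == DoseDecision(5.0, 0.0)  # drug 1 first, single-drug MTD
        rng = np.random.default_rng(2)
        decision, state = controller_update(state, 5100, cfg, rng)
        assert decision == DoseDecision(0.0, 5.0)  # first use of drug 2 at MTD

    def test_adjusts_against_two_cycles_ago(self):
        cfg, state, _ = started_state(Protocol.DM_PP_ALT)
        rng = np.random.default_rng(3)
        controller_update(state, 5100, cfg, rng)  # cycle 2: drug 2 at MTD
        # cycle 3: drug 1 again; tumor shrank vs its cycle-1 reference (5000)
        decision, state = controller_update(state, 4000, cfg, rng)
        assert decision == DoseDecision(2.5, 0.0)  # 5.0 * (1 - 0.5)
        # cycle 4: drug 2; grew vs its cycle-2 reference (5100)? 6000 > +10%
        decision, state = controller_update(state, 6000, cfg, rng)
        assert decision == DoseDecision(0.0, 5.0)  # 5.0 * 1.5 capped at MTD

    def test_single_drug_at_a_time(self):
        cfg, state, _ = started_state(Protocol.DM_PP_ALT)
        rng = np.random.default_rng(4)
        for burden in rng.integers(2600, 9500, size=30):
            decision, state = controller_update(state, int(burden), cfg, rng)
            assert min(decision.dose1, decision.dose2) == 0.0


class TestPingPongOnProgression:
    def test_first_cycle_drug1_at_mtd(self):
        _, _, decision = started_state(Protocol.DM_PP_PROG)
        assert decision == DoseDecision(5.0, 0.0)

    def test_shrank_stays_and_steps_down(self):
        cfg, state, _ = started_state(Protocol.DM_PP_PROG)
        state.last_measured = 5000
        state.last_dose = [2.0, None]
        decision, state = decide_dm_pingpong_progression(state, 4000, cfg)
        assert decision == DoseDecision(1.0, 0.0)
        assert state.active_drug == 1

    def test_growth_switches_to_other_drug_delta_dose_higher(self):
        cfg, state, _ = started_state(Protocol.DM_PP_PROG)
        state.last_measured = 5000
        state.last_dose = [1.0, 2.0]
        state.active_drug = 1
        decision, state = decide_dm_pingpong_progression(state, 5800, cfg)
        assert state.active_drug == 2
        assert decision == DoseDecision(0.0, 3.0)  # 2.0 * 1.5

    def test_growth_switch_first_use_at_mtd(self):
        cfg, state, _ = started_state(Protocol.DM_PP_PROG)
        state.last_measured = 5000
        decision, state = decide_dm_pingpong_progression(state, 5800, cfg)
        assert state.active_drug == 2
        assert decision == DoseDecision(0.0, 5.0)

    def test_stable_keeps_drug_and_dose(self):
        cfg, state, _ = started_state(Protocol.DM_PP_PROG)
        state.last_measured = 5000
        state.last_dose = [2.5, None]
        decision, state = decide_dm_pingpong_progression(state, 5100, cfg)
        assert decision == DoseDecision(2.5, 0.0)


class TestFDDoseSkipping:
    def test_growth_triggers_fixed_dose(self):
        cfg, state, _ = started_state(Protocol.FD_SKIP)
        state.last_measured = 5000
        state.max_burden = 6000
        decision, _ = decide_fd_doseskip(state, 5600, cfg)
        assert decision == DoseDecision(2.25, 2.25)

    def test_skip_when_stable_below_running_max(self):
        cfg, state, _ = started_state(Protocol.FD_SKIP)
        state.last_measured = 5000
        state.max_burden = 6000
        decision, _ = decide_fd_doseskip(state, 4800, cfg)
        assert decision == DoseDecision(0.0, 0.0)

    def test_running_max_overrides_stability(self):
        cfg, state, _ = started_state(Protocol.FD_SKIP)
        state.last_measured = 5000
        state.max_burden = 5100
        decision, _ = decide_fd_doseskip(state, 5200, cfg)
        assert decision == DoseDecision(2.25, 2.25)


class TestFDIntermittent:
    def test_stops_at_half_of_initiation(self):
        cfg, state, _ = started_state(Protocol.FD_INT)
        decision, state = decide_fd_intermittent(state, 2400, cfg)
        assert decision == DoseDecision(0.0, 0.0)
        assert not state.fd_dosing_on

    def test_restarts_at_initiation_burden(self):
        cfg, state, _ = started_state(Protocol.FD_INT)
        state.fd_dosing_on = False
        decision, state = decide_fd_intermittent(state, 5100, cfg)
        assert decision == DoseDecision(2.25, 2.25)
        assert state.fd_dosing_on

    def test_hysteresis_holds_between_thresholds(self):
        cfg, state, _ = started_state(Protocol.FD_INT)
        for on in (True, False):
            state.fd_dosing_on = on
            decision, state2 = decide_fd_intermittent(state, 3800, cfg)
            assert state2.fd_dosing_on == on
            assert (decision.dose1 > 0) == on

    def test_onoff_sequence_replay_deterministic(self):
        # pure hysteresis: the on/off pattern depends only on the burdens
        cfg, _, _ = started_state(Protocol.FD_INT)
        burdens = [4800, 3000, 2400, 2600, 4000, 5200, 2500, 2450, 5100]
        patterns = []
        for _ in range(2):
            _, state, _ = started_state(Protocol.FD_INT)
            pattern = []
            for b in burdens:
                decision, state = decide_fd_intermittent(state, b, cfg)
                pattern.append(decision.dose1 > 0)
            patterns.append(tuple(pattern))
        assert patterns[0] == patterns[1]
        assert patterns[0] == (True, True, False, False, False, True, False, False, True)


class TestVacationAndClamp:
    def test_vacation_at_threshold(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        out = apply_vacation_and_clamp(DoseDecision(2.0, 2.0), 2500, cfg, state)
        assert out == DoseDecision(0.0, 0.0)
        assert state.on_vacation

    def test_just_above_threshold_unchanged(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        out = apply_vacation_and_clamp(DoseDecision(2.0, 2.0), 2501, cfg, state)
        assert out == DoseDecision(2.0, 2.0)

    def test_caps_at_applicable_mtd(self):
        cfg, state, _ = started_state(Protocol.DM_COCKTAIL)
        out = apply_vacation_and_clamp(DoseDecision(4.0, 4.0), 6000, cfg, state)
        assert out == DoseDecision(3.0, 3.0)

    def test_no_vacation_for_fd(self):
        cfg, state, _ = started_state(Protocol.FD_INT)
        out = apply_vacation_and_clamp(DoseDecision(2.25, 2.25), 2000, cfg, state)
        assert out == DoseDecision(2.25, 2.25)


class TestControllerUpdate:
    def test_initiation_threshold(self):
        cfg = ProtocolConfig(protocol=Protocol.DM_COCKTAIL, measurement_noise_sd=0.0)
        state = ControllerState()
        rng = np.random.default_rng(0)
        decision, state = controller_update(state, 4990, cfg, rng)
        assert decision == DoseDecision(0.0, 0.0) and not state.treatment_started
        decision, state = controller_update(state, 5010, cfg, rng)
        assert decision == DoseDecision(3.0, 3.0) and state.treatment_started
        assert state.initiation_burden == 5010

    def test_pingpong_initiation_drug1_mtd(self):
        cfg, state, decision = started_state(Protocol.DM_PP_PROG, initiation=5010)
        assert decision == DoseDecision(5.0, 0.0)

    @pytest.mark.parametrize("protocol", list(Protocol))
    @given(data=st.data())
    @settings(max_examples=15, deadline=None)
    def test_emitted_doses_valid(self, protocol, data):
        # every dose is 0 or in [min_dose, applicable MTD]
        cfg = ProtocolConfig(protocol=protocol)
        state = ControllerState()
        rng = np.random.default_rng(7)
        burdens = data.draw(
            st.lists(st.integers(0, 10000), min_size=5, max_size=25)
        )
        for b in burdens:
            decision, state = controller_update(state, b, cfg, rng)
            for d in decision:
                assert d == 0.0 or cfg.min_dose <= d <= cfg.mtd
            if protocol.is_ping_pong:
                assert min(decision) == 0.0


class TestProtocolConfigValidation:
    def test_vacation_below_initiation(self):
        with pytest.raises(ValueError):
            ProtocolConfig(vacation_threshold=6000, initiation_threshold=5000)

    def test_dm_requires_positive_deltas(self):
        with pytest.raises(ValueError):
            ProtocolConfig(protocol=Protocol.DM_COCKTAIL, delta_tumor=0.0)

    def test_applicable_mtd(self):
        assert ProtocolConfig(protocol=Protocol.DM_PP_ALT).mtd == 5.0
        assert ProtocolConfig(protocol=Protocol.DM_COCKTAIL).mtd == 3.0
        assert ProtocolConfig(protocol=Protocol.ST).mtd == 3.0
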