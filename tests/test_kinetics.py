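"""Rate laws: elementary factors, regulation terms, and the flux engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chokinet as ck
import chokinet.canonical as C
from chokinet.kinetics import (FluxEngine, RATE_INDEX, activation_factor,
                               inhibition_factor, saturation_term,
                               threshold_activation)

pos = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)
nonneg = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestElementaryFactors:
    def test_saturation_values(self):
        assert saturation_term(1.0, 1.0) == pytest.approx(0.5)
        assert saturation_term(0.0, 1.0) == 0.0
        assert saturation_term(99.0, 1.0) == pytest.approx(0.99)

    def test_inhibition_values(self):
        assert inhibition_factor(0.0, 1.0) == 1.0
        assert inhibition_factor(1.0, 1.0) == pytest.approx(0.5)
        assert inhibition_factor(1e9, 1.0) < 1e-8

    def test_activation_values(self):
        assert activation_factor(1.0, 1.0) == pytest.approx(0.5)
        assert activation_factor(0.0, 1.0) == 0.0

    @pytest.mark.parametrize("fn", [saturation_term, inhibition_factor,
                                    activation_factor])
    def test_nonpositive_constant_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(1.0, 0.0)
        with pytest.raises(ValueError):
            fn(-1.0, 1.0)

    @settings(deadline=None, max_examples=100)
    @given(conc=nonneg, k=pos)
    def test_factor_ranges(self, conc, k):
        assert 0.0 <= saturation_term(conc, k) < 1.0
        assert 0.0 < inhibition_factor(conc, k) <= 1.0
        assert 0.0 <= activation_factor(conc, k) < 1.0

    @settings(deadline=None, max_examples=50)
    @given(e1=nonneg, e2=nonneg, k=pos)
    def test_activation_monotone(self, e1, e2, k):
        lo, hi = sorted((e1, e2))
        assert activation_factor(lo, k) <= activation_factor(hi, k)


class TestThresholdActivation:
    def test_midpoint_and_limits(self):
        thr = C.GLN_THRESHOLD_DEFAULT
        assert threshold_activation(thr, thr) == pytest.approx(0.5)
        assert threshold_activation(0.0, thr) > 0.99
        # initial medium glutamine level: gate essentially closed
        assert threshold_activation(4.0, thr) < 0.01

    @settings(deadline=None, max_examples=50)
    @given(g1=nonneg, g2=nonneg)
    def test_monotone_decreasing_in_glutamine(self, g1, g2):
        lo, hi = sorted((g1, g2))
        assert threshold_activation(lo, 0.3) >= threshold_activation(hi, 0.3)


def _hand_hk_rate(state, params, with_reg):
    """Independent element-by-element evaluation of the hexokinase rate."""
    vmax = params.vmax["HK"]
    sat = state["GLC"] / (params.affinity[("HK", "GLC")] + state["GLC"])
    r = state["ATP"] / state["ADP"]
    drive = r / (C.REF_RATIOS[("ATP", "ADP")] + r)
    reg = 1.0
    if with_reg:
        reg = 1.0 / (1.0 + state["G6P"] / params.regulatory["ki_hk_g6p"])
    return vmax * sat * drive * reg


class TestFluxEngine:
    def test_hand_computed_hk_matches(self, base_params, reference_state):
        for scenario, with_reg in (("none", False), ("I+II", True)):
            fx = ck.flux_vector(reference_state, base_params,
                                ck.RegulationConfig.from_scenario(scenario))
            expected = _hand_hk_rate(reference_state, base_params, with_reg)
            assert fx["HK"] == pytest.approx(expected, rel=1e-12)

    def test_flux_vector_matches_reaction_rate(self, base_params,
                                               reference_state):
        fx = ck.flux_vector(reference_state, base_params)
        for rid in C.REACTION_IDS:
            assert fx[rid] == pytest.approx(
                ck.reaction_rate(rid, reference_state, base_params),
                rel=1e-12, abs=1e-300)

    def test_qo2_appended(self, base_params, reference_state):
        fx = ck.flux_vector(reference_state, base_params)
        assert fx["qO2"] == pytest.approx(0.5 * (fx["resp"] + fx["leak"]))

    def test_zero_vmax_zero_fluxes(self, reference_state, base_params):
        p = base_params.copy()
        for k in p.vmax:
            p.vmax[k] = 0.0
        fx = ck.flux_vector(reference_state, p)
        assert np.allclose(fx.to_numpy(), 0.0)

    def test_saturating_substrates_approach_vmax(self, base_params):
        """With substrates far above their Km, driving ratios saturated
        and no regulation, an irreversible rate approaches its maximum."""
        sv = ck.StateVector()
        sv["GLC"] = 1e6
        sv["ATP"] = 1e6          # ATP/ADP ratio term -> 1
        sv["ADP"] = 1e-3
        v = ck.directional_rates(sv, base_params,
                                 ck.RegulationConfig.from_scenario("none"))
        assert v["HK"] == pytest.approx(base_params.vmax["HK"], rel=1e-3)

    def test_reversible_pair_symmetry(self, base_params, reference_state):
        """Equal forward and reverse rate terms cancel in the net flux."""
        p = base_params.copy()
        v = ck.directional_rates(reference_state, p,
                                 ck.RegulationConfig.from_scenario("none"))
        if v["LDH_f"] > 0:
            p.vmax["LDH_r"] = p.vmax["LDH_r"] * v["LDH_f"] / v["LDH_r"]
        fx = ck.flux_vector(reference_state, p,
                            ck.RegulationConfig.from_scenario("none"))
        assert fx["LDH"] == pytest.approx(0.0, abs=1e-18)

    def test_term_i_half_inhibition(self, base_params):
        """At G6P equal to its inhibition constant the hexokinase rate is
        exactly halved relative to the unregulated rate."""
        sv = ck.StateVector()
        sv["G6P"] = base_params.regulatory["ki_hk_g6p"]
        v_on = ck.flux_vector(sv, base_params,
                              ck.RegulationConfig.from_scenario("I"))
        v_off = ck.flux_vector(sv, base_params,
                               ck.RegulationConfig.from_scenario("none"))
        assert v_on["HK"] == pytest.approx(0.5 * v_off["HK"], rel=1e-12)

    def test_disabling_regulation_monotonicity(self, base_params,
                                               reference_state):
        """Disabling an inhibition can only increase the regulated flux;
        disabling an activation can only decrease it."""
        none = ck.directional_rates(reference_state, base_params,
                                    ck.RegulationConfig.from_scenario("none"))
        full = ck.directional_rates(reference_state, base_params,
                                    ck.RegulationConfig.from_scenario("all"))
        for rate in ("HK", "PFK", "LDH_f"):       # inhibited targets
            assert none[rate] >= full[rate]
        # activation (term IV on PK): enabling can only reduce vs none
        assert full["PK"] <= none["PK"]

    def test_all_fluxes_finite_on_random_states(self, base_params, rng):
        for _ in range(20):
            vals = rng.uniform(0, 50, size=46)
            fx = ck.flux_vector(ck.StateVector(vals), base_params)
            assert np.all(np.isfinite(fx.to_numpy()))

    def test_negative_state_rejected(self, base_params):
        sv = ck.StateVector()
        sv["GLC"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            ck.flux_vector(sv, base_params)

    def test_unknown_reaction_rejected(self, base_params, reference_state):
        with pytest.raises(ck.network.NetworkError):
            ck.reaction_rate("NOPE", reference_state, base_params)


class TestRegulationConfig:
    def test_scenarios(self):
        assert ck.RegulationConfig.from_scenario("none").enabled == frozenset()
        assert ck.RegulationConfig.from_scenario("I").enabled == {"I"}
        assert ck.RegulationConfig.from_scenario("I+II").enabled == {"I", "II"}
        assert ck.RegulationConfig.from_scenario("all").enabled == \
            {"I", "II", "III", "IV", "V"}

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            ck.RegulationConfig.from_scenario("II+III")

    def test_overrides(self):
        cfg = ck.RegulationConfig(scenario="none", overrides=(("V", True),))
        assert cfg.enabled == {"V"}
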