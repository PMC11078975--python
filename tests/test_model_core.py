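"""Structural-model primitives: gates, maturation, allometry, transit chain,
milk volume, and the ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lactokin.model_core import (FeedingPattern, IndividualParams, ModelLayout,
                                 ParameterSet, allometric_scale, build_matrix,
                                 maturation_fraction, milk_compartment_volume,
                                 mother_infant_rhs, square_wave_pair,
                                 square_wave_pair_sine, transit_rate)


class TestSquareWave:
    def test_feeding_window_on_break_off(self, feeding):
        # 10 feeds/day: 24-min window then a 2-h break
        assert square_wave_pair(0.1, feeding) == (1.0, 0.0)
        assert square_wave_pair(1.0, feeding) == (0.0, 1.0)

    def test_duty_cycle_is_window_over_cycle(self, feeding):
        t = np.linspace(0.0, feeding.t_cycle, 100001)[:-1]
        g_mi, _ = square_wave_pair(t, feeding)
        assert g_mi.mean() == pytest.approx(feeding.window_h / feeding.t_cycle,
                                            rel=1e-3)
        assert g_mi.mean() == pytest.approx(1.0 / 6.0, rel=1e-3)

    @given(t=st.floats(0.0, 200.0), feeds=st.integers(4, 20),
           window=st.floats(0.1, 0.5), offset=st.floats(0.0, 2.0))
    def test_complementarity_and_sine_agreement(self, t, feeds, window, offset):
        fp = FeedingPattern(feeds_per_day=float(feeds), window_h=window,
                            first_feed_offset_h=offset)
        # keep clear of the switching instants, where constructions may differ
        phase = (t - offset) % fp.t_cycle
        if min(abs(phase), abs(phase - window), abs(phase - fp.t_cycle)) < 1e-6:
            return
        g_mi, g_vm = square_wave_pair(t, fp)
        assert g_mi + g_vm == 1.0
        assert square_wave_pair_sine(t, fp) == (g_mi, g_vm)

    def test_invalid_patterns_rejected(self):
        with pytest.raises(ValueError):
            FeedingPattern(feeds_per_day=0.0)
        with pytest.raises(ValueError):
            FeedingPattern(feeds_per_day=10.0, window_h=2.5)  # >= cycle
        with pytest.raises(ValueError):
            square_wave_pair(-1.0, FeedingPattern())


class TestMaturation:
    def test_full_term_birth_is_55_percent(self):
        assert maturation_fraction(9.2, 7.6) == pytest.approx(0.5476, abs=5e-4)
        assert round(100 * maturation_fraction(9.2, 7.6)) == 55

    def test_half_maturation_at_tm50(self):
        assert maturation_fraction(7.6, 7.6) == 0.5

    def test_asymptote(self):
        assert maturation_fraction(1e9, 7.6) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("pma,tm50", [(0.0, 7.6), (-1.0, 7.6), (9.2, 0.0)])
    def test_nonpositive_inputs_rejected(self, pma, tm50):
        with pytest.raises(ValueError):
            maturation_fraction(pma, tm50)


class TestAllometryAndTransit:
    @pytest.mark.parametrize("value,w,ref,exp,expected", [
        (17.1, 60.0, 51.0, 0.75, 17.1 * (60.0 / 51.0) ** 0.75),
        (17.1, 51.0, 51.0, 0.75, 17.1),
        (131.0, 25.5, 51.0, 1.0, 65.5),
    ])
    def test_power_law(self, value, w, ref, exp, expected):
        assert allometric_scale(value, w, ref, exp) == pytest.approx(expected)
        assert allometric_scale(17.1, 60.0, 51.0, 0.75) == pytest.approx(19.31,
                                                                         abs=0.01)

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            allometric_scale(17.1, -1.0, 51.0, 0.75)

    @pytest.mark.parametrize("mtt,n,expected", [
        (1.44, 4, 5 / 1.44),
        (2.0, 0, 0.5),
        (0.706, 2, 3 / 0.706),
    ])
    def test_transit_rate(self, mtt, n, expected):
        assert transit_rate(mtt, n) == pytest.approx(expected)
        assert transit_rate(1.44, 4) == pytest.approx(3.472, abs=1e-3)

    def test_transit_rate_errors(self):
        with pytest.raises(ValueError):
            transit_rate(0.0, 4)
        with pytest.raises(ValueError):
            transit_rate(1.0, -1)


class TestMilkVolume:
    @pytest.mark.parametrize("w,feeds,expected", [
        (4.13, 10, 0.062), (10.8, 10, 0.162), (10.0, 15, 0.100),
    ])
    def test_volume_of_one_feed(self, w, feeds, expected):
        assert milk_compartment_volume(w, feeds) == pytest.approx(expected,
                                                                  abs=5e-4)

    def test_zero_feeds_rejected(self):
        with pytest.raises(ValueError):
            milk_compartment_volume(6.8, 0)


class TestParameterSet:
    def test_defaults_valid_and_roundtrip(self, params):
        d = params.to_dict()
        assert ParameterSet.from_dict(d).to_dict() == d

    def test_unknown_keys_rejected(self, params):
        d = params.to_dict()
        d["CL_UNKNOWN"] = 1.0
        with pytest.raises(ValueError, match="unknown"):
            ParameterSet.from_dict(d)

    @pytest.mark.parametrize("kw", [
        {"CL_PQ": -1.0}, {"FM": 1.5}, {"PC_PQ": -0.1}, {"n_transit": 2.5},
        {"MTT": 0.0},
    ])
    def test_invariants_enforced(self, kw):
        with pytest.raises(ValueError):
            ParameterSet(**kw)


def _typical_ip(params):
    return IndividualParams(
        f=1.0, mtt=params.MTT, fm=params.FM, cl_pq=params.CL_PQ,
        v_pq=params.V_PQ, cl_cpq=params.CL_CPQ, v_cpq=params.V_CPQ,
        cf_pq=params.CF_PQ, cf_cpq=params.CF_CPQ, q=params.Q,
        pc_pq=params.PC_PQ, pc_cpq=params.PC_CPQ, n_transit=params.n_transit)


class TestRhs:
    def test_zero_state_zero_derivative(self, params, feeding):
        layout = ModelLayout(infant=True)
        y = np.zeros(layout.n_states)
        dy = mother_infant_rhs(1.0, y, layout, _typical_ip(params), 0.1,
                               feeding, None)
        assert np.all(dy == 0.0)

    def test_mass_conservation_of_fluxes(self, params, feeding, rng):
        # compartment derivatives plus the sink sum to zero at any state,
        # in both gate phases of the coupled mother-infant system
        from lactokin.model_core import InfantParams
        layout = ModelLayout(infant=True)
        ip = _typical_ip(params)
        infp = InfantParams(cl_pq=1.0, v_pq=17.0, cl_cpq=0.2, v_cpq=3.0)
        for t in (0.05, 1.0, 2.5):   # 0.05 in-window, others in the break
            y = np.zeros(layout.n_states)
            y[layout.mass_indices()] = rng.uniform(0, 10, len(layout.mass_indices()))
            dy = mother_infant_rhs(t, y, layout, ip, 0.1, feeding, infp,
                                   mtinf=params.MTINF)
            assert np.sum(dy[layout.mass_indices()]) == pytest.approx(
                0.0, abs=1e-9 * np.abs(dy).max())

    def test_q_zero_leaves_only_feed_outflow(self, params, feeding):
        import dataclasses
        layout = ModelLayout(infant=False)
        ip = dataclasses.replace(_typical_ip(params), q=0.0)
        y = np.zeros(layout.n_states)
        y[layout.pq_m] = 5.0
        t_feed = 0.1   # inside the feeding window
        dy = mother_infant_rhs(t_feed, y, layout, ip, 0.1, feeding,
                               mtinf=params.MTINF)
        assert dy[layout.pq_m] == pytest.approx(-params.MTINF * 5.0)
        assert dy[layout.pq_c] == 0.0

    def test_nonfinite_state_flagged(self, params, feeding):
        layout = ModelLayout(infant=False)
        y = np.zeros(layout.n_states)
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            mother_infant_rhs(0.0, y, layout, _typical_ip(params), 0.1, feeding)
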