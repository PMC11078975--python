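"""Maternal simulation layer: individual parameters, concentration series,
AUC integrators, and secondary PK metrics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lactokin.infant import scale_infant_params, simulate_pair
from lactokin.model_core import (DosingRegimen, FeedingPattern,
                                 mother_infant_rhs)
from lactokin.mother import (ConcentrationSeries, MotherSubject,
                             capillary_from_venous, individual_params,
                             secondary_pk, simulate_mother)


class TestIndividualParams:
    def test_typical_subject_is_population(self, params, typical_mother):
        ip = individual_params(params, typical_mother, 0)
        assert ip.cl_pq == params.CL_PQ
        assert ip.v_pq == params.V_PQ
        assert ip.fm == params.FM

    def test_exponential_iiv(self, params):
        s = MotherSubject(weight=51.0, eta={"CL_PQ": np.log(2.0)})
        assert individual_params(params, s, 0).cl_pq == pytest.approx(
            2 * params.CL_PQ)

    def test_iov_applies_per_occasion(self, params):
        s = MotherSubject(weight=51.0,
                          kappa={"MTT": np.array([0.0, np.log(2), 0.0, 0.0])})
        assert individual_params(params, s, 0).mtt == params.MTT
        assert individual_params(params, s, 1).mtt == pytest.approx(2 * params.MTT)

    def test_unknown_occasion(self, params, typical_mother):
        with pytest.raises(ValueError):
            individual_params(params, typical_mother, 7)

    def test_median_over_draws_is_typical(self, params, rng):
        # lognormal random effects: the population median equals the typical value
        draws = [individual_params(
            params, MotherSubject(weight=51.0, eta={
                "CL_PQ": rng.normal(0, np.sqrt(params.omega["CL_PQ"]))}), 0).cl_pq
            for _ in range(4000)]
        assert np.median(draws) == pytest.approx(params.CL_PQ, rel=0.02)


class TestCapillaryConversion:
    @pytest.mark.parametrize("cf,expected", [(0.898, 89.8), (1.0, 100.0),
                                             (1.06, 106.0)])
    def test_proportional(self, cf, expected):
        assert capillary_from_venous(100.0, cf) == pytest.approx(expected)

    def test_invalid_cf(self):
        with pytest.raises(ValueError):
            capillary_from_venous(100.0, 0.0)

    def test_series_is_exact_multiple(self, params, typical_mother, standard):
        res = simulate_mother(typical_mother, params, standard,
                              t_out=np.arange(0.0, 48.1, 0.5))
        for analyte, cf in (("PQ", params.CF_PQ), ("CPQ", params.CF_CPQ)):
            ven = res.concentrations(analyte, "venous")
            cap = res.concentrations(analyte, "capillary")
            np.testing.assert_allclose(cap, cf * ven, rtol=1e-12)


class TestSimulateMother:
    def test_single_dose_auc_matches_closed_form(self, params):
        # superposition oracle: AUCinf = F (1-FM) Dose / CL at the reference weight
        p = params.replace(ref_weight=60.0)
        subj = MotherSubject(weight=60.0)
        reg = DosingRegimen(0.25, 24.0, 1, "sld")
        res = simulate_mother(subj, p, reg, t_out=np.array([0.0, 120.0]))
        expected = (1 - p.FM) * 15.0e6 / (p.CL_PQ * 1000.0)  # ng·h/mL
        assert expected == pytest.approx(630.0, rel=1e-2)
        assert res.auc("PQ", "venous") == pytest.approx(expected, rel=1e-3)

    def test_milk_to_plasma_ratio_last_interval(self, params, typical_mother,
                                                standard):
        res = simulate_mother(typical_mother, params, standard,
                              t_out=np.array([0.0, 312.0, 336.0]))
        ratio = (res.auc("PQ", "milk", (312.0, 336.0))
                 / res.auc("PQ", "venous", (312.0, 336.0)))
        assert ratio == pytest.approx(params.PC_PQ, abs=1e-4)

    def test_dose_linearity(self, params, typical_mother):
        t = np.arange(0.0, 48.1, 0.5)
        lo = simulate_mother(typical_mother, params,
                             DosingRegimen(0.5, 24.0, 2), t_out=t)
        hi = simulate_mother(typical_mother, params,
                             DosingRegimen(1.0, 24.0, 2), t_out=t)
        np.testing.assert_allclose(hi.concentrations("PQ", "venous"),
                                   2 * lo.concentrations("PQ", "venous"),
                                   rtol=1e-10)

    def test_integrator_auc_matches_trapezoid(self, params, typical_mother,
                                              standard):
        t = np.round(np.arange(312.0, 336.001, 0.01), 8)
        res = simulate_mother(typical_mother, params, standard,
                              t_out=np.concatenate([[0.0], t]))
        ven = res.concentrations("PQ", "venous")[1:]
        trap = np.trapezoid(ven, t)
        assert res.auc("PQ", "venous", (312.0, 336.0)) == pytest.approx(
            trap, rel=5e-3)

    def test_mass_balance_through_full_regimen(self, params, typical_mother,
                                               standard):
        t = np.round(np.arange(1.0, 337.0, 7.0), 8)   # clear of dose times
        res = simulate_mother(typical_mother, params, standard, t_out=t)
        amt = 0.5 * 51.0 / params.mw_PQ * 1000.0
        dosed = amt * np.minimum(np.floor(t / 24.0) + 1, 14)
        total = res.total_in_system()
        assert np.max(np.abs(total - dosed) / dosed) < 1e-6

    def test_invalid_regimen_rejected(self):
        with pytest.raises(ValueError):
            DosingRegimen(0.0, 24.0, 14)


class TestAgainstOdeSolver:
    def test_matrix_exponential_matches_lsoda(self, params, typical_mother,
                                              typical_infant, feeding):
        """The exact piecewise propagation agrees with adaptive integration of
        the gated mother-infant system."""
        reg = DosingRegimen(0.5, 24.0, 2, "short")
        t_out = np.round(np.arange(0.0, 48.01, 0.5), 10)
        res = simulate_pair(typical_mother, typical_infant, params, reg,
                            feeding, t_out)
        ip = individual_params(params, typical_mother, 0)
        infp = scale_infant_params(ip, typical_infant, params,
                                   typical_mother.weight)
        L = res.layout
        v_milk = 0.15 * typical_infant.weight / feeding.feeds_per_day
        amt = ip.f * 0.5 * 51.0 / params.mw_PQ * 1000.0
        y = np.zeros(L.n_states)
        y[L.chain[0]] = amt
        traj = {}
        for a, b in ((0.0, 24.0), (24.0, 48.0)):
            tt = t_out[(t_out > a) & (t_out <= b)]
            sol = solve_ivp(mother_infant_rhs, (a, b), y, t_eval=tt,
                            args=(L, ip, v_milk, feeding, infp, params.MTINF),
                            method="LSODA", rtol=1e-10, atol=1e-12,
                            max_step=0.1)
            for j, x in enumerate(sol.t):
                traj[round(float(x), 6)] = sol.y[:, j]
            y = sol.y[:, -1].copy()
            if b < 48.0:
                y[L.chain[0]] += amt
        check = [t for t in t_out if t not in (0.0, 24.0, 48.0)]
        for ix in (L.pq_c, L.pq_m, L.inf_pq_c, L.auc_ven_pq):
            a = np.array([res.states[np.flatnonzero(t_out == t)[0], ix]
                          for t in check])
            b = np.array([traj[round(float(t), 6)][ix] for t in check])
            assert np.abs(a - b).max() <= 1e-6 * max(np.abs(a).max(), 1e-12)

    def test_fast_equilibration_limit(self, params, typical_mother):
        # with fast exchange and no feeding loss, milk tracks PC x plasma
        p = params.replace(Q=200.0)
        res = simulate_mother(typical_mother, p, DosingRegimen(0.5, 24.0, 2),
                              t_out=np.arange(0.0, 48.1, 0.5))
        ven = res.concentrations("PQ", "venous")
        milk = res.concentrations("PQ", "milk")
        sel = ven > 1.0
        np.testing.assert_allclose(milk[sel], p.PC_PQ * ven[sel], rtol=0.02)


class TestSecondaryPk:
    def test_half_life_closed_form(self):
        t = np.linspace(0.0, 48.0, 200)
        s = ConcentrationSeries("PQ", "venous", t, 100 * np.exp(-0.1386 * t))
        assert secondary_pk(s)["half_life"] == pytest.approx(5.0, rel=1e-3)

    def test_typical_pq_half_life(self, params, typical_mother, standard):
        # one-compartment terminal phase: t1/2 = ln2 V/CL ~ 5.31 h
        res = simulate_mother(typical_mother, params, standard,
                              t_out=np.round(np.arange(312.0, 336.01, 0.1), 8))
        pk = secondary_pk(res.series("PQ", "venous"))
        assert pk["half_life"] == pytest.approx(
            np.log(2) * params.V_PQ / params.CL_PQ, rel=0.02)

    def test_tmax_within_observed_range(self, params, typical_mother, standard):
        res = simulate_mother(typical_mother, params, standard,
                              t_out=np.round(np.arange(312.0, 336.01, 0.05), 8))
        pk = secondary_pk(res.series("PQ", "venous"))
        assert 1.29 <= pk["t_max"] - 312.0 <= 5.87

    def test_window_too_short(self):
        s = ConcentrationSeries("PQ", "venous", [0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            secondary_pk(s, window=(10.0, 20.0))
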