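"""Mother-to-infant coupling: parameter scaling, feeding transfer, and the
sensitivity analyses."""

import numpy as np
import pytest

from lactokin.infant import (InfantSubject, feeding_sensitivity,
                             maturation_sensitivity, scale_infant_params,
                             simulate_pair, tm50_from_birth_activity)
from lactokin.metrics import mother_exposure_summary
from lactokin.model_core import (FeedingPattern, maturation_fraction,
                                 square_wave_pair)
from lactokin.mother import MotherSubject, individual_params, simulate_mother

INFANT_LLOQ_PQ = 1.82


class TestScaling:
    def test_same_weight_mature_infant_equals_mother(self, params):
        ip = individual_params(params, MotherSubject(weight=51.0), 0)
        inf = InfantSubject(weight=51.0, age_months=24.0)
        p = params.replace(TM50=1e-12)   # maturation fraction -> 1
        got = scale_infant_params(ip, inf, p, 51.0)
        assert got.cl_pq == pytest.approx(ip.cl_pq, rel=1e-9)
        assert got.v_pq == ip.v_pq
        assert got.cl_cpq == ip.cl_cpq

    def test_closed_form_composition(self, params, typical_mother,
                                     typical_infant):
        ip = individual_params(params, typical_mother, 0)
        got = scale_infant_params(ip, typical_infant, params, 51.0)
        mf = (5.0 + 9.2) / (5.0 + 9.2 + 7.6)
        assert got.cl_pq == pytest.approx(17.1 * (6.8 / 51) ** 0.75 * mf)
        assert got.v_pq == pytest.approx(131.0 * 6.8 / 51)

    def test_maturation_hits_pq_clearance_only(self, params, typical_mother):
        ip = individual_params(params, typical_mother, 0)
        young = InfantSubject(weight=6.8, age_months=1.0)
        old = InfantSubject(weight=6.8, age_months=24.0)
        py, po = (scale_infant_params(ip, a, params, 51.0) for a in (young, old))
        assert py.cl_pq < po.cl_pq
        assert py.cl_cpq == po.cl_cpq

    def test_age_domain(self):
        with pytest.raises(ValueError):
            InfantSubject(weight=6.8, age_months=30.0)


@pytest.fixture(scope="module")
def pair_result(params, standard, feeding):
    return simulate_pair(MotherSubject(weight=51.0),
                         InfantSubject(weight=6.8, age_months=5.0),
                         params, standard, feeding)


@pytest.fixture(scope="module")
def feeding_table(params, standard):
    pats = [FeedingPattern(6.0, 0.4), FeedingPattern(10.0, 0.4),
            FeedingPattern(18.0, 0.4)]
    return feeding_sensitivity(pats, params, standard)


@pytest.fixture(scope="module")
def maturation_table(params, standard):
    return maturation_sensitivity([0.125, 0.25, 0.55, 1.0], params, standard)


class TestSimulatePair:
    def test_median_infant_pq_below_lloq(self, pair_result):
        s = pair_result.series("PQ", "infant_capillary")
        assert np.median(s.conc[s.times >= 24.0]) < INFANT_LLOQ_PQ
        assert s.conc.max() < INFANT_LLOQ_PQ

    def test_milk_emptied_during_feed(self, pair_result, feeding):
        # MTINF = 100/h over a 0.4-h window: > 95 % of milk content transfers
        L = pair_result.layout
        t, milk = pair_result.t, pair_result.states[:, L.pq_m]
        pre = np.interp(312.0 + 2.4 - 1e-9, t, milk)   # just before a feed
        post = np.interp(312.0 + 2.4 + feeding.window_h, t, milk)
        assert post < 0.05 * pre

    def test_ingested_not_more_than_milk_inflow(self, params, standard,
                                                feeding, typical_mother,
                                                typical_infant):
        """Molar bookkeeping over the last dosing interval: what the infant
        ingests is bounded by what entered the milk compartment."""
        t = np.unique(np.concatenate(
            [standard.dose_times(),
             np.round(np.arange(312.0, 336.0001, 0.002), 8)]))
        res = simulate_pair(typical_mother, typical_infant, params, standard,
                            feeding, t)
        L = res.layout
        sel = (res.t >= 312.0) & (res.t <= 336.0)
        ts = res.t[sel]
        g_mi, g_vm = (np.asarray(g) for g in square_wave_pair(ts, feeding))
        ip = res.ip
        c_c = res.states[sel, L.pq_c] / ip.v_pq
        c_m = res.states[sel, L.pq_m] / res.v_milk
        inflow = np.trapezoid(g_vm * ip.q * (ip.pc_pq * c_c - c_m), ts)
        ingested = np.trapezoid(g_mi * params.MTINF * res.states[sel, L.pq_m],
                                ts)
        carryover = res.states[sel, L.pq_m][0]   # milk present at window start
        # conservation: intake cannot exceed inflow plus the initial content
        # (5 % margin for trapezoid error on the gated fluxes), and at periodic
        # steady state the two fluxes nearly balance
        assert 0 < ingested <= (inflow + carryover) * 1.05
        assert ingested == pytest.approx(inflow, rel=0.05)

    def test_daily_intake_matches_dose_metric_chain(self, params, standard,
                                                    feeding, typical_mother,
                                                    typical_infant):
        # mass-flow oracle: milk emptied per feed over one day at steady state
        # equals the infant daily dose from the AUC-ratio formula
        res = simulate_pair(typical_mother, typical_infant, params, standard,
                            feeding)
        L = res.layout
        t, milk = res.t, res.states[:, L.pq_m]
        feeds = np.arange(312.0, 336.0, feeding.t_cycle)
        per_feed = [np.interp(f - 1e-6, t, milk)
                    - np.interp(f + feeding.window_h, t, milk) for f in feeds]
        delivered_ug = sum(per_feed) * params.mw_PQ
        s = mother_exposure_summary(
            simulate_mother(typical_mother, params, standard, feeding),
            standard)
        assert delivered_ug == pytest.approx(
            s.total_infant_daily_dose * typical_infant.weight, rel=0.1)

    def test_infant_exposure_linear_in_maternal_dose(self, params, feeding,
                                                     typical_mother,
                                                     typical_infant):
        from lactokin.model_core import DosingRegimen
        t = np.arange(0.0, 48.1, 0.2)
        lo = simulate_pair(typical_mother, typical_infant, params,
                           DosingRegimen(0.5, 24.0, 2), feeding, t)
        hi = simulate_pair(typical_mother, typical_infant, params,
                           DosingRegimen(1.0, 24.0, 2), feeding, t)
        np.testing.assert_allclose(
            hi.concentrations("PQ", "infant_capillary"),
            2 * lo.concentrations("PQ", "infant_capillary"), rtol=1e-9,
            atol=1e-15)


class TestFeedingSensitivity:
    def test_exposure_comparable_across_frequencies(self, feeding_table):
        table = feeding_table
        ref = table.loc[table.feeds_per_day == 10.0, "infant_auc24_PQ"].iloc[0]
        assert np.all(np.abs(table.infant_auc24_PQ / ref - 1.0) < 0.25)

    def test_infant_far_below_mother_even_large_feeds(self, params, standard):
        # extreme volume per feed (~>500 mL for a 7-kg infant)
        big = FeedingPattern(feeds_per_day=2.0, window_h=0.4,
                             intake_L_per_kg_day=0.15)
        t = feeding_sensitivity([big], params, standard)
        assert t.exposure_ratio_PQ.iloc[0] < 1.0 / 100.0

    def test_no_feeds_is_invalid(self):
        with pytest.raises(ValueError):
            FeedingPattern(feeds_per_day=0.0)


class TestMaturationSensitivity:
    def test_monotone_in_birth_activity(self, maturation_table):
        auc = maturation_table.sort_values(
            "activity_at_birth").infant_auc24_PQ.to_numpy()
        assert np.all(np.diff(auc) < 0)

    def test_slowest_maturation_still_below_lloq(self, maturation_table):
        assert maturation_table.loc[maturation_table.activity_at_birth == 0.125,
                                    "infant_cmax_PQ"].iloc[0] < INFANT_LLOQ_PQ

    def test_default_activity_matches_printed_tm50(self, params):
        # 55 % at full-term birth corresponds to TM50 ~ 7.5 months, close to
        # the implemented 7.6
        tm50 = tm50_from_birth_activity(0.55, params.gestation_months)
        assert tm50 == pytest.approx(params.TM50, rel=0.02)
        assert maturation_fraction(9.2, tm50) == pytest.approx(0.55, abs=1e-12)

    def test_full_activity_means_no_maturation(self, maturation_table):
        row = maturation_table.loc[
            maturation_table.activity_at_birth == 1.0].iloc[0]
        assert row.tm50 < 1e-6

    def test_invalid_activity(self):
        with pytest.raises(ValueError):
            tm50_from_birth_activity(0.0)
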