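"""Single-mother simulation: venous, capillary, and breast-milk
concentration-time profiles plus secondary pharmacokinetic parameters.

The maternal model (as estimated from the clinical data) keeps the plasma-milk
exchange open continuously; the feeding square wave belongs to the coupled
mother-to-infant simulation (see :mod:`lactokin.infant`).  The feeding pattern
still matters here because it sets the milk-compartment volume (one feed's
volume of milk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model_core as mc
from .engine import Bolus, Segmented, propagate
from .model_core import (DosingRegimen, FeedingPattern, IndividualParams,
                         InfantParams, ModelLayout, ParameterSet,
                         build_matrix, milk_compartment_volume)

__all__ = ["MotherSubject", "ConcentrationSeries", "SimResult",
           "individual_params", "simulate_mother", "capillary_from_venous",
           "secondary_pk", "DEFAULT_OCCASION_STARTS"]

#: dosing days carrying separate inter-occasion random effects (h)
DEFAULT_OCCASION_STARTS = (0.0, 72.0, 168.0, 312.0)

IIV_PARAMS = ("F", "MTT", "FM", "CL_PQ", "V_PQ", "CL_CPQ", "V_CPQ", "Q")
IOV_PARAMS = ("F", "MTT")


@dataclass
class MotherSubject:
    """A (virtual) breastfeeding mother: covariates plus sampled random effects.

    ``eta`` maps parameter names to IIV deviates; ``kappa`` maps parameter
    names to one IOV deviate per occasion.  The most recent occasion's deviate
    persists beyond the last occasion boundary.
    """

    id: int = 0
    weight: float = 51.0
    age: float | None = None
    smoking: bool = False
    eta: dict = field(default_factory=dict)
    kappa: dict = field(default_factory=dict)
    occasion_starts: tuple = DEFAULT_OCCASION_STARTS
    infant_weight: float = 6.8     # linked infant, sets the Eq-1 milk volume

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        for d in (self.eta, self.kappa):
            for k, v in d.items():
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"non-finite random effect for {k}")

    def occasion_at(self, t: float) -> int:
        occ = int(np.searchsorted(self.occasion_starts, t, side="right")) - 1
        return max(occ, 0)


@dataclass
class ConcentrationSeries:
    analyte: str                 # "PQ" | "CPQ"
    matrix: str                  # venous | capillary | milk | infant_capillary
    times: np.ndarray            # h
    conc: np.ndarray             # ng/mL
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc < -1e-9):
            raise ValueError("negative concentrations")
        self.conc = np.clip(self.conc, 0.0, None)


def individual_params(params: ParameterSet, subject: MotherSubject,
                      occasion: int = 0) -> IndividualParams:
    """Resolve individual parameter values for one occasion.

    theta_i = theta_pop x (W/W_ref)^exp x exp(eta + kappa_occ); F and MTT
    carry both IIV and IOV; clearances scale with exponent 0.75 and volumes
    with 1.  Covariate hooks (smoking on F, age on V_PQ) are inert unless
    enabled in the :class:`~lactokin.model_core.ParameterSet`.
    """
    n_occ = len(subject.occasion_starts)
    if not 0 <= occasion < n_occ:
        raise ValueError(f"unknown occasion {occasion}")

    def eff(name: str, base: float) -> float:
        e = subject.eta.get(name, 0.0)
        if name in IOV_PARAMS and name in subject.kappa:
            e = e + subject.kappa[name][occasion]
        return base * float(np.exp(e))

    wr = subject.weight / params.ref_weight
    f = eff("F", params.F)
    if subject.smoking:
        f *= 1.0 + params.smoking_effect_on_F
    v_pq = eff("V_PQ", params.V_PQ) * wr ** params.alloV_exp
    if subject.age is not None and params.age_effect_on_V_PQ:
        v_pq *= 1.0 + params.age_effect_on_V_PQ * (subject.age - 23.0)
    fm = min(eff("FM", params.FM), 0.999)  # lognormal IIV can stray above 1
    return IndividualParams(
        f=f,
        mtt=eff("MTT", params.MTT),
        fm=fm,
        cl_pq=eff("CL_PQ", params.CL_PQ) * wr ** params.alloCL_exp,
        v_pq=v_pq,
        cl_cpq=eff("CL_CPQ", params.CL_CPQ) * wr ** params.alloCL_exp,
        v_cpq=eff("V_CPQ", params.V_CPQ) * wr ** params.alloV_exp,
        cf_pq=params.CF_PQ,
        cf_cpq=params.CF_CPQ,
        q=eff("Q", params.Q) * wr ** params.alloCL_exp,
        pc_pq=params.PC_PQ,
        pc_cpq=params.PC_CPQ,
        n_transit=params.n_transit,
    )


class SimResult:
    """Trajectory of one simulated subject (or mother-infant pair)."""

    def __init__(self, t: np.ndarray, states: np.ndarray, layout: ModelLayout,
                 ip0: IndividualParams, v_milk: float, subject_id: int = 0,
                 infant: InfantParams | None = None,
                 mw_pq: float = mc.MW_PQ, mw_cpq: float = mc.MW_CPQ):
        self.t = t
        self.states = states
        self.layout = layout
        self.ip = ip0          # volumes/CFs carry no IOV: constant per subject
        self.v_milk = v_milk
        self.subject_id = subject_id
        self.infant = infant
        self.mw = {"PQ": mw_pq, "CPQ": mw_cpq}

    def concentrations(self, analyte: str, matrix: str) -> np.ndarray:
        L, ip = self.layout, self.ip
        mw = self.mw[analyte]
        if matrix in ("venous", "capillary"):
            ix = L.pq_c if analyte == "PQ" else L.cpq_c
            v = ip.v_pq if analyte == "PQ" else ip.v_cpq
            conc = self.states[:, ix] * mw / v
            if matrix == "capillary":
                conc = capillary_from_venous(
                    conc, ip.cf_pq if analyte == "PQ" else ip.cf_cpq)
            return conc
        if matrix == "milk":
            ix = L.pq_m if analyte == "PQ" else L.cpq_m
            return self.states[:, ix] * mw / self.v_milk
        if matrix == "infant_capillary":
            if self.infant is None:
                raise ValueError("no infant in this simulation")
            ix = L.inf_pq_c if analyte == "PQ" else L.inf_cpq_c
            v = self.infant.v_pq if analyte == "PQ" else self.infant.v_cpq
            return self.states[:, ix] * mw / v
        raise ValueError(f"unknown matrix {matrix!r}")

    def series(self, analyte: str, matrix: str) -> ConcentrationSeries:
        return ConcentrationSeries(analyte, matrix, self.t,
                                   self.concentrations(analyte, matrix),
                                   self.subject_id)

    def auc(self, analyte: str, matrix: str,
            window: tuple[float, float] | None = None) -> float:
        """AUC (ng.h/mL) from the exact integrator states."""
        L = self.layout
        ix = {("PQ", "venous"): L.auc_ven_pq,
              ("CPQ", "venous"): L.auc_ven_cpq,
              ("PQ", "milk"): L.auc_milk_pq,
              ("CPQ", "milk"): L.auc_milk_cpq}
        if self.infant is not None:
            ix[("PQ", "infant_capillary")] = L.auc_inf_pq
            ix[("CPQ", "infant_capillary")] = L.auc_inf_cpq
        col = self.states[:, ix[(analyte, matrix)]]
        if window is None:
            return float(col[-1])
        a, b = window
        return float(np.interp(b, self.t, col) - np.interp(a, self.t, col))

    def total_in_system(self) -> np.ndarray:
        """Total micromoles in all amount compartments plus the sink."""
        return self.states[:, self.layout.mass_indices()].sum(axis=1)


def _dose_events(subject: MotherSubject, params: ParameterSet,
                 regimen: DosingRegimen, layout: ModelLayout) -> tuple[list, float]:
    doses, total = [], 0.0
    dose_mg = regimen.dose_mg_base_per_kg * subject.weight
    for td in regimen.dose_times():
        occ = subject.occasion_at(td)
        ip = individual_params(params, subject, occ)
        amt = ip.f * dose_mg / params.mw_PQ * 1000.0  # µmol
        doses.append(Bolus(float(td), layout.chain[0], amt))
        total += amt
    return doses, total


def _build_schedule(subject: MotherSubject, params: ParameterSet,
                    regimen: DosingRegimen, layout: ModelLayout,
                    v_milk: float, t_end: float,
                    feeding: FeedingPattern | None,
                    infant: InfantParams | None) -> Segmented:
    occ_starts = [t for t in subject.occasion_starts if 0.0 < t < t_end]
    gate_times: list[float] = []
    if feeding is not None:
        t0 = feeding.first_feed_offset_h
        n_cyc = int(np.ceil((t_end - t0) / feeding.t_cycle)) + 1
        for j in range(n_cyc):
            a = t0 + j * feeding.t_cycle
            for x in (a, a + feeding.window_h):
                if 0.0 < x < t_end:
                    gate_times.append(x)
    breaks = sorted(set(occ_starts) | set(gate_times))
    mids = [0.5 * (a + b) for a, b in
            zip([0.0] + breaks, breaks + [t_end if breaks else max(t_end, 1.0)])]

    matrices: dict = {}
    keys = []
    for tm in mids:
        occ = subject.occasion_at(tm)
        if feeding is not None:
            g_mi, g_vm = mc.square_wave_pair(tm, feeding)
        else:
            g_mi, g_vm = 0.0, 1.0
        key = (occ, int(g_mi))
        keys.append(key)
        if key not in matrices:
            ip = individual_params(params, subject, occ)
            matrices[key] = build_matrix(
                layout, ip, v_milk, gate_vm=g_vm, gate_mi=g_mi,
                infant=infant, mtinf=params.MTINF,
                mw_pq=params.mw_PQ, mw_cpq=params.mw_CPQ)
    return Segmented(breaks, keys, matrices)


def simulate_subject(subject: MotherSubject, params: ParameterSet,
                     regimen: DosingRegimen,
                     feeding: FeedingPattern | None,
                     t_out: np.ndarray, gated: bool,
                     infant: InfantParams | None = None) -> SimResult:
    """Shared driver behind the mother-only and mother-infant simulations."""
    feeding = feeding if feeding is not None else FeedingPattern()
    layout = ModelLayout(n_transit=params.n_transit,
                         n_transit_inf=params.n_transit_inf,
                         infant=infant is not None, auc=True, sink=True)
    v_milk = milk_compartment_volume(subject.infant_weight,
                                     feeding.feeds_per_day,
                                     feeding.intake_L_per_kg_day)
    t_out = np.asarray(t_out, dtype=float)
    t_end = float(t_out[-1])
    doses, _ = _dose_events(subject, params, regimen, layout)
    schedule = _build_schedule(subject, params, regimen, layout, v_milk, t_end,
                               feeding if gated else None, infant)
    states = propagate(schedule, doses, t_out, layout.n_states)
    ip0 = individual_params(params, subject, 0)
    return SimResult(t_out, states, layout, ip0, v_milk, subject.id,
                     infant=infant, mw_pq=params.mw_PQ, mw_cpq=params.mw_CPQ)


def default_grid(regimen: DosingRegimen, dt: float = 0.1,
                 tail_h: float = 24.0) -> np.ndarray:
    t_end = regimen.last_dose_time + tail_h
    return np.round(np.arange(0.0, t_end + dt / 2, dt), 10)


def simulate_mother(subject: MotherSubject, params: ParameterSet,
                    regimen: DosingRegimen,
                    feeding: FeedingPattern | None = None,
                    t_out: np.ndarray | None = None,
                    gated: bool = False) -> SimResult:
    """Simulate one mother (venous/capillary/milk, both analytes).

    ``gated=False`` (default) is the maternal model as estimated: continuous
    plasma-milk equilibration, no milk loss to the infant.  ``gated=True``
    applies the feeding square waves (used mainly through
    :func:`lactokin.infant.simulate_pair`).
    """
    if t_out is None:
        t_out = default_grid(regimen)
    return simulate_subject(subject, params, regimen, feeding, t_out, gated)


def capillary_from_venous(venous_conc, cf: float):
    """Proportional venous-to-capillary conversion."""
    if cf <= 0:
        raise ValueError("conversion factor must be positive")
    return np.asarray(venous_conc, dtype=float) * cf


def secondary_pk(series: ConcentrationSeries,
                 window: tuple[float, float] | None = None,
                 n_terminal: int = 5) -> dict:
    """C_MAX/T_MAX, trapezoidal AUC, and log-linear terminal half-life.

    ``window`` restricts all metrics to a time window (e.g. the last dosing
    interval); the half-life regression uses the last ``n_terminal`` positive
    concentrations after T_MAX.
    """
    t, c = series.times, series.conc
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, c = t[m], c[m]
    if t.size < 2:
        raise ValueError("series does not cover the requested window")
    imax = int(np.argmax(c))
    out = {
        "t_max": float(t[imax]),
        "c_max": float(c[imax]),
        "auc": float(np.trapezoid(c, t)),
    }
    pos = np.where((c > 0) & (t > t[imax]))[0]
    if pos.size >= n_terminal:
        sel = pos[-n_terminal:]
        slope = np.polyfit(t[sel], np.log(c[sel]), 1)[0]
        out["half_life"] = float(np.log(2.0) / -slope) if slope < 0 else np.inf
    else:
        out["half_life"] = np.nan
    return out
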