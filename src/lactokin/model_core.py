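"""Structural mother-to-infant pharmacokinetic model of primaquine (PQ) and
carboxyprimaquine (CPQ) during lactation.

The maternal model is a transit-compartment absorption chain feeding a
one-compartment disposition model for each analyte, with a first-pass split of
the absorbed flux into the metabolite, and a breast-milk compartment per
analyte that equilibrates with venous plasma through a shared intercompartmental
clearance Q.  The infant side receives the milk-compartment content through a
fast first-order emptying rate (MTINF) that is switched on only during feeding
windows; transfer from plasma to milk is switched off during feeds.  Both
switches are exact 0/1 square waves derived from the feeding pattern.

All amounts are carried internally in micromoles; concentrations are reported
in ng/mL (amount[µmol] x molar mass[g/mol] / volume[L]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

__all__ = [
    "MW_PQ",
    "MW_CPQ",
    "ParameterSet",
    "FeedingPattern",
    "DosingRegimen",
    "IndividualParams",
    "InfantParams",
    "ModelLayout",
    "square_wave_pair",
    "square_wave_pair_sine",
    "maturation_fraction",
    "allometric_scale",
    "transit_rate",
    "milk_compartment_volume",
    "build_matrix",
    "mother_infant_rhs",
]

# Molar masses (g/mol) of the free bases: primaquine C15H21N3O and
# carboxyprimaquine C15H18N2O3.  Used only to convert mg doses in and
# ng/mL concentrations out; the state vector is molar.
MW_PQ = 259.35
MW_CPQ = 274.32

#: residual-error keys: (analyte, matrix)
RESIDUAL_KEYS = (
    ("PQ", "venous"),
    ("CPQ", "venous"),
    ("PQ", "capillary"),
    ("CPQ", "capillary"),
    ("PQ", "milk"),
    ("CPQ", "milk"),
)


def _cv_to_variance(cv_percent: float) -> float:
    """Variance of a lognormal random effect from its %CV."""
    return math.log(1.0 + (cv_percent / 100.0) ** 2)


@dataclass
class ParameterSet:
    """Population parameters of the final simultaneous PQ/CPQ model.

    Fixed effects are typical values for a mother at ``ref_weight``; ``omega``
    and ``pi`` hold the inter-individual (IIV) and inter-occasion (IOV)
    variances of the exponential random-effect model, and ``sigma`` the
    additive-on-log-scale residual variances per analyte x matrix.
    """

    F: float = 1.0                 # relative bioavailability (fixed)
    MTT: float = 1.44              # mean transit absorption time (h)
    n_transit: int = 4             # maternal transit compartments
    FM: float = 0.282              # first-pass fraction PQ -> CPQ
    CL_PQ: float = 17.1            # L/h
    V_PQ: float = 131.0            # L
    CL_CPQ: float = 0.967          # L/h
    V_CPQ: float = 22.7            # L
    CF_PQ: float = 0.898           # venous -> capillary factor
    CF_CPQ: float = 1.06
    Q: float = 0.400               # plasma <-> milk clearance, both analytes (L/h)
    PC_PQ: float = 0.376           # milk partition fraction
    PC_CPQ: float = 0.00889
    MTINF: float = 100.0           # milk -> infant emptying rate during feeds (1/h)
    MTT_inf: float = 0.706         # infant mean transit time (h)
    n_transit_inf: int = 2
    TM50: float = 7.6              # PMA of half-mature MAO-A clearance (months)
    gestation_months: float = 9.2  # full-term PMA offset
    alloCL_exp: float = 0.75
    alloV_exp: float = 1.0
    ref_weight: float = 51.0       # allometric reference body weight (kg)
    mw_PQ: float = MW_PQ
    mw_CPQ: float = MW_CPQ
    # IIV variances, keyed by parameter name
    omega: dict = field(default_factory=lambda: {
        "F": _cv_to_variance(15.7),
        "MTT": _cv_to_variance(20.5),
        "FM": _cv_to_variance(42.1),
        "CL_PQ": _cv_to_variance(15.1),
        "V_PQ": _cv_to_variance(19.2),
        "CL_CPQ": _cv_to_variance(26.7),
        "V_CPQ": _cv_to_variance(17.7),
        "Q": _cv_to_variance(89.7),
    })
    # IOV variances (per occasion), keyed by parameter name
    pi: dict = field(default_factory=lambda: {
        "F": _cv_to_variance(20.5),
        "MTT": _cv_to_variance(56.8),
    })
    # residual variances on the log scale, keyed "ANALYTE:matrix"
    sigma: dict = field(default_factory=lambda: {
        "PQ:venous": 0.102,
        "CPQ:venous": 0.0198,
        "PQ:capillary": 0.0570,
        "CPQ:capillary": 0.0115,
        "PQ:milk": 0.156,
        "CPQ:milk": 0.0911,
    })
    # optional covariate hooks, OFF by default (rejected in backward elimination)
    smoking_effect_on_F: float = 0.0     # e.g. -0.259 for -25.9 % in smokers
    age_effect_on_V_PQ: float = 0.0      # e.g. +0.0129 per year from median age

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("MTT", "CL_PQ", "V_PQ", "CL_CPQ", "V_CPQ", "Q",
                     "MTINF", "MTT_inf", "TM50", "ref_weight", "F",
                     "CF_PQ", "CF_CPQ", "mw_PQ", "mw_CPQ"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.FM <= 1.0:
            raise ValueError("FM must lie in [0, 1]")
        for name in ("PC_PQ", "PC_CPQ"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for n in ("n_transit", "n_transit_inf"):
            v = getattr(self, n)
            if int(v) != v or v < 0:
                raise ValueError(f"{n} must be a non-negative integer")
        for d in (self.omega, self.pi, self.sigma):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"variance {k} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class FeedingPattern:
    """Breastfeeding pattern driving the square-wave gates and Eq-1 milk volume."""

    feeds_per_day: float = 10.0
    window_h: float = 0.4          # feeding-window length (24 min by default)
    intake_L_per_kg_day: float = 0.15
    first_feed_offset_h: float = 0.0

    def __post_init__(self) -> None:
        if self.feeds_per_day <= 0:
            raise ValueError("feeds_per_day must be positive")
        if self.intake_L_per_kg_day <= 0:
            raise ValueError("intake must be positive")
        if not 0.0 < self.window_h < self.t_cycle:
            raise ValueError("need 0 < window_h < 24/feeds_per_day")

    @property
    def t_cycle(self) -> float:
        return 24.0 / self.feeds_per_day


@dataclass(frozen=True)
class DosingRegimen:
    dose_mg_base_per_kg: float
    interval_h: float
    n_doses: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.dose_mg_base_per_kg <= 0 or self.interval_h <= 0 or self.n_doses < 1:
            raise ValueError("invalid dosing regimen")

    @property
    def last_dose_time(self) -> float:
        return (self.n_doses - 1) * self.interval_h

    def dose_times(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.interval_h

    def daily_dose_mg_per_kg(self) -> float:
        """Weight-normalised dose per 24 h during the dosing period."""
        return self.dose_mg_base_per_kg * (24.0 / self.interval_h)


def square_wave_pair(t, feeding: FeedingPattern):
    """Exact modular-arithmetic square-wave gates.

    Returns ``(gate_milk_to_infant, gate_venous_to_milk)``; the first is 1
    during the feeding window of each cycle, the second is its complement.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    phase = np.mod(t - feeding.first_feed_offset_h, feeding.t_cycle)
    g_mi = (phase < feeding.window_h).astype(float)
    return (g_mi, 1.0 - g_mi) if t.ndim else (float(g_mi), float(1.0 - g_mi))


def square_wave_pair_sine(t, feeding: FeedingPattern):
    """Sine-wave construction of the same gates.

    A sinusoid with the cycle period is compared against the level
    ``S1 = cos(pi * SH1 / T_CYCLE)`` (SH1 = time spent in state 0); the gate is
    1 on the sub-threshold arc, whose length equals the feeding window.  Agrees
    with :func:`square_wave_pair` at all non-boundary times.
    """
    t = np.asarray(t, dtype=float)
    T = feeding.t_cycle
    sh1 = T - feeding.window_h
    s1 = math.sin((math.pi - 2.0 * math.pi * sh1 / T) / 2.0)  # = cos(pi*sh1/T)
    # phase chosen so the ON arc starts at the first feed offset
    phi0 = math.pi / 2.0 + math.pi * sh1 / T
    s2 = np.sin(2.0 * np.pi * (t - feeding.first_feed_offset_h) / T + phi0)
    g_mi = (s2 < s1).astype(float)
    return (g_mi, 1.0 - g_mi) if t.ndim else (float(g_mi), float(1.0 - g_mi))


def maturation_fraction(pma_months: float, tm50: float) -> float:
    """Hyperbolic MAO-A maturation: fraction of mature clearance at a given
    postmenstrual age (months)."""
    if pma_months <= 0 or tm50 <= 0:
        raise ValueError("pma and tm50 must be positive")
    return pma_months / (pma_months + tm50)


def allometric_scale(value: float, weight: float, ref_weight: float,
                     exponent: float) -> float:
    if weight <= 0 or ref_weight <= 0:
        raise ValueError("weights must be positive")
    return value * (weight / ref_weight) ** exponent


def transit_rate(mtt: float, n: int) -> float:
    """Transit (and absorption) rate constant k = (n+1)/MTT for a chain of
    n transit compartments plus the absorption step (k_a = k_tr)."""
    if mtt <= 0:
        raise ValueError("mtt must be positive")
    if n < 0:
        raise ValueError("n must be >= 0")
    return (n + 1) / mtt


def milk_compartment_volume(infant_weight: float, feeds_per_day: float,
                            intake_L_per_kg_day: float = 0.15) -> float:
    """Breast-milk compartment volume: daily intake volume divided by the
    number of feeds (the volume of one feed)."""
    if infant_weight <= 0 or intake_L_per_kg_day <= 0:
        raise ValueError("inputs must be positive")
    if feeds_per_day <= 0:
        raise ValueError("feeds_per_day must be positive")
    return intake_L_per_kg_day * infant_weight / feeds_per_day


@dataclass(frozen=True)
class IndividualParams:
    """Occasion-resolved individual maternal parameters (allometry and random
    effects already applied)."""

    f: float
    mtt: float
    fm: float
    cl_pq: float
    v_pq: float
    cl_cpq: float
    v_cpq: float
    cf_pq: float
    cf_cpq: float
    q: float
    pc_pq: float
    pc_cpq: float
    n_transit: int = 4

    @property
    def k_tr(self) -> float:
        return transit_rate(self.mtt, self.n_transit)


@dataclass(frozen=True)
class InfantParams:
    """Infant disposition parameters (scaled from the mother and fixed)."""

    cl_pq: float      # maturation-scaled PQ clearance (L/h)
    v_pq: float
    cl_cpq: float
    v_cpq: float
    mtt: float = 0.706
    n_transit: int = 2

    @property
    def k_tr(self) -> float:
        return transit_rate(self.mtt, self.n_transit)


class ModelLayout:
    """State-vector index map.

    Mother: absorption chain of (n_transit + 1) compartments, PQ/CPQ central,
    PQ/CPQ milk, elimination sink.  Optional infant block: one chain of
    (n_transit_inf + 1) per analyte plus two centrals.  Optional cumulative-AUC
    integrator states (venous PQ/CPQ, milk PQ/CPQ and, with an infant,
    infant PQ/CPQ), which integrate concentration in ng/mL.
    """

    def __init__(self, n_transit: int = 4, n_transit_inf: int = 2,
                 infant: bool = False, auc: bool = True, sink: bool = True):
        self.n_chain = n_transit + 1
        self.n_chain_inf = n_transit_inf + 1
        self.infant = infant
        self.auc = auc
        self.sink = sink
        i = 0
        self.chain = list(range(i, i + self.n_chain)); i += self.n_chain
        self.pq_c = i; i += 1
        self.cpq_c = i; i += 1
        self.pq_m = i; i += 1
        self.cpq_m = i; i += 1
        if sink:
            self.sink_ix = i; i += 1
        else:
            self.sink_ix = None
        if infant:
            self.inf_chain_pq = list(range(i, i + self.n_chain_inf)); i += self.n_chain_inf
            self.inf_chain_cpq = list(range(i, i + self.n_chain_inf)); i += self.n_chain_inf
            self.inf_pq_c = i; i += 1
            self.inf_cpq_c = i; i += 1
        if auc:
            self.auc_ven_pq = i; i += 1
            self.auc_ven_cpq = i; i += 1
            self.auc_milk_pq = i; i += 1
            self.auc_milk_cpq = i; i += 1
            if infant:
                self.auc_inf_pq = i; i += 1
                self.auc_inf_cpq = i; i += 1
        self.n_states = i

    def mass_indices(self) -> list:
        """Indices of true amount states (AUC integrators excluded)."""
        ix = list(self.chain) + [self.pq_c, self.cpq_c, self.pq_m, self.cpq_m]
        if self.sink:
            ix.append(self.sink_ix)
        if self.infant:
            ix += self.inf_chain_pq + self.inf_chain_cpq
            ix += [self.inf_pq_c, self.inf_cpq_c]
        return ix


def build_matrix(layout: ModelLayout, ip: IndividualParams, v_milk: float,
                 gate_vm: float = 1.0, gate_mi: float = 0.0,
                 infant: InfantParams | None = None, mtinf: float = 100.0,
                 mw_pq: float = MW_PQ, mw_cpq: float = MW_CPQ) -> np.ndarray:
    """Assemble the (gate-resolved) constant system matrix M with y' = M y.

    All first-order, so the full system is linear; the gates enter as fixed
    0/1 multipliers, making the dynamics piecewise time-invariant.
    """
    L = layout
    M = np.zeros((L.n_states, L.n_states))
    k = ip.k_tr
    # absorption chain
    for j, ix in enumerate(L.chain):
        M[ix, ix] -= k
        if j > 0:
            M[ix, L.chain[j - 1]] += k
    last = L.chain[-1]
    # first-pass split of the absorbed flux
    M[L.pq_c, last] += (1.0 - ip.fm) * k
    M[L.cpq_c, last] += ip.fm * k
    ke_pq = ip.cl_pq / ip.v_pq
    ke_cpq = ip.cl_cpq / ip.v_cpq
    # PQ elimination converts mole-for-mole into CPQ central
    M[L.pq_c, L.pq_c] -= ke_pq
    M[L.cpq_c, L.pq_c] += ke_pq
    M[L.cpq_c, L.cpq_c] -= ke_cpq
    if L.sink:
        M[L.sink_ix, L.cpq_c] += ke_cpq
    # plasma <-> milk equilibration: Q x (PC x C_central - C_milk), gated
    for c, m, pc in ((L.pq_c, L.pq_m, ip.pc_pq), (L.cpq_c, L.cpq_m, ip.pc_cpq)):
        vc = ip.v_pq if c == L.pq_c else ip.v_cpq
        M[m, c] += gate_vm * ip.q * pc / vc
        M[c, c] -= gate_vm * ip.q * pc / vc
        M[m, m] -= gate_vm * ip.q / v_milk
        M[c, m] += gate_vm * ip.q / v_milk
        # milk -> infant emptying during feeds
        M[m, m] -= gate_mi * mtinf
    if infant is not None:
        if not L.infant:
            raise ValueError("layout lacks infant states")
        M[L.inf_chain_pq[0], L.pq_m] += gate_mi * mtinf
        M[L.inf_chain_cpq[0], L.cpq_m] += gate_mi * mtinf
        ki = infant.k_tr
        for chain, central in ((L.inf_chain_pq, L.inf_pq_c),
                               (L.inf_chain_cpq, L.inf_cpq_c)):
            for j, ix in enumerate(chain):
                M[ix, ix] -= ki
                if j > 0:
                    M[ix, chain[j - 1]] += ki
            M[central, chain[-1]] += ki
        kei_pq = infant.cl_pq / infant.v_pq
        kei_cpq = infant.cl_cpq / infant.v_cpq
        # infant PQ elimination forms infant CPQ (mirrors the mother)
        M[L.inf_pq_c, L.inf_pq_c] -= kei_pq
        M[L.inf_cpq_c, L.inf_pq_c] += kei_pq
        M[L.inf_cpq_c, L.inf_cpq_c] -= kei_cpq
        if L.sink:
            M[L.sink_ix, L.inf_cpq_c] += kei_cpq
    if L.auc:
        M[L.auc_ven_pq, L.pq_c] += mw_pq / ip.v_pq
        M[L.auc_ven_cpq, L.cpq_c] += mw_cpq / ip.v_cpq
        M[L.auc_milk_pq, L.pq_m] += mw_pq / v_milk
        M[L.auc_milk_cpq, L.cpq_m] += mw_cpq / v_milk
        if infant is not None:
            M[L.auc_inf_pq, L.inf_pq_c] += mw_pq / infant.v_pq
            M[L.auc_inf_cpq, L.inf_cpq_c] += mw_cpq / infant.v_cpq
    return M


def mother_infant_rhs(t: float, y: np.ndarray, layout: ModelLayout,
                      ip: IndividualParams, v_milk: float,
                      feeding: FeedingPattern | None,
                      infant: InfantParams | None = None,
                      mtinf: float = 100.0) -> np.ndarray:
    """Time-dependent right-hand side for ODE solvers.

    With ``feeding=None`` the venous->milk gate is held open and the
    milk->infant gate closed (the continuous maternal model).  NaN or negative
    state signals solver failure.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise FloatingPointError("non-finite state encountered")
    if feeding is None:
        g_mi, g_vm = 0.0, 1.0
    else:
        g_mi, g_vm = square_wave_pair(t, feeding)
    M = build_matrix(layout, ip, v_milk, gate_vm=g_vm, gate_mi=g_mi,
                     infant=infant, mtinf=mtinf)
    return M @ y
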