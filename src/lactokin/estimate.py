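"""Mixed-effects estimation and simulation-based diagnostics.

The observation model is Gaussian on the log scale: log(obs) ~ N(log(pred),
sigma^2) with a separate residual variance per analyte x matrix.  Fitting
maximises either the naive pooled likelihood (all random effects zero) or a
per-subject Laplace approximation to the marginal likelihood over the
inter-individual random effects (a practical stand-in for FOCE-I).  The
objective function value (OFV) is -2 x log-likelihood, and nested models are
compared on its chi-square-distributed difference.

Also here: the %CV conversion for lognormal random-effect variances and the
prediction-corrected visual predictive check (pcVPC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import PowerPropagator
from .model_core import (FeedingPattern, IndividualParams, ModelLayout,
                         ParameterSet, build_matrix, milk_compartment_volume)
from .mother import MotherSubject, individual_params
from .synthetic import PKDataset

__all__ = ["FitResult", "VPCResult", "SubjectRecords", "prepare_subjects",
           "subject_loglik", "fit_population", "ofv_test", "cv_from_variance",
           "pc_vpc"]

FIT_PARAMS_DEFAULT = ("CL_PQ", "V_PQ", "CL_CPQ", "V_CPQ", "FM")
_QUANTUM = 0.25  # study sampling times fall on a 15-minute grid


# ---------------------------------------------------------------------------
# data preparation

@dataclass
class SubjectRecords:
    """One subject's dosing and (non-BLQ unless M3) observation records.

    The merged event schedule (``ev_*``) is precomputed so repeated likelihood
    evaluations only pay for matrix exponentials, not bookkeeping.
    """

    id: int
    weight: float
    infant_weight: float
    dose_times: np.ndarray
    dose_amt_mg: np.ndarray
    obs_times: np.ndarray
    log_dv: np.ndarray            # NaN for BLQ rows kept under the M3 policy
    sigma2: np.ndarray            # residual variance per record
    state_ix: np.ndarray          # state index per record
    factor_kind: np.ndarray       # 0: /V_PQ, 1: /V_CPQ, 2: x CF.., see predict
    blq: np.ndarray
    log_lloq: np.ndarray
    ev_times: np.ndarray = None
    ev_dose_mg: np.ndarray = None
    ev_obs_ix: list = None

    def __post_init__(self) -> None:
        self.ev_times = np.unique(np.concatenate([self.dose_times,
                                                  self.obs_times]))
        self.ev_dose_mg = np.zeros(self.ev_times.size)
        self.ev_obs_ix = []
        for i, te in enumerate(self.ev_times):
            self.ev_dose_mg[i] = self.dose_amt_mg[self.dose_times == te].sum()
            self.ev_obs_ix.append(np.flatnonzero(self.obs_times == te))


_KINDS = {("PQ", "venous"): 0, ("CPQ", "venous"): 1,
          ("PQ", "capillary"): 2, ("CPQ", "capillary"): 3,
          ("PQ", "milk"): 4, ("CPQ", "milk"): 5}


def prepare_subjects(dataset: PKDataset, params: ParameterSet,
                     blq_policy: str = "discard",
                     feeding: FeedingPattern | None = None) -> list[SubjectRecords]:
    """Index the maternal records of a dataset for fast likelihood evaluation."""
    if blq_policy not in ("discard", "m3"):
        raise ValueError("blq_policy must be 'discard' or 'm3'")
    feeding = feeding if feeding is not None else FeedingPattern()
    layout = ModelLayout(n_transit=params.n_transit, auc=False, sink=False)
    six = {0: layout.pq_c, 1: layout.cpq_c, 2: layout.pq_c, 3: layout.cpq_c,
           4: layout.pq_m, 5: layout.cpq_m}
    out = []
    df = dataset.df[dataset.df.ROLE == "mother"]
    for sid, g in df.groupby("ID"):
        doses = g[g.EVID == 1]
        obs = g[g.EVID == 0]
        if blq_policy == "discard":
            obs = obs[obs.BLQ == 0]
        # zero observations (pre-first-dose samples) carry no information
        # under a lognormal error model
        obs = obs[(obs.BLQ == 1) | (obs.DV > 0)]
        kinds = np.array([_KINDS[(a, m)] for a, m in
                          zip(obs.ANALYTE, obs.MATRIX)], dtype=int)
        sig = np.array([params.sigma[f"{a}:{m}"] for a, m in
                        zip(obs.ANALYTE, obs.MATRIX)])
        dv = obs.DV.to_numpy(dtype=float)
        lq = obs.LLOQ.to_numpy(dtype=float)
        out.append(SubjectRecords(
            id=int(sid), weight=float(g.WT.iloc[0]),
            infant_weight=float(g.IWT.iloc[0]),
            dose_times=doses.TIME.to_numpy(dtype=float),
            dose_amt_mg=doses.AMT.to_numpy(dtype=float),
            obs_times=obs.TIME.to_numpy(dtype=float),
            log_dv=np.log(np.where(dv > 0, dv, np.nan)),
            sigma2=sig, state_ix=np.array([six[k] for k in kinds]),
            factor_kind=kinds,
            blq=obs.BLQ.to_numpy(dtype=int),
            log_lloq=np.where(lq > 0, np.log(np.where(lq > 0, lq, 1.0)), -np.inf),
        ))
    return out


# ---------------------------------------------------------------------------
# prediction and likelihood

def _predict(subj: SubjectRecords, ip: IndividualParams, params: ParameterSet,
             v_milk: float) -> np.ndarray:
    """Model-predicted concentrations (ng/mL) at the subject's record times."""
    layout = ModelLayout(n_transit=ip.n_transit, auc=False, sink=False)
    M = build_matrix(layout, ip, v_milk, gate_vm=1.0, gate_mi=0.0,
                     mw_pq=params.mw_PQ, mw_cpq=params.mw_CPQ)
    pp = PowerPropagator(M, _QUANTUM, max_pow=14)
    conv = ip.f / params.mw_PQ * 1000.0
    y = np.zeros(layout.n_states)
    amounts = np.empty(subj.obs_times.size)
    t_cur = 0.0
    for i, te in enumerate(subj.ev_times):
        if te > t_cur:
            y = pp.step(y, te - t_cur)
            t_cur = te
        if subj.ev_dose_mg[i]:
            y[layout.chain[0]] += subj.ev_dose_mg[i] * conv
        ox = subj.ev_obs_ix[i]
        if ox.size:
            amounts[ox] = y[subj.state_ix[ox]]
    factors = np.array([
        params.mw_PQ / ip.v_pq, params.mw_CPQ / ip.v_cpq,
        ip.cf_pq * params.mw_PQ / ip.v_pq, ip.cf_cpq * params.mw_CPQ / ip.v_cpq,
        params.mw_PQ / v_milk, params.mw_CPQ / v_milk,
    ])
    return amounts * factors[subj.factor_kind]


def subject_loglik(subj: SubjectRecords, ip: IndividualParams,
                   params: ParameterSet, blq_policy: str = "discard") -> float:
    """Gaussian log-likelihood of log(obs) around log(pred); BLQ records
    contribute their censoring probability under the M3 policy."""
    v_milk = milk_compartment_volume(subj.infant_weight, 10.0, 0.15)
    pred = _predict(subj, ip, params, v_milk)
    quant = subj.blq == 0
    if np.any(pred[quant] <= 0):
        return -np.inf
    lp = np.log(pred[quant])
    s2 = subj.sigma2[quant]
    ll = float(np.sum(-0.5 * (np.log(2 * np.pi * s2)
                              + (subj.log_dv[quant] - lp) ** 2 / s2)))
    if blq_policy == "m3" and np.any(~quant):
        pb = pred[~quant]
        pos = pb > 0  # a zero prediction is censored with certainty
        z = (subj.log_lloq[~quant][pos] - np.log(pb[pos])) \
            / np.sqrt(subj.sigma2[~quant][pos])
        ll += float(np.sum(stats.norm.logcdf(z)))
    return ll


def _make_ip(params: ParameterSet, theta: dict, eta: np.ndarray,
             eta_names: tuple, weight: float) -> IndividualParams:
    vals = {k: theta.get(k, getattr(params, k))
            for k in ("F", "MTT", "FM", "CL_PQ", "V_PQ", "CL_CPQ", "V_CPQ",
                      "Q", "CF_PQ", "CF_CPQ", "PC_PQ", "PC_CPQ")}
    for name, e in zip(eta_names, eta):
        vals[name] = vals[name] * math.exp(e)
    wr = weight / params.ref_weight
    acl = wr ** params.alloCL_exp
    av = wr ** params.alloV_exp
    return IndividualParams(
        f=vals["F"], mtt=vals["MTT"], fm=min(vals["FM"], 0.999),
        cl_pq=vals["CL_PQ"] * acl, v_pq=vals["V_PQ"] * av,
        cl_cpq=vals["CL_CPQ"] * acl, v_cpq=vals["V_CPQ"] * av,
        cf_pq=vals["CF_PQ"], cf_cpq=vals["CF_CPQ"], q=vals["Q"] * acl,
        pc_pq=vals["PC_PQ"], pc_cpq=vals["PC_CPQ"],
        n_transit=params.n_transit)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    estimates: dict
    ofv: float
    converged: bool
    method: str
    n_subjects: int
    omega: dict = field(default_factory=dict)
    sigma: dict = field(default_factory=dict)
    etas: dict = field(default_factory=dict)   # empirical-Bayes modes per subject
    message: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.ofv):
            raise ValueError("OFV must be finite at the reported optimum")


_LOGIT_PARAMS = {"FM", "PC_PQ", "PC_CPQ"}


def _to_internal(name: str, x: float) -> float:
    if name in _LOGIT_PARAMS:
        return math.log(x / (1.0 - x))
    return math.log(x)


def _from_internal(name: str, z: float) -> float:
    if name in _LOGIT_PARAMS:
        return 1.0 / (1.0 + math.exp(-z))
    return math.exp(z)


def fit_population(dataset: PKDataset, init: ParameterSet,
                   method: str = "laplace",
                   estimate: tuple = FIT_PARAMS_DEFAULT,
                   eta_names: tuple | None = None,
                   blq_policy: str = "discard",
                   maxiter: int = 400,
                   xatol: float = 2e-3,
                   fatol: float = 0.1) -> FitResult:
    """Maximise the (marginal) likelihood over the selected fixed effects.

    Variance components (omega, sigma) are taken from ``init`` and held
    fixed; ``eta_names`` selects the random effects marginalised by the
    Laplace approximation (defaults to the estimated parameters that carry
    IIV in ``init``).  Deterministic given data and starting values.
    """
    if method not in ("laplace", "naive_pooled"):
        raise ValueError("method must be 'laplace' or 'naive_pooled'")
    subjects = prepare_subjects(dataset, init, blq_policy)
    if not subjects:
        raise ValueError("dataset contains no maternal subjects")
    if eta_names is None:
        eta_names = tuple(p for p in estimate if init.omega.get(p, 0.0) > 0)
    omega_d = np.array([init.omega.get(p, 0.0) for p in eta_names])
    if method == "laplace" and (len(eta_names) == 0 or np.all(omega_d < 1e-12)):
        method = "naive_pooled"          # degenerate: no random effects left
    d = len(eta_names)
    warm: dict[int, np.ndarray] = {s.id: np.zeros(d) for s in subjects}

    def theta_of(x: np.ndarray) -> dict:
        return {n: _from_internal(n, z) for n, z in zip(estimate, x)}

    def pooled_obj(x: np.ndarray) -> float:
        th = theta_of(x)
        ll = 0.0
        for s in subjects:
            ip = _make_ip(init, th, np.zeros(0), (), s.weight)
            ll += subject_loglik(s, ip, init, blq_policy)
        return -2.0 * ll

    omega_inv = 1.0 / omega_d if d else np.zeros(0)
    log_det_omega = float(np.sum(np.log(omega_d))) if d else 0.0

    def _residuals(s: SubjectRecords, th: dict, eta: np.ndarray):
        """Standardised log-scale residuals of the quantifiable records."""
        ip = _make_ip(init, th, eta, eta_names, s.weight)
        v_milk = milk_compartment_volume(s.infant_weight, 10.0, 0.15)
        pred = _predict(s, ip, init, v_milk)
        quant = s.blq == 0
        if np.any(pred[quant] <= 0):
            return None
        return (s.log_dv[quant] - np.log(pred[quant])) / np.sqrt(s.sigma2[quant])

    def laplace_subject(s: SubjectRecords, th: dict) -> float:
        """Laplace-approximated marginal log-likelihood for one subject.

        The conditional mode is found by damped Gauss-Newton on the penalised
        least-squares objective; the Gauss-Newton information J'J + Omega^-1
        also serves as the Hessian in the Laplace determinant (the classical
        first-order-conditional approximation).
        """
        eta = warm[s.id].copy()
        r = _residuals(s, th, eta)
        if r is None:
            eta = np.zeros(d)
            r = _residuals(s, th, eta)
            if r is None:
                return -5e5
        obj = 0.5 * float(r @ r) + 0.5 * float(eta ** 2 @ omega_inv)
        A = None
        h = 1e-4
        for _ in range(8):
            J = np.empty((r.size, d))
            for k in range(d):
                ek = np.zeros(d); ek[k] = h
                rk = _residuals(s, th, eta + ek)
                if rk is None:
                    return -5e5
                J[:, k] = (rk - r) / h
            A = J.T @ J + np.diag(omega_inv)
            grad = J.T @ r + omega_inv * eta
            step = -np.linalg.solve(A, grad)
            if np.max(np.abs(step)) < 1e-4:
                break
            # damped update
            lam = 1.0
            for _ in range(6):
                eta_new = eta + lam * step
                r_new = _residuals(s, th, eta_new)
                if r_new is not None:
                    obj_new = (0.5 * float(r_new @ r_new)
                               + 0.5 * float(eta_new ** 2 @ omega_inv))
                    if obj_new <= obj + 1e-12:
                        eta, r, obj = eta_new, r_new, obj_new
                        break
                lam *= 0.5
            else:
                break
        warm[s.id] = eta
        quant = s.blq == 0
        const = -0.5 * float(np.sum(np.log(2 * np.pi * s.sigma2[quant])))
        ll = const - 0.5 * float(r @ r)
        sign, logdet_h = np.linalg.slogdet(A)
        if sign <= 0:
            logdet_h = float(np.sum(np.log(omega_inv)))
        return (ll - 0.5 * float(eta ** 2 @ omega_inv)
                - 0.5 * log_det_omega - 0.5 * logdet_h)

    def laplace_subject_generic(s: SubjectRecords, th: dict) -> float:
        """BFGS + finite-difference Hessian fallback (used with the M3
        censored-likelihood policy, where the objective is not least squares)."""
        def g(eta: np.ndarray) -> float:
            ip = _make_ip(init, th, eta, eta_names, s.weight)
            ll = subject_loglik(s, ip, init, blq_policy)
            if not np.isfinite(ll):
                return 1e12
            return -ll + 0.5 * float(np.sum(eta ** 2 / omega_d))
        res_in = optimize.minimize(g, warm[s.id], method="BFGS",
                                   options={"gtol": 1e-4, "maxiter": 60})
        eta_hat = res_in.x
        warm[s.id] = eta_hat
        H = _fd_hessian(g, eta_hat)
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            logdet_h = float(np.sum(np.log(1.0 / omega_d)))
        return -g(eta_hat) - 0.5 * log_det_omega - 0.5 * logdet_h

    per_subject = (laplace_subject if blq_policy == "discard"
                   else laplace_subject_generic)

    def laplace_obj(x: np.ndarray) -> float:
        th = theta_of(x)
        return -2.0 * sum(per_subject(s, th) for s in subjects)

    obj = pooled_obj if method == "naive_pooled" else laplace_obj
    x0 = np.array([_to_internal(n, getattr(init, n)) for n in estimate])
    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": xatol,
                                     "fatol": fatol, "adaptive": True})
    th = theta_of(res.x)
    etas = {s.id: warm[s.id].copy() for s in subjects} if method == "laplace" else {}
    return FitResult(estimates=th, ofv=float(res.fun), converged=bool(res.success),
                     method=method, n_subjects=len(subjects),
                     omega={n: float(v) for n, v in zip(eta_names, omega_d)},
                     sigma=dict(init.sigma), etas=etas, message=res.message)


def _fd_hessian(f, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    f0 = f(x)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (f(x + ei + ej) - fp[i] - fp[j] + f0
                                 + f0 - fm[i] - fm[j] + f(x - ei - ej)) / (2 * h ** 2)
    return H


def conditional_objective(subj: SubjectRecords, params: ParameterSet,
                          theta: dict, eta: np.ndarray, eta_names: tuple,
                          blq_policy: str = "discard") -> float:
    """Penalised negative log-likelihood -ll(y|eta) + 0.5 eta' Omega^-1 eta.

    The empirical-Bayes eta of a converged fit minimises this for each
    subject, which the tests verify against arbitrary alternatives.
    """
    omega_d = np.array([params.omega[n] for n in eta_names])
    ip = _make_ip(params, theta, np.asarray(eta, dtype=float), eta_names,
                  subj.weight)
    ll = subject_loglik(subj, ip, params, blq_policy)
    if not np.isfinite(ll):
        return np.inf
    return -ll + 0.5 * float(np.sum(np.asarray(eta) ** 2 / omega_d))


def evaluate_ofv(dataset: PKDataset, params: ParameterSet,
                 theta: dict | None = None,
                 etas: dict | None = None,
                 blq_policy: str = "discard") -> float:
    """-2 log-likelihood at fixed parameter values (etas optional per id)."""
    subjects = prepare_subjects(dataset, params, blq_policy)
    th = theta or {}
    ll = 0.0
    for s in subjects:
        eta_map = (etas or {}).get(s.id, {})
        names = tuple(eta_map)
        e = np.array([eta_map[n] for n in names])
        ip = _make_ip(params, th, e, names, s.weight)
        ll += subject_loglik(s, ip, params, blq_policy)
    return -2.0 * ll


# ---------------------------------------------------------------------------
# model comparison and variability conversion

OFV_THRESHOLDS = {0.05: 3.84, 0.01: 6.63, 0.001: 10.83}


def ofv_test(delta_ofv: float, df: int = 1) -> dict:
    """Chi-square significance of an OFV drop between nested models.

    ``delta_ofv`` is the change (larger minus smaller model); a drop greater
    than 3.84 / 6.63 / 10.83 is significant at p < 0.05 / 0.01 / 0.001 for
    one degree of freedom.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    drop = max(-float(delta_ofv), 0.0)
    p = float(stats.chi2.sf(drop, df))
    return {"drop": drop, "df": df, "p_value": p,
            "significant_0.05": p < 0.05,
            "significant_0.01": p < 0.01,
            "significant_0.001": p < 0.001}


def cv_from_variance(omega_sq: float) -> float:
    """%CV of a lognormal random effect from its variance:
    100 x sqrt(exp(omega^2) - 1)."""
    if omega_sq < 0:
        raise ValueError("variance must be >= 0")
    return 100.0 * math.sqrt(math.exp(omega_sq) - 1.0)


# ---------------------------------------------------------------------------
# prediction-corrected visual predictive check

@dataclass
class VPCResult:
    table: pd.DataFrame       # one row per (analyte, matrix, bin)
    n_sim: int
    observations: pd.DataFrame | None = None   # records with PRED and PCDV

    def coverage(self, percentiles=(5, 50, 95)) -> float:
        """Fraction of observed percentile points inside their simulated 95 %
        confidence bands."""
        hits, total = 0, 0
        for p in percentiles:
            lo = self.table[f"sim_lo_{p}"]
            hi = self.table[f"sim_hi_{p}"]
            ob = self.table[f"obs_p{p}"]
            ok = ob.notna()
            hits += int(np.sum((ob[ok] >= lo[ok]) & (ob[ok] <= hi[ok])))
            total += int(ok.sum())
        return hits / total if total else float("nan")


def pc_vpc(dataset: PKDataset, params: ParameterSet, n_sim: int = 1000,
           bins: dict | None = None, seed: int = 0,
           feeding: FeedingPattern | None = None) -> VPCResult:
    """Prediction-corrected VPC of the maternal model.

    Observations and simulated replicates are scaled by (bin-median population
    prediction / record population prediction); observed 5th/50th/95th
    percentiles per bin are compared with the 95 % band of the same
    percentiles across ``n_sim`` simulated datasets.  Bins default to the
    nominal sampling times per analyte x matrix.  BLQ records are excluded.
    """
    from .popsim import draw_population  # local import avoids a cycle
    feeding = feeding if feeding is not None else FeedingPattern()
    rng = np.random.default_rng(seed)
    obs = dataset.observations(role="mother", drop_blq=True).copy()
    if obs.empty:
        raise ValueError("no quantifiable maternal observations")
    doses = dataset.df[(dataset.df.EVID == 1) & (dataset.df.ROLE == "mother")]

    # population prediction (eta = kappa = 0) per record
    preds = np.empty(len(obs))
    sim_cache: dict[int, dict] = {}
    from .model_core import DosingRegimen
    from .mother import simulate_mother as _sim
    for sid, g in obs.groupby("ID"):
        dsub = doses[doses.ID == sid]
        interval = float(np.median(np.diff(np.sort(dsub.TIME)))) if len(dsub) > 1 else 24.0
        reg = DosingRegimen(float(dsub.AMT.iloc[0] / g.WT.iloc[0]), interval,
                            len(dsub))
        subj = MotherSubject(id=int(sid), weight=float(g.WT.iloc[0]),
                             infant_weight=float(g.IWT.iloc[0]))
        t_out = np.unique(g.TIME.to_numpy(dtype=float))
        r = _sim(subj, params, reg, feeding, t_out=t_out)
        sim_cache[sid] = {"reg": reg, "subj": subj, "t": t_out, "res": r}
        for (an, mx), gg in g.groupby(["ANALYTE", "MATRIX"]):
            c = r.concentrations(an, mx)
            preds[obs.index.get_indexer(gg.index)] = np.interp(
                gg.TIME.to_numpy(dtype=float), t_out, c)
    obs["PRED"] = preds
    obs = obs[obs.PRED > 0]
    obs["BIN"] = list(zip(obs.ANALYTE, obs.MATRIX, obs.TIME))
    bin_median = obs.groupby("BIN").PRED.median()
    obs["PCDV"] = obs.DV * obs.BIN.map(bin_median) / obs.PRED

    # simulate replicates at the observed design
    pcs = np.empty((n_sim, len(obs)))
    tix = {sid: obs[obs.ID == sid] for sid in sim_cache}
    for k in range(n_sim):
        vals = np.empty(len(obs))
        pop = draw_population(params, len(sim_cache), 51.0, rng)  # etas only
        for subj_rnd, (sid, cache) in zip(pop, sim_cache.items()):
            s = MotherSubject(id=sid, weight=cache["subj"].weight,
                              infant_weight=cache["subj"].infant_weight,
                              eta=subj_rnd.eta, kappa=subj_rnd.kappa)
            r = _sim(s, params, cache["reg"], feeding, t_out=cache["t"])
            g = tix[sid]
            for (an, mx), gg in g.groupby(["ANALYTE", "MATRIX"]):
                c = np.interp(gg.TIME.to_numpy(dtype=float), cache["t"],
                              r.concentrations(an, mx))
                sd = np.sqrt(params.sigma[f"{an}:{mx}"])
                c = c * np.exp(rng.normal(0.0, sd, size=c.size))
                vals[obs.index.get_indexer(gg.index)] = c
        pcs[k] = vals * obs.BIN.map(bin_median).to_numpy() / obs.PRED.to_numpy()

    rows = []
    for b, g in obs.groupby("BIN"):
        ix = obs.index.get_indexer(g.index)
        row = {"analyte": b[0], "matrix": b[1], "time": b[2], "n_obs": len(g)}
        sims = pcs[:, ix]
        for p in (5, 50, 95):
            row[f"obs_p{p}"] = float(np.percentile(g.PCDV, p))
            sp = np.percentile(sims, p, axis=1)
            row[f"sim_lo_{p}"] = float(np.percentile(sp, 2.5))
            row[f"sim_hi_{p}"] = float(np.percentile(sp, 97.5))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(["analyte", "matrix", "time"])
    return VPCResult(table=table.reset_index(drop=True), n_sim=n_sim,
                     observations=obs)
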