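"""Study-like synthetic clinical datasets.

The trial design being emulated: 21 breastfeeding mothers (35-81 kg) on
0.5 mg base/kg once daily for 14 days, with dense venous sampling on days 0
and 13, sparse sampling on days 3 and 7, capillary and breast-milk sampling,
and infant capillary sampling timed to the first breastfeed after the
maternal dose.  Residual error is additive on the log scale per analyte and
matrix, and observations are censored at the assay LLOQ.

Datasets use NONMEM-convention long format (ID, TIME, AMT, DV, EVID, MDV,
CMT, BLQ, LLOQ, WT, OCC ...) so they interoperate with pharmacometric tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .infant import InfantSubject, simulate_pair
from .model_core import DosingRegimen, FeedingPattern, ParameterSet
from .mother import MotherSubject, simulate_mother
from .popsim import draw_population, infant_weight_for_age, uniform_weight

__all__ = ["PKDataset", "study_schedule", "generate_study_dataset",
           "lloq_substitute", "LLOQ", "CMT_CODES"]

#: assay lower limits of quantification (ng/mL)
LLOQ = {
    ("PQ", "venous"): 1.14, ("CPQ", "venous"): 4.88,
    ("PQ", "capillary"): 1.14, ("CPQ", "capillary"): 4.88,
    ("PQ", "milk"): 1.14, ("CPQ", "milk"): 4.88,
    ("PQ", "infant_capillary"): 1.82, ("CPQ", "infant_capillary"): 7.81,
}

CMT_CODES = {"depot": 1, ("PQ", "venous"): 2, ("CPQ", "venous"): 3,
             ("PQ", "capillary"): 2, ("CPQ", "capillary"): 3,
             ("PQ", "milk"): 4, ("CPQ", "milk"): 5,
             ("PQ", "infant_capillary"): 6, ("CPQ", "infant_capillary"): 7}

COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "CMT", "ANALYTE",
           "MATRIX", "BLQ", "LLOQ", "WT", "IWT", "OCC", "ROLE"]

_DENSE = [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0]
_MILK_WINDOW_MID = [2.0, 5.0, 9.5, 18.0]   # midpoints of 1-3, 3-7, 7-12, 12-24 h


@dataclass
class PKDataset:
    """Long-format dose/observation records with BLQ flags."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        obs = self.df[self.df.EVID == 0]
        if obs["ANALYTE"].isna().any() or obs["MATRIX"].isna().any():
            raise ValueError("every observation needs analyte and matrix")
        if (self.df.TIME < 0).any():
            raise ValueError("negative times")
        blq = obs[obs.BLQ == 1]
        if blq["DV"].notna().any():
            raise ValueError("BLQ records must not carry a DV value")

    def observations(self, role: str | None = None,
                     drop_blq: bool = False) -> pd.DataFrame:
        d = self.df[self.df.EVID == 0]
        if role is not None:
            d = d[d.ROLE == role]
        if drop_blq:
            d = d[d.BLQ == 0]
        return d

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PKDataset":
        df = pd.read_csv(path, dtype={"ANALYTE": "string", "MATRIX": "string",
                                      "ROLE": "string"})
        df["ANALYTE"] = df["ANALYTE"].astype(object).where(df["ANALYTE"].notna(), None)
        df["MATRIX"] = df["MATRIX"].astype(object).where(df["MATRIX"].notna(), None)
        df["ROLE"] = df["ROLE"].astype(object)
        return cls(df)


def study_schedule(dose_days: tuple = (0, 3, 7, 13),
                   feeding: FeedingPattern | None = None) -> dict:
    """Planned sampling times (h after first dose) per matrix.

    Per mother: 28 venous, 8 capillary and 10 breast-milk samples (milk
    windows are sampled at their midpoints); per infant 11 capillary samples
    relative to the first breastfeed after the maternal dose.
    """
    feeding = feeding if feeding is not None else FeedingPattern()
    d0, d3, d7, d13 = (24.0 * d for d in dose_days)
    venous = ([d0 + t for t in _DENSE] + [d3, d3 + 2.0, d7, d7 + 2.0]
              + [d13 + t for t in _DENSE])
    capillary = [d + t for d in (d0, d13) for t in (0.0, 2.0, 6.0, 12.0)]
    milk = ([d0 + t for t in _MILK_WINDOW_MID] + [d3 + 2.0, d7 + 2.0]
            + [d13 + t for t in _MILK_WINDOW_MID])

    def first_feed_after(t: float) -> float:
        tc = feeding.t_cycle
        k = np.ceil((t - feeding.first_feed_offset_h) / tc)
        return feeding.first_feed_offset_h + k * tc

    inf = ([first_feed_after(d0) + t for t in (0.0, 2.0, 6.0)]
           + [first_feed_after(d3) + t for t in (0.0, 2.0)]
           + [first_feed_after(d7) + t for t in (0.0, 2.0)]
           + [first_feed_after(d13) + t for t in (0.0, 2.0, 6.0, 24.0)])
    return {"venous": sorted(venous), "capillary": sorted(capillary),
            "milk": sorted(milk), "infant_capillary": sorted(inf)}


def _occ_at(t: float, starts=(0.0, 72.0, 168.0, 312.0)) -> int:
    return max(int(np.searchsorted(starts, t, side="right")) - 1, 0)


def generate_study_dataset(params: ParameterSet, n_mothers: int = 21,
                           seed: int = 0,
                           regimen: DosingRegimen | None = None,
                           feeding: FeedingPattern | None = None,
                           sigma_scale: float = 1.0,
                           lloq: dict | None = None,
                           include_infants: bool = True,
                           iiv: bool = True,
                           weight_range: tuple[float, float] = (35.0, 81.0)) -> PKDataset:
    """Simulate a full study-like dataset with residual error and censoring.

    ``sigma_scale=0`` gives a noise-free dataset equal to the model
    predictions; ``lloq={}`` disables censoring; ``iiv=False`` zeroes all
    random effects (typical-subject data).
    """
    regimen = regimen if regimen is not None else DosingRegimen(0.5, 24.0, 14, "standard")
    feeding = feeding if feeding is not None else FeedingPattern()
    lloq = LLOQ if lloq is None else lloq
    rng = np.random.default_rng(seed)
    p = params if iiv else params.replace(
        omega={k: 0.0 for k in params.omega}, pi={k: 0.0 for k in params.pi})
    sampler = (float(weight_range[0]) if weight_range[0] == weight_range[1]
               else uniform_weight(*weight_range))
    mothers = draw_population(p, n_mothers, sampler, rng)
    sched = study_schedule(feeding=feeding)
    # infant covariates drawn up front so datasets differing only in the
    # residual-noise settings share the same virtual subjects
    ages = rng.uniform(1.0, 22.0, size=n_mothers)
    zs = np.clip(rng.normal(size=n_mothers), -3, 3)
    rows = []
    for m, age_mo, z in zip(mothers, ages, zs):
        infant = InfantSubject(id=m.id,
                               weight=infant_weight_for_age(float(age_mo), float(z)),
                               age_months=float(age_mo), mother_id=m.id)
        m.infant_weight = infant.weight
        base = {"WT": m.weight, "IWT": infant.weight}
        for td in regimen.dose_times():
            rows.append({"ID": m.id, "TIME": float(td),
                         "AMT": regimen.dose_mg_base_per_kg * m.weight,
                         "DV": np.nan, "EVID": 1, "MDV": 1,
                         "CMT": CMT_CODES["depot"], "ANALYTE": None,
                         "MATRIX": None, "BLQ": 0, "LLOQ": np.nan,
                         "OCC": _occ_at(td), "ROLE": "mother", **base})
        t_mother = np.unique(np.concatenate(
            [sched["venous"], sched["capillary"], sched["milk"],
             regimen.dose_times()]))
        res_m = simulate_mother(m, params, regimen, feeding, t_out=t_mother)
        res_i = None
        if include_infants:
            t_inf = np.unique(np.asarray(sched["infant_capillary"]))
            res_i = simulate_pair(m, infant, params, regimen, feeding,
                                  t_out=t_inf)
        for matrix in ("venous", "capillary", "milk", "infant_capillary"):
            if matrix == "infant_capillary" and res_i is None:
                continue
            res = res_i if matrix == "infant_capillary" else res_m
            role = "infant" if matrix == "infant_capillary" else "mother"
            rid = m.id if role == "mother" else m.id + 1000
            for analyte in ("PQ", "CPQ"):
                sig_key = f"{analyte}:{'capillary' if matrix == 'infant_capillary' else matrix}"
                sd = np.sqrt(params.sigma[sig_key]) * sigma_scale
                pred = np.interp(sched[matrix], res.t,
                                 res.concentrations(analyte, matrix))
                for t, c in zip(sched[matrix], pred):
                    dv = c * float(np.exp(rng.normal(0.0, sd))) if (c > 0 and sd > 0) else c
                    lq = lloq.get((analyte, matrix), 0.0)
                    blq = int(dv < lq)
                    rows.append({"ID": rid, "TIME": float(t),
                                 "AMT": np.nan,
                                 "DV": np.nan if blq else float(dv),
                                 "EVID": 0, "MDV": blq,
                                 "CMT": CMT_CODES[(analyte, matrix)],
                                 "ANALYTE": analyte, "MATRIX": matrix,
                                 "BLQ": blq, "LLOQ": lq,
                                 "OCC": _occ_at(t), "ROLE": role, **base})
    df = pd.DataFrame(rows, columns=COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return PKDataset(df)


def lloq_substitute(value: float, blq: bool, lloq: float) -> float:
    """Half-LLOQ substitution for visualisation of censored records."""
    return lloq / 2.0 if blq else value


def lloq_substitute_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorised half-LLOQ substitution over a dataset's observation rows."""
    return pd.Series(np.where(df["BLQ"] == 1, df["LLOQ"] / 2.0, df["DV"]),
                     index=df.index)
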