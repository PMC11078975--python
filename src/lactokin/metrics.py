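"""Infant-dose exposure metrics: milk-to-plasma ratio, total infant daily
dose, relative infant dose, and threshold comparisons.

Total infant daily dose (µg/kg) =
    (AUC_milk / AUC_venous) x C_ss,average (µg/mL) x 150 (mL/kg),
with both AUCs taken over 0-24 h after the last maternal dose, and the
steady-state average concentration defined as AUC_venous over that window
divided by 24 h (for a single dose the same 0-24 h window is used).
Relative infant dose (%) = infant dose (mg/kg) / maternal dose (mg/kg) x 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mother import ConcentrationSeries, SimResult

__all__ = ["ExposureSummary", "total_infant_daily_dose",
           "relative_infant_dose", "css_average", "milk_plasma_ratio",
           "threshold_compare", "mother_exposure_summary"]

MILK_INTAKE_ML_PER_KG = 150.0


def steady_state_window(regimen) -> tuple[float, float]:
    """The 24-h AUC window of the dose-metric chain.

    For once-daily (or sparser) dosing this is 0-24 h after the last dose; for
    more frequent dosing it is the last full dosing day, so that the window
    reflects steady-state dosing rather than a part-day washout.
    """
    end = regimen.last_dose_time + min(regimen.interval_h, 24.0)
    return (max(0.0, end - 24.0), end)


@dataclass
class ExposureSummary:
    auc_milk: float                  # µg·h/mL
    auc_venous: float                # µg·h/mL
    c_ss_average: float              # µg/mL
    milk_plasma_ratio: float
    total_infant_daily_dose: float   # µg/kg
    relative_infant_dose: float      # %
    mother_cmax: float = np.nan      # ng/mL
    mother_tmax: float = np.nan      # h

    def __post_init__(self) -> None:
        for f in ("auc_milk", "auc_venous", "c_ss_average",
                  "total_infant_daily_dose", "relative_infant_dose"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def total_infant_daily_dose(auc_milk: float, auc_venous: float,
                            c_ss_avg: float,
                            intake_ml_per_kg: float = MILK_INTAKE_ML_PER_KG) -> float:
    """µg/kg of drug ingested by the infant per day via breast milk."""
    if auc_venous <= 0:
        raise ValueError("venous AUC must be positive")
    return (auc_milk / auc_venous) * c_ss_avg * intake_ml_per_kg


def relative_infant_dose(infant_dose_mg_kg: float,
                         maternal_dose_mg_kg: float) -> float:
    """Infant weight-adjusted dose as a percentage of the maternal one."""
    if maternal_dose_mg_kg <= 0:
        raise ValueError("maternal dose must be positive")
    return infant_dose_mg_kg / maternal_dose_mg_kg * 100.0


def css_average(auc_window_ng_h_ml: float, interval_h: float = 24.0) -> float:
    """Average steady-state concentration (µg/mL) from a window AUC (ng·h/mL)."""
    if interval_h <= 0:
        raise ValueError("interval must be positive")
    return auc_window_ng_h_ml / 1000.0 / interval_h


def milk_plasma_ratio(auc_milk: float, auc_venous: float) -> float:
    if auc_venous <= 0:
        raise ValueError("venous AUC must be positive")
    return auc_milk / auc_venous


def mother_exposure_summary(res: SimResult, regimen,
                            intake_ml_per_kg: float = MILK_INTAKE_ML_PER_KG,
                            analyte: str = "PQ") -> ExposureSummary:
    """Milk:plasma ratio, steady-state average concentration, total infant
    daily dose and relative infant dose for one simulated mother."""
    window = steady_state_window(regimen)
    auc_v = res.auc(analyte, "venous", window)     # ng·h/mL
    auc_m = res.auc(analyte, "milk", window)
    c_ss = css_average(auc_v, 24.0)
    tidd = total_infant_daily_dose(auc_m / 1000.0, auc_v / 1000.0, c_ss,
                                   intake_ml_per_kg)
    rid = relative_infant_dose(tidd / 1000.0, regimen.daily_dose_mg_per_kg())
    ven = res.series(analyte, "venous")
    m = (ven.times >= window[0]) & (ven.times <= window[1])
    sub = ConcentrationSeries(analyte, "venous", ven.times[m], ven.conc[m])
    imax = int(np.argmax(sub.conc))
    return ExposureSummary(
        auc_milk=auc_m / 1000.0,
        auc_venous=auc_v / 1000.0,
        c_ss_average=c_ss,
        milk_plasma_ratio=milk_plasma_ratio(auc_m, auc_v),
        total_infant_daily_dose=tidd,
        relative_infant_dose=rid,
        mother_cmax=float(sub.conc[imax]),
        mother_tmax=float(sub.times[imax] - window[0]),
    )


def threshold_compare(exposures: pd.DataFrame, reference_cmax: float,
                      reference_auc: float,
                      cmax_col: str = "infant_cmax_PQ",
                      auc_col: str = "infant_auc24_PQ") -> dict:
    """Flag per-infant exposures against a reference (e.g. the maternal
    single-low-dose medians) and report the fraction below."""
    below_cmax = exposures[cmax_col].to_numpy() < reference_cmax
    below_auc = exposures[auc_col].to_numpy() < reference_auc
    return {
        "fraction_below_cmax": float(np.mean(below_cmax)) if len(exposures) else 0.0,
        "fraction_below_auc": float(np.mean(below_auc)) if len(exposures) else 0.0,
        "all_below": bool(np.all(below_cmax & below_auc)) if len(exposures) else False,
        "below_cmax": below_cmax,
        "below_auc": below_auc,
    }
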