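"""Non-carcinogenic (HQ/HI) and carcinogenic (CDI/LTCR) risk metrics.

The internal EDI unit is ng/kg/day everywhere in this package; the unit
conversions the risk formulas need (ng -> ug for HQ against an RfD in
ug/kg/day, ng -> mg for the cancer slope factor in (mg/kg/day)^-1) happen
only inside these functions, because exposure literature routinely mixes
all three scales.

* HQ = EDI / RfD (dimensionless); HI sums the HQs of analytes assumed to
  act additively — here by default benzophenone (BP), 4-methylbenzophenone
  (4-MBP) and benzophenone-3 (BP-3), the congeners with shared mode of
  action and adequate detection frequency.  HI < 1 reads as negligible
  non-carcinogenic concern.
* CDI = EDI x ED x EF / AT averages intake over a lifetime (exposure
  duration in years, frequency in days/year, averaging time in days);
  LTCR = CDI x CSF, conventionally acceptable within 1e-6 .. 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .exposure import AGE_GROUPS, EdiDraws, percentile

__all__ = [
    "RiskConstants",
    "RiskSummary",
    "hazard_quotient",
    "hazard_index",
    "chronic_daily_intake",
    "lifetime_cancer_risk",
    "classify_ltcr",
    "classify_hi",
    "ltcr_table",
]

NG_PER_UG = 1_000.0
NG_PER_MG = 1_000_000.0

#: conventional acceptability band for lifetime cancer risk
LTCR_ACCEPTABLE = (1e-6, 1e-4)


def _default_rfd() -> dict[str, float]:
    return {"BP": 30.0, "4-MBP": 30.0, "BP-3": 100.0}


def _default_ed() -> dict[str, float]:
    return {"0-3": 2.0, "3-6": 6.0, "6-12": 12.0, "12-16": 16.0, "16-18": 18.0, "19-65": 65.0, ">65": 70.0}


@dataclass(frozen=True)
class RiskConstants:
    """Toxicological and exposure constants.

    ``rfd``: oral reference dose per analyte, ug/kg/day.  ``csf``: cancer
    slope factor, (mg/kg/day)^-1 (benzophenone: 4.8e-3).  ``ef``: exposure
    frequency, days/year.  ``at_days``: averaging time, 70 y x 365 d.
    ``ed_years``: exposure duration per age group; the >65 group uses 70 y
    as conventionally tabulated (it overlaps the 19-65 group's 65 and is
    kept as-is, uncorrected).  ``hi_components`` lists the analytes summed
    into the hazard index.
    """

    rfd: dict[str, float] = field(default_factory=_default_rfd)
    csf: float = 4.8e-3
    ef: float = 365.0
    at_days: float = 25_550.0
    ed_years: dict[str, float] = field(default_factory=_default_ed)
    hi_components: tuple[str, ...] = ("BP", "4-MBP", "BP-3")


@dataclass(frozen=True)
class RiskSummary:
    """Mean and high-percentile risk metrics for one age group."""

    age_group: str
    hq: dict[str, tuple[float, float]]
    hi: tuple[float, float]
    ltcr: tuple[float, float] | None
    percentile_level: float = 0.975


def hazard_quotient(edi, rfd: float):
    """HQ = EDI/RfD with EDI in ng/kg/day and RfD in ug/kg/day.

    Accepts a scalar, an array of draws or an :class:`EdiDraws`; returns
    the same shape (draws stay draws).
    """
    if rfd <= 0:
        raise ValidationError(f"rfd must be positive, got {rfd}")
    values = edi.values if isinstance(edi, EdiDraws) else np.asarray(edi, dtype=float)
    if np.any(values < 0):
        raise ValidationError("EDI must be nonnegative")
    hq = (values / NG_PER_UG) / rfd
    if not isinstance(edi, EdiDraws) and np.ndim(edi) == 0:
        return float(hq)
    return hq


def hazard_index(hqs: list[np.ndarray]) -> np.ndarray:
    """Draw-wise sum of hazard-quotient vectors (additive mixture)."""
    if not hqs:
        raise ValidationError("need at least one HQ component")
    arrs = [np.atleast_1d(np.asarray(h, dtype=float)) for h in hqs]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValidationError("HQ components must have equal length")
    return np.sum(arrs, axis=0)


def chronic_daily_intake(edi_mg: float, ed_years: float, ef: float = 365.0, at_days: float = 25_550.0) -> float:
    """CDI = EDI x ED x EF / AT, all intakes in mg/kg/day."""
    if ed_years <= 0 or ef <= 0 or at_days <= 0:
        raise ValidationError("ed_years, ef and at_days must be positive")
    return float(edi_mg * ed_years * ef / at_days)


def lifetime_cancer_risk(cdi_mg: float, csf: float = 4.8e-3) -> float:
    """LTCR = CDI x CSF (dimensionless lifetime probability increment)."""
    if cdi_mg < 0:
        raise ValidationError("cdi must be nonnegative")
    return float(cdi_mg * csf)


def ltcr_from_edi_ng(edi_ng: float, ed_years: float, constants: RiskConstants = RiskConstants()) -> float:
    """LTCR from an EDI in the package's internal ng/kg/day unit."""
    cdi = chronic_daily_intake(edi_ng / NG_PER_MG, ed_years, constants.ef, constants.at_days)
    return lifetime_cancer_risk(cdi, constants.csf)


def classify_ltcr(ltcr: float) -> str:
    """Label against the conventional 1e-6..1e-4 acceptability band."""
    lo, hi = LTCR_ACCEPTABLE
    if ltcr < lo:
        return "below-concern"
    if ltcr <= hi:
        return "acceptable"
    return "above-acceptable"


def classify_hi(hi: float) -> str:
    return "negligible" if hi < 1.0 else "of-concern"


def ltcr_table(
    edi_mean_mg: dict[str, float],
    edi_p975_mg: dict[str, float],
    constants: RiskConstants = RiskConstants(),
) -> pd.DataFrame:
    """Lifetime-cancer-risk report: one column per age group.

    Inputs are the mean and P97.5 EDI per age group in mg/kg/day; rows
    mirror the conventional report layout (EDI, ED, EF, AT, LTCR).  The
    P97.5 LTCR is computed from the P97.5 EDI (the tabulated convention),
    not from the LTCR distribution's own quantile.
    """
    groups = [g for g in AGE_GROUPS if g in edi_mean_mg]
    rows: dict[str, list] = {
        "quantity": ["edi_mean_mg_kg_day", "edi_p975_mg_kg_day", "ed_years", "ef_days_year", "at_days", "ltcr_mean", "ltcr_p975", "classification_p975"],
    }
    for g in groups:
        ed = constants.ed_years[g]
        lt_mean = lifetime_cancer_risk(chronic_daily_intake(edi_mean_mg[g], ed, constants.ef, constants.at_days), constants.csf)
        lt_p = lifetime_cancer_risk(chronic_daily_intake(edi_p975_mg[g], ed, constants.ef, constants.at_days), constants.csf)
        rows[g] = [edi_mean_mg[g], edi_p975_mg[g], ed, constants.ef, constants.at_days, lt_mean, lt_p, classify_ltcr(lt_p)]
    return pd.DataFrame(rows)


def summarize_risk(
    age_group: str,
    hq_draws: dict[str, np.ndarray],
    ltcr_mean: float | None = None,
    ltcr_p975: float | None = None,
    p: float = 0.975,
) -> RiskSummary:
    """Bundle per-analyte HQ and HI (mean, P-quantile) for one age group."""
    hq_summary = {a: (float(np.mean(v)), percentile(np.asarray(v), p)) for a, v in hq_draws.items()}
    hi_draws = hazard_index(list(hq_draws.values()))
    hi = (float(hi_draws.mean()), percentile(hi_draws, p))
    ltcr = (ltcr_mean, ltcr_p975) if ltcr_mean is not None else None
    return RiskSummary(age_group=age_group, hq=hq_summary, hi=hi, ltcr=ltcr, percentile_level=p)
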