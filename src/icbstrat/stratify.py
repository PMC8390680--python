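"""Early-response stratification from ctDNA and tumor-burden dynamics.

Patients on anti-PD-1 therapy are classified by the joint sign of two early
percent changes from baseline: circulating tumor DNA level (ΔctDNA, measured
in mean tumor molecules per mL plasma at treatment cycle 2 or 3) and the sum
of RECIST target-lesion measurements (ΔTM, at week 9).  The four quadrants
define molecular-sensitivity groups:

====  =======  ====  =============================================
ΔctDNA  ΔTM    group  interpretation
====  =======  ====  =============================================
  +      +     LS     low sensitivity (both increase)
  −      −     HS     high sensitivity (both decrease)
  −      +     MSPP   mixed: potential pseudoprogression
  +      −     MSER   mixed: emerging resistance
====  =======  ====  =============================================

An "increase" is defined as strictly greater than zero; an exact zero change
is grouped with decrease (not an increase).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

GROUPS = ("LS", "HS", "MSPP", "MSER")
UNCLASSIFIED = "UNCLASSIFIED"

#: preferred on-treatment cycle labels, in order (6-7 week window)
ON_TREATMENT_CYCLES = ("C3", "C2")

#: duration of stable disease (weeks) that must be exceeded for clinical benefit
SD_BENEFIT_WEEKS = 18.0


@dataclass
class CtdnaSeries:
    """Longitudinal ctDNA levels for one patient (MTM per mL plasma)."""

    patient_id: str
    measurements: dict[str, float] = field(default_factory=dict)  # cycle -> mtm/mL

    def __post_init__(self) -> None:
        for cycle, v in self.measurements.items():
            if v < 0:
                raise ValueError(
                    f"{self.patient_id}: negative MTM/mL at {cycle}: {v}"
                )


@dataclass
class LesionSeries:
    """Target-lesion sum (mm) by week for one patient."""

    patient_id: str
    measurements: dict[int, float] = field(default_factory=dict)  # week -> mm


@dataclass
class SensitivityCall:
    patient_id: str
    delta_ctdna: float  # percent; NaN when magnitude undefined
    delta_tm: float  # percent; NaN when undefined
    group: str
    #: set when baseline ctDNA was 0 but the increase/no-increase rule applied
    ctdna_magnitude_undefined: bool = False


def compute_delta_ctdna(series: CtdnaSeries, on_cycle: str | None = None) -> float:
    """Percent change in ctDNA from baseline to the on-treatment cycle.

    Returns ``100 * (on - baseline) / baseline``.  When *on_cycle* is None the
    first available of C3 then C2 is used.  Returns NaN when either value is
    missing or baseline is 0 (magnitude undefined; see
    :func:`classify_sensitivity_from_series` for the sign-only rule).
    """
    base = series.measurements.get("baseline")
    if on_cycle is None:
        on = next(
            (series.measurements[c] for c in ON_TREATMENT_CYCLES
             if c in series.measurements),
            None,
        )
    else:
        on = series.measurements.get(on_cycle)
    if base is None or on is None:
        return math.nan
    if base == 0:
        return math.nan
    return 100.0 * (on - base) / base


def compute_delta_tm(series: LesionSeries, on_week: int = 9) -> float:
    """Percent change in target-lesion sum between baseline (week 0) and week 9."""
    base = series.measurements.get(0)
    on = series.measurements.get(on_week)
    if base is None or on is None:
        return math.nan
    if base <= 0:
        raise ValueError(f"{series.patient_id}: baseline lesion sum must be > 0")
    return 100.0 * (on - base) / base


def classify_sensitivity(delta_ctdna: float, delta_tm: float) -> str:
    """Quadrant group from the two percent changes.

    Exact zeros count as "not increased" and are grouped with decreases.
    Either input NaN yields ``UNCLASSIFIED``.
    """
    if math.isnan(delta_ctdna) or math.isnan(delta_tm):
        return UNCLASSIFIED
    ct_up = delta_ctdna > 0
    tm_up = delta_tm > 0
    if ct_up and tm_up:
        return "LS"
    if not ct_up and not tm_up:
        return "HS"
    if not ct_up and tm_up:
        return "MSPP"
    return "MSER"


def call_patient(
    ctdna: CtdnaSeries, lesions: LesionSeries, on_cycle: str | None = None
) -> SensitivityCall:
    """Full sensitivity call for one patient, handling the baseline-0 edge.

    A baseline ctDNA of exactly 0 leaves the percent magnitude undefined, but
    the increase/no-increase rule still applies: any on-treatment signal > 0 is
    an increase, 0 → 0 is undefined.
    """
    d_tm = compute_delta_tm(lesions)
    d_ct = compute_delta_ctdna(ctdna, on_cycle)
    mag_undef = False
    base = ctdna.measurements.get("baseline")
    if base == 0:
        on = next(
            (ctdna.measurements[c] for c in ON_TREATMENT_CYCLES
             if c in ctdna.measurements),
            None,
        ) if on_cycle is None else ctdna.measurements.get(on_cycle)
        if on is not None and on > 0:
            # increase of undefined magnitude: classify by sign only
            mag_undef = True
            group = classify_sensitivity(1.0, d_tm)
            return SensitivityCall(ctdna.patient_id, math.nan, d_tm, group, True)
    group = classify_sensitivity(d_ct, d_tm)
    return SensitivityCall(ctdna.patient_id, d_ct, d_tm, group, mag_undef)


def classify_clinical_benefit(
    best_overall_response: str, sd_duration_weeks: float = 0.0
) -> bool:
    """Clinical benefit: CR, PR, or SD sustained for more than 18 weeks."""
    r = best_overall_response.upper()
    if r in ("CR", "PR"):
        return True
    if r == "SD":
        return sd_duration_weeks > SD_BENEFIT_WEEKS
    if r == "NE":
        warnings.warn("best overall response NE treated as no clinical benefit")
    return False


def combine_strata(*labels: str | None) -> str | None:
    """Cross-product composite stratum, e.g. ``TMB-high & ΔctDNA<0``.

    Returns None (patient excluded) if any component is missing.
    """
    if any(lb is None or (isinstance(lb, float) and math.isnan(lb)) for lb in labels):
        return None
    return " & ".join(str(lb) for lb in labels)


def call_cohort(
    ctdna_df: pd.DataFrame,
    lesions_df: pd.DataFrame,
    on_cycle: str | None = None,
) -> pd.DataFrame:
    """Vectorised cohort-level calls from the long-format tables.

    ``ctdna_df`` needs columns patient_id, cycle, mtm_per_ml;
    ``lesions_df`` needs patient_id, week, target_lesion_sum_mm.
    Returns a frame with one row per patient appearing in both tables.
    """
    calls = []
    lesion_groups = {
        pid: LesionSeries(pid, dict(zip(g["week"].astype(int),
                                        g["target_lesion_sum_mm"])))
        for pid, g in lesions_df.groupby("patient_id")
    }
    for pid, g in ctdna_df.groupby("patient_id"):
        if pid not in lesion_groups:
            continue
        series = CtdnaSeries(pid, dict(zip(g["cycle"], g["mtm_per_ml"])))
        call = call_patient(series, lesion_groups[pid], on_cycle)
        calls.append(
            {
                "patient_id": pid,
                "delta_ctdna_pct": call.delta_ctdna,
                "delta_tm_pct": call.delta_tm,
                "group": call.group,
                "ctdna_magnitude_undefined": call.ctdna_magnitude_undefined,
            }
        )
    return pd.DataFrame(calls)
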