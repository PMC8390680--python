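"""Survival machinery: Kaplan-Meier, log-rank, univariate Cox, landmarking.

All stratified comparisons in the pipeline (sensitivity groups, TMB x ΔctDNA
strata, PGA tertiles, immune-score and cell-score splits) funnel through the
same small surface.  Estimation is delegated to lifelines: product-limit
curves from ``KaplanMeierFitter``, the standard observed-minus-expected
log-rank statistic, and Cox partial-likelihood maximization with Efron tie
handling.  Landmark analyses re-origin time at a post-baseline anchor
(treatment cycle 3) and drop patients without follow-up beyond it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

#: default significance threshold used in reported summaries
SIGNIFICANCE_P = 0.10


@dataclass
class CoxResult:
    hazard_ratio: float
    log_hr: float
    se_log_hr: float
    p_value: float  # Wald
    ci_low: float
    ci_high: float
    n: int
    n_events: int


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no survival records")
    if (records["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0/1")
    return records


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve with at-risk counts.

    ``records`` needs columns time_months and event.  Returns a frame with
    time, survival, n_at_risk; S(0) = 1 and steps occur at event times only.
    """
    _validate(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_months"], records["event"])
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index, "survival": surv.to_numpy(),
         "n_at_risk": at_risk.to_numpy()}
    ).reset_index(drop=True)


def logrank_test(records: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Log-rank chi-square statistic and p across >= 2 groups."""
    _validate(records)
    counts = records.groupby(group_col).size()
    if len(counts) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    res = multivariate_logrank_test(
        records["time_months"], records[group_col], records["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(
    records: pd.DataFrame,
    covariate: str,
    reference: str | None = None,
) -> CoxResult:
    """Univariate Cox PH for a binary/two-level covariate (Efron ties).

    For a categorical covariate the *reference* level is the baseline; the
    returned hazard ratio is for the other level versus the reference.
    Complete separation is reported as an unbounded HR with a warning rather
    than an error.
    """
    df = _validate(records)[["time_months", "event", covariate]].copy()
    levels = sorted(df[covariate].astype(str).unique())
    if df[covariate].dtype == object or isinstance(
        df[covariate].dtype, pd.CategoricalDtype
    ):
        if len(levels) != 2:
            raise ValueError(f"covariate must have 2 levels, got {levels}")
        ref = reference if reference is not None else levels[0]
        other = [lv for lv in levels if lv != ref][0]
        df["x"] = (df[covariate].astype(str) == other).astype(float)
    else:
        df["x"] = df[covariate].astype(float)
    for lv in df["x"].unique():
        if df.loc[df["x"] == lv, "event"].sum() == 0 and len(df["x"].unique()) == 2:
            warnings.warn("a covariate level has no events; HR may be unstable")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df[["time_months", "event", "x"]],
                    duration_col="time_months", event_col="event")
        except Exception as err:  # convergence failure ≈ separation
            warnings.warn(f"Cox fit failed ({err}); reporting unbounded HR")
            return CoxResult(np.inf, np.inf, np.inf, np.nan, np.nan, np.nan,
                             len(df), int(df["event"].sum()))
    s = cph.summary.loc["x"]
    coef, se = float(s["coef"]), float(s["se(coef)"])
    if abs(coef) > 10 or se > 10:
        warnings.warn(
            "possible complete separation: hazard ratio effectively unbounded")
    with np.errstate(over="ignore"):
        ci_low = float(np.exp(coef - 1.96 * se))
        ci_high = float(np.exp(coef + 1.96 * se))
    return CoxResult(
        hazard_ratio=float(s["exp(coef)"]),
        log_hr=coef,
        se_log_hr=se,
        p_value=float(s["p"]),
        ci_low=ci_low,
        ci_high=ci_high,
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def landmark_filter(records: pd.DataFrame, landmark_months: float) -> pd.DataFrame:
    """Re-origin survival at a landmark; drop patients without follow-up past it."""
    if landmark_months < 0:
        raise ValueError("landmark must be >= 0")
    _validate(records)
    out = records[records["time_months"] > landmark_months].copy()
    if len(out) == 0:
        raise ValueError("landmark removed every patient")
    out["time_months"] = out["time_months"] - landmark_months
    return out.reset_index(drop=True)


def two_sample_test(
    x, y, test: str = "wilcoxon", alternative: str = "two-sided"
) -> tuple[float, float]:
    """Rank-based two-sample tests used throughout the analysis.

    ``wilcoxon`` is the Wilcoxon rank-sum (Mann-Whitney U, exact for small n
    without ties), ``ks`` the Kolmogorov-Smirnov two-sample test, ``kruskal``
    the Kruskal-Wallis test (*y* may then be a list of further samples).
    """
    x = np.asarray(x, dtype=float)
    if test == "kruskal":
        samples = [x] + [np.asarray(s, dtype=float) for s in y]
        if any(s.size == 0 for s in samples):
            raise ValueError("empty sample")
        r = stats.kruskal(*samples)
        return float(r.statistic), float(r.pvalue)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if test == "wilcoxon":
        r = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    elif test == "ks":
        r = stats.ks_2samp(x, y, alternative=alternative)
    else:
        raise ValueError(f"unknown test: {test}")
    return float(r.statistic), float(r.pvalue)
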