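"""Cohort-level statistics: regional CVR versus SVD burden and cognition.

Linear regressions with regional CVR (%/mmHg) as outcome and one SVD
feature or clinical score as the predictor of interest.  Adjusted models
additionally include age, sex, mean arterial pressure, smoking history
(current/recent and ex-smoker >1 y contrasts against never), and diagnoses
of hypertension, diabetes and hypercholesterolaemia.  One model is fitted
per (ROI, predictor) pair; WMH lesion volume enters as log10(%ICV) so that
residuals are plausibly normal and the coefficient reads "per ten-fold
volume increase".  Missing data are excluded per model (complete-case), and
no multiple-comparison correction is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from cvrkit.errors import CollinearityWarning, InsufficientDataError, InvalidArgumentError

__all__ = [
    "RegressionResult",
    "AssumptionReport",
    "ADJUSTMENT_COVARIATES",
    "TABLE2_PREDICTORS",
    "transform_wmh",
    "fit_model",
    "standardize_coefficients",
    "paired_region_difference",
    "check_assumptions",
    "build_table2",
]

logger = logging.getLogger(__name__)

ADJUSTMENT_COVARIATES = (
    "age_years",
    "sex",
    "map_mmHg",
    "smoking",
    "hypertension",
    "diabetes",
    "hypercholesterolaemia",
)

_ADJUST_FORMULA = (
    "age_years + C(sex, Treatment('female')) + map_mmHg"
    " + C(smoking, Treatment('never'))"
    " + hypertension + diabetes + hypercholesterolaemia"
)

#: predictor column and units of its coefficient, one per results-table row
TABLE2_PREDICTORS = (
    ("wmh_log10_pct_icv", "%BOLD/mmHg per log_10(%ICV)"),
    ("fazekas_pv", "%BOLD/mmHg per score unit"),
    ("fazekas_deep", "%BOLD/mmHg per score unit"),
    ("fazekas_total", "%BOLD/mmHg per score unit"),
    ("n_lacunes", "%BOLD/mmHg per lacune"),
    ("n_microbleeds", "%BOLD/mmHg per microbleed"),
    ("atrophy_deep", "%BOLD/mmHg per score unit"),
    ("atrophy_superficial", "%BOLD/mmHg per score unit"),
    ("atrophy_total", "%BOLD/mmHg per score unit"),
    ("brain_pct_icv", "%BOLD/mmHg per %ICV"),
    ("pvs_bg_score", "%BOLD/mmHg per score unit"),
    ("pvs_cso_score", "%BOLD/mmHg per score unit"),
    ("pvs_total_score", "%BOLD/mmHg per score unit"),
    ("pvs_bg_pct_roiv", "%BOLD/mmHg per %ROIV"),
    ("pvs_cso_pct_roiv", "%BOLD/mmHg per %ROIV"),
    ("pvs_total_pct_roiv", "%BOLD/mmHg per %ROIV"),
    ("svd_score", "%BOLD/mmHg per score unit"),
    ("nihss", "%BOLD/mmHg per score unit"),
    ("mrs", "%BOLD/mmHg per score unit"),
    ("moca", "%BOLD/mmHg per score unit"),
)

CONDITION_NUMBER_THRESHOLD = 30.0
MIN_COMPLETE_CASES = 10


@dataclass(frozen=True)
class RegressionResult:
    """One results-table row: coefficient B with 95% CI and p-value."""

    outcome_roi: str
    predictor: str
    B: float
    ci95_low: float
    ci95_high: float
    p_value: float
    n_used: int
    units_text: str = ""
    model: str = "multivariable"  # univariable | multivariable
    standardized_B: float | None = None


@dataclass(frozen=True)
class AssumptionReport:
    """Advisory residual diagnostics (no automatic refitting)."""

    available: bool
    shapiro_stat: float = float("nan")
    shapiro_p: float = float("nan")
    normality_ok: bool = False
    bp_stat: float = float("nan")
    bp_p: float = float("nan")
    homoscedastic_ok: bool = False
    alpha: float = 0.05
    reason: str = ""


def transform_wmh(wmh_pct_icv):
    """log10 of WMH volume in %ICV; +1 in the predictor = a ten-fold volume
    increase.  Non-positive volumes are invalid (callers exclude them)."""
    arr = np.asarray(wmh_pct_icv, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise InvalidArgumentError("WMH volume must be positive for the log10 transform")
    out = np.log10(arr)
    return float(out) if np.isscalar(wmh_pct_icv) else out


def _prepare(cohort: pd.DataFrame, predictor: str) -> pd.DataFrame:
    df = cohort.copy()
    if predictor == "wmh_log10_pct_icv" and predictor not in df.columns:
        vol = df["wmh_pct_icv"]
        n_bad = int((vol <= 0).sum())
        if n_bad:
            logger.info("excluding %d subjects with zero WMH volume from log model", n_bad)
        df[predictor] = np.where(vol > 0, np.log10(vol.where(vol > 0)), np.nan)
    return df


def fit_model(
    cohort: pd.DataFrame,
    outcome_roi: str,
    predictor: str,
    adjusted: bool = True,
    units_text: str = "",
    return_model: bool = False,
    min_cases: int = MIN_COMPLETE_CASES,
):
    """OLS of ``cvr_<outcome_roi>`` on one predictor, optionally adjusted.

    Complete-case per model; requires at least ``min_cases`` complete cases
    (default 10).  The 95% CI uses the t distribution with residual degrees
    of freedom.  A standardized-design condition number above 30 triggers a
    :class:`CollinearityWarning`.
    """
    outcome = f"cvr_{outcome_roi}" if not outcome_roi.startswith("cvr_") else outcome_roi
    df = _prepare(cohort, predictor)
    cols = [outcome, predictor] + (list(ADJUSTMENT_COVARIATES) if adjusted else [])
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise InvalidArgumentError(f"cohort lacks columns: {missing_cols}")
    data = df[cols].dropna()
    if len(data) < min_cases:
        raise InsufficientDataError(
            f"only {len(data)} complete cases for {outcome} ~ {predictor}"
        )
    formula = f"{outcome} ~ {predictor}"
    if adjusted:
        formula += " + " + _ADJUST_FORMULA
    res = smf.ols(formula, data=data).fit()

    exog = res.model.exog[:, 1:]  # drop intercept before standardizing
    sds = exog.std(axis=0)
    if np.all(sds > 0):
        cond = np.linalg.cond((exog - exog.mean(axis=0)) / sds)
        if cond > CONDITION_NUMBER_THRESHOLD:
            warnings.warn(
                f"condition number {cond:.1f} exceeds {CONDITION_NUMBER_THRESHOLD}",
                CollinearityWarning,
            )
    ci = res.conf_int().loc[predictor]
    result = RegressionResult(
        outcome_roi=outcome_roi,
        predictor=predictor,
        B=float(res.params[predictor]),
        ci95_low=float(ci[0]),
        ci95_high=float(ci[1]),
        p_value=float(res.pvalues[predictor]),
        n_used=int(res.nobs),
        units_text=units_text,
        model="multivariable" if adjusted else "univariable",
    )
    return (result, res) if return_model else result


def standardize_coefficients(
    result: RegressionResult,
    cohort: pd.DataFrame,
    convention: str = "both",
) -> float:
    """Standardized coefficient for forest plots.

    ``both`` (default): B * sd(predictor) / sd(outcome), equivalent to
    z-scoring both variables; ``predictor_only``: B * sd(predictor).
    Computed on the complete cases of the two columns.
    """
    outcome = f"cvr_{result.outcome_roi}"
    df = _prepare(cohort, result.predictor)[[outcome, result.predictor]].dropna()
    sd_x = float(df[result.predictor].std())
    sd_y = float(df[outcome].std())
    if sd_x == 0 or (convention == "both" and sd_y == 0):
        raise InvalidArgumentError("zero variance: standardized coefficient undefined")
    if convention == "both":
        return result.B * sd_x / sd_y
    if convention == "predictor_only":
        return result.B * sd_x
    raise InvalidArgumentError(f"unknown convention {convention!r}")


def paired_region_difference(
    cohort: pd.DataFrame, roi_a: str, roi_b: str
) -> tuple[float, tuple[float, float], int]:
    """Mean within-subject CVR difference roi_a - roi_b with t-based 95% CI.

    Pairwise-complete: only subjects with both regional values contribute.
    Returns (mean difference, (ci_low, ci_high), n_pairs).
    """
    a, b = f"cvr_{roi_a}", f"cvr_{roi_b}"
    diffs = (cohort[a] - cohort[b]).dropna().to_numpy(dtype=float)
    n = diffs.size
    if n < 3:
        raise InsufficientDataError(f"only {n} complete pairs for {roi_a}-{roi_b}")
    mean = float(diffs.mean())
    sem = diffs.std(ddof=1) / np.sqrt(n)
    if sem == 0:
        return mean, (mean, mean), n
    half = stats.t.ppf(0.975, n - 1) * sem
    return mean, (mean - half, mean + half), n


def check_assumptions(sm_result, alpha: float = 0.05) -> AssumptionReport:
    """Residual diagnostics for a fitted OLS model.

    Shapiro-Wilk for residual normality and Breusch-Pagan for
    heteroscedasticity, flagged at ``alpha``.  Advisory only — the model is
    never refitted automatically.
    """
    resid = np.asarray(sm_result.resid, dtype=float)
    scale = max(1.0, float(np.abs(sm_result.fittedvalues).max()))
    if resid.size < 3 or np.ptp(resid) < 1e-12 * scale:
        return AssumptionReport(available=False, reason="residuals too few or constant")
    try:
        sw_stat, sw_p = stats.shapiro(resid)
        bp_stat, bp_p, _, _ = het_breuschpagan(resid, sm_result.model.exog)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return AssumptionReport(available=False, reason=str(exc))
    return AssumptionReport(
        available=True,
        shapiro_stat=float(sw_stat),
        shapiro_p=float(sw_p),
        normality_ok=bool(sw_p > alpha),
        bp_stat=float(bp_stat),
        bp_p=float(bp_p),
        homoscedastic_ok=bool(bp_p > alpha),
        alpha=alpha,
    )


def build_table2(cohort: pd.DataFrame, rois=("sgm", "nawm", "wmh")) -> pd.DataFrame:
    """Adjusted model per predictor row and ROI: the full results table.

    Per-model failures (e.g. too few complete cases) are collected in
    ``df.attrs['errors']`` rather than aborting the table.
    """
    rows = []
    errors = []
    if len(cohort) == 0:
        out = pd.DataFrame(
            columns=[
                "predictor", "outcome_roi", "B", "ci95_low", "ci95_high",
                "p_value", "n_used", "units_text", "model",
            ]
        )
        out.attrs["errors"] = []
        return out
    for predictor, units in TABLE2_PREDICTORS:
        for roi in rois:
            try:
                res = fit_model(cohort, roi, predictor, adjusted=True, units_text=units)
            except (InsufficientDataError, InvalidArgumentError) as exc:
                errors.append((predictor, roi, str(exc)))
                continue
            rows.append(
                {
                    "predictor": predictor,
                    "outcome_roi": roi,
                    "B": res.B,
                    "ci95_low": res.ci95_low,
                    "ci95_high": res.ci95_high,
                    "p_value": res.p_value,
                    "n_used": res.n_used,
                    "units_text": units,
                    "model": res.model,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["errors"] = errors
    return out
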