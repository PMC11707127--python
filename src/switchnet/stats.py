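"""Group statistics, behavioral correlations, and prediction models.

The group-comparison pipeline mirrors standard practice for network
metrics: a one-sample Kolmogorov-Smirnov normality gate per group (with
estimated mean/SD — the Lilliefors caveat applies and is logged) picks
an independent-sample t-test when both groups look Gaussian and a
Mann-Whitney U-test otherwise; node-level and subnetwork-level families
are corrected with Benjamini-Hochberg FDR separately, while the single
global-level test is reported uncorrected.

Behavioral correlations are Pearson (Spearman by flag), computed on
score-bearing subjects (patients) only, uncorrected.  Prediction models
are ordinary least squares with an intercept; fit quality is reported
as R^2, RMSE = sqrt(RSS/n), and the constant-free AIC
``n*ln(RSS/n) + 2k`` with k counting the intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sct
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult", "RegressionFit",
    "normality_gate", "group_compare", "correlate",
    "fit_prediction_models", "regression_table", "demographics_table",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class GroupTestResult:
    metric: str
    test: str                  # 't' | 'mann_whitney' | 'chi_square'
    statistic: float
    p_raw: float
    p_fdr: float
    direction: str             # 'patient>control' | 'control>patient' | 'none'


@dataclass
class RegressionFit:
    model: str
    response: str
    predictor: str
    coef: float                # unstandardized B
    beta: float                # standardized coefficient
    intercept: float
    p_value: float
    r_squared: float
    rmse: float
    aic: float
    n: int


def _ks_normal(x: np.ndarray) -> float:
    """One-sample KS p-value against a normal with estimated moments."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(sct.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def normality_gate(group_a: np.ndarray, group_b: np.ndarray,
                   alpha: float = ALPHA) -> str:
    """Choose 't' when both groups pass the KS normality check at
    ``alpha``, else 'mann_whitney'.  Tiny or degenerate groups force the
    nonparametric branch."""
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if len(group_a) < 3 or len(group_b) < 3:
        logger.warning("normality gate: group with n < 3; forcing Mann-Whitney")
        return "mann_whitney"
    if group_a.std(ddof=1) == 0 or group_b.std(ddof=1) == 0:
        logger.warning("normality gate: degenerate constant sample; "
                       "forcing Mann-Whitney")
        return "mann_whitney"
    if _ks_normal(group_a) > alpha and _ks_normal(group_b) > alpha:
        return "t"
    return "mann_whitney"


def _two_sample_test(patients: np.ndarray, controls: np.ndarray) -> tuple[str, float, float]:
    test = normality_gate(patients, controls)
    if test == "t":
        res = sct.ttest_ind(patients, controls)
    else:
        try:
            res = sct.mannwhitneyu(patients, controls, alternative="two-sided")
        except ValueError:  # all values identical
            return test, 0.0, 1.0
    return test, float(res.statistic), float(res.pvalue)


def group_compare(cohort: pd.DataFrame, metric_columns: list[str],
                  family: str = "node",
                  group_column: str = "group") -> pd.DataFrame:
    """One two-group test per metric column with family-wise BH-FDR.

    ``family='global'`` (or a single-metric family) reports the raw p
    unchanged as ``p_fdr`` — the global-level test is uncorrected by
    design.  Empty or constant-missing columns are skipped with a
    warning.
    """
    patients = cohort[cohort[group_column] == "patient"]
    controls = cohort[cohort[group_column] == "control"]
    if patients.empty or controls.empty:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in metric_columns:
        x = patients[col].dropna().to_numpy(dtype=float)
        y = controls[col].dropna().to_numpy(dtype=float)
        if x.size == 0 or y.size == 0:
            logger.warning("metric %s has an empty group; skipped", col)
            continue
        test, statistic, p_raw = _two_sample_test(x, y)
        if x.mean() > y.mean():
            direction = "patient>control"
        elif x.mean() < y.mean():
            direction = "control>patient"
        else:
            direction = "none"
        rows.append({"metric": col, "test": test, "statistic": statistic,
                     "p_raw": p_raw, "direction": direction})
    table = pd.DataFrame(rows)
    if table.empty:
        return table.assign(p_fdr=pd.Series(dtype=float))
    if family == "global" or len(table) == 1:
        table["p_fdr"] = table["p_raw"]
    else:
        table["p_fdr"] = multipletests(table["p_raw"].to_numpy(),
                                       method="fdr_bh")[1]
    table["family"] = family
    return table


def correlate(cohort: pd.DataFrame, metric: str, score: str,
              method: str = "pearson",
              group_column: str = "group") -> tuple[float, float, int]:
    """Correlation between a network metric and a behavioral score on
    score-bearing subjects (patients); two-sided p, uncorrected."""
    patients = cohort[cohort[group_column] == "patient"]
    sub = patients[[metric, score]].dropna()
    if len(sub) < 4:
        raise ValueError(
            f"need at least 4 score-bearing subjects, got {len(sub)}")
    x = sub[metric].to_numpy(dtype=float)
    y = sub[score].to_numpy(dtype=float)
    if method == "pearson":
        r, p = sct.pearsonr(x, y)
    elif method == "spearman":
        r, p = sct.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p), len(sub)


def _ols_fit(y: np.ndarray, x: np.ndarray, model: str, response: str,
             predictor: str) -> RegressionFit:
    if x.std() == 0:
        raise ValueError(f"predictor {predictor} is constant; model rejected")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    n = len(y)
    rss = float((fit.resid ** 2).sum())
    k = 2  # slope + intercept
    rmse = float(np.sqrt(rss / n))
    aic = float(n * np.log(rss / n) + 2 * k) if rss > 0 else -np.inf
    coef = float(fit.params[1])
    beta = coef * x.std(ddof=1) / y.std(ddof=1)
    return RegressionFit(
        model=model, response=response, predictor=predictor,
        coef=coef, beta=float(beta), intercept=float(fit.params[0]),
        p_value=float(fit.pvalues[1]), r_squared=float(fit.rsquared),
        rmse=rmse, aic=aic, n=n)


def fit_prediction_models(cohort: pd.DataFrame,
                          response: str = "change_score",
                          predictors: tuple[str, ...] = ("baseline_score",
                                                         "global_rate"),
                          group_column: str = "group") -> list[RegressionFit]:
    """Separate single-predictor OLS models of motor recovery.

    Model 1 regresses the change score on the baseline score, Model 2
    on the global switching rate, both on patients only, matching the
    two-row model-comparison layout used for recovery prediction.
    """
    patients = cohort[cohort[group_column] == "patient"]
    fits = []
    for i, predictor in enumerate(predictors, start=1):
        sub = patients[[response, predictor]].dropna()
        if len(sub) < 4:
            raise ValueError(f"model {i}: need at least 4 complete cases")
        fits.append(_ols_fit(sub[response].to_numpy(dtype=float),
                             sub[predictor].to_numpy(dtype=float),
                             model=f"Model {i}", response=response,
                             predictor=predictor))
    return fits


def regression_table(fits: list[RegressionFit]) -> pd.DataFrame:
    """Model-comparison table with columns B, beta, p, R2, RMSE, AIC."""
    return pd.DataFrame([{
        "model": f.model, "variable": f.predictor, "B": f.coef,
        "beta": f.beta, "p": f.p_value, "R2": f.r_squared,
        "RMSE": f.rmse, "AIC": f.aic, "n": f.n,
    } for f in fits])


def demographics_table(cohort: pd.DataFrame,
                       group_column: str = "group") -> pd.DataFrame:
    """Cohort report: age (gated t / Mann-Whitney) and sex (chi-square)."""
    patients = cohort[cohort[group_column] == "patient"]
    controls = cohort[cohort[group_column] == "control"]
    rows = []
    test, statistic, p = _two_sample_test(
        patients["age"].to_numpy(dtype=float),
        controls["age"].to_numpy(dtype=float))
    rows.append({"characteristic": "age", "test": test,
                 "statistic": statistic, "p": p})
    contingency = pd.crosstab(cohort[group_column], cohort["sex"])
    if contingency.shape == (2, 2):
        chi2, p_sex, _, _ = sct.chi2_contingency(contingency.to_numpy())
        rows.append({"characteristic": "sex", "test": "chi_square",
                     "statistic": float(chi2), "p": float(p_sex)})
    else:
        logger.warning("sex chi-square skipped: degenerate contingency table")
    return pd.DataFrame(rows)
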