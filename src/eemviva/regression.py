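"""Calibration of cell viability against PARAFAC component scores.

Viability (% of untreated control, from the MTT reference assay) is
regressed on the component scores by ordinary multiple linear regression
with intercept, one model per cell line.  Leave-one-out cross-validation
quantifies predictive skill, and the accordance fit — an OLS of predicted
on reference dose-group means — tests whether the two methods agree with
the ideal line y = x (slope 1, intercept 0) at the 95% confidence level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ViabilityModel:
    """Per-cell-line linear map from component scores to viability %."""

    cell_line: str
    intercept: float
    coefficients: np.ndarray      # length F, viability % per unit score
    r2: float
    rmse: float
    r2_cv: float
    rmse_cv: float

    @property
    def F(self) -> int:
        return int(self.coefficients.size)

    def predict(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        pred = self.intercept + scores @ self.coefficients
        out_of_range = (pred < 0) | (pred > 100)
        if out_of_range.any():
            logger.warning("%d predictions outside [0, 100]%% (not clipped)",
                           int(out_of_range.sum()))
        return pred


@dataclass
class AccordanceResult:
    """OLS agreement between predicted and reference dose-group means.

    ``slope``/``intercept`` carry the fitted line (predicted on reference);
    the halfwidths are 95% confidence intervals from the OLS t-distribution.
    The fit is ideal-consistent when 1 lies in the slope CI and 0 in the
    intercept CI.
    """

    slope: float
    slope_ci95_halfwidth: float
    intercept: float
    intercept_ci95_halfwidth: float
    r2: float

    @property
    def ideal_consistent(self) -> bool:
        return (abs(self.slope - 1.0) <= self.slope_ci95_halfwidth
                and abs(self.intercept) <= self.intercept_ci95_halfwidth)

    def format(self) -> str:
        return (f"a = {self.slope:.2f} ± {self.slope_ci95_halfwidth:.2f}, "
                f"b = {self.intercept:.2f} ± {self.intercept_ci95_halfwidth:.2f}, "
                f"R² = {self.r2:.3f}")


def fit_mlr(scores: np.ndarray, viability: np.ndarray, cell_line: str = "",
            compute_cv: bool = True) -> ViabilityModel:
    """Ordinary least squares of viability on component scores, with intercept.

    Requires more samples than coefficients; collinear score columns are
    reported with the design condition number rather than silently
    regularized.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(viability, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be a 2-D (samples x components) matrix")
    I, F = X.shape
    if I <= F + 1:
        raise ValueError(f"need more than F+1={F + 1} samples, got {I}")
    design = sm.add_constant(X, has_constant="add")
    cond = np.linalg.cond(design)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"score columns are collinear (design condition number {cond:.3g})"
        )
    fit = sm.OLS(y, design).fit()
    pred = fit.fittedvalues
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - pred) ** 2).sum())
    # guard the constant-target case (centered TSS of 0)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float(ss_res <= 1e-12)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    if compute_cv:
        cv_pred = loocv_predict(X, y)["prediction"].to_numpy()
        ss_res_cv = float(((y - cv_pred) ** 2).sum())
        r2_cv = 1.0 - ss_res_cv / ss_tot if ss_tot > 0 else float(ss_res_cv <= 1e-12)
        rmse_cv = float(np.sqrt(np.mean((y - cv_pred) ** 2)))
    else:
        r2_cv = np.nan
        rmse_cv = np.nan
    return ViabilityModel(cell_line=cell_line, intercept=float(fit.params[0]),
                          coefficients=np.asarray(fit.params[1:]),
                          r2=r2, rmse=rmse, r2_cv=r2_cv, rmse_cv=rmse_cv)


def loocv_predict(scores: np.ndarray, viability: np.ndarray) -> pd.DataFrame:
    """Leave-one-out OLS predictions, each excluding its own sample.

    Uses the closed-form deleted residual e_i / (1 - h_ii) of the hat
    matrix, which equals the prediction of an explicit refit without
    sample i.  Returns a DataFrame with observed, prediction and leverage.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(viability, dtype=float)
    design = sm.add_constant(X, has_constant="add")
    I, p = design.shape
    if I <= p:
        raise ValueError("leave-one-out requires more samples than parameters")
    fit = sm.OLS(y, design).fit()
    h = fit.get_influence().hat_matrix_diag
    if np.any(h >= 1.0 - 1e-12):
        raise np.linalg.LinAlgError("a leverage of 1 makes a fold singular")
    resid = y - fit.fittedvalues
    loo_resid = resid / (1.0 - h)
    pred = y - loo_resid
    return pd.DataFrame({"observed": y, "prediction": pred, "leverage": h})


def cv_metrics(scores: np.ndarray, viability: np.ndarray) -> tuple[float, float]:
    """(R2cv, RMSECV) from leave-one-out predictions."""
    df = loocv_predict(scores, viability)
    y = df["observed"].to_numpy()
    pred = df["prediction"].to_numpy()
    r2_cv = 1.0 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    return float(r2_cv), float(np.sqrt(np.mean((y - pred) ** 2)))


def accordance_fit(reference_means: np.ndarray, predicted_means: np.ndarray,
                   sd: np.ndarray | None = None) -> AccordanceResult:
    """OLS of predicted on reference dose-group means with 95% CIs.

    ``sd`` enables optional 1/SD^2 weighting (weighted least squares);
    the default is the unweighted fit of the group means.
    """
    x = np.asarray(reference_means, dtype=float)
    y = np.asarray(predicted_means, dtype=float)
    if x.size != y.size:
        raise ValueError("reference and predicted means differ in length")
    if x.size < 3:
        raise ValueError("accordance fit needs at least 3 dose groups")
    design = sm.add_constant(x)
    if sd is not None:
        w = 1.0 / np.asarray(sd, dtype=float) ** 2
        fit = sm.WLS(y, design, weights=w).fit()
    else:
        fit = sm.OLS(y, design).fit()
    tq = stats.t.ppf(0.975, df=int(fit.df_resid))
    b, a = fit.params           # intercept, slope
    se_b, se_a = fit.bse
    return AccordanceResult(slope=float(a), slope_ci95_halfwidth=float(tq * se_a),
                            intercept=float(b), intercept_ci95_halfwidth=float(tq * se_b),
                            r2=float(fit.rsquared))
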