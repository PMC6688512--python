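"""Backward-selection multiple regression of gait percent-changes on
baseline clinical covariates, with the standard validity checks.

Candidate predictors: age, sex (male=0 / female=1), disease duration,
UPDRS-II, UPDRS-III, Hoehn-Yahr stage, levodopa-equivalent dose, and the
baseline value of the outcome's own gait variable; the baseline covariate is
always retained.  Estimation is ordinary least squares with classical
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import (
    OLSInfluence,
    variance_inflation_factor,
)
from statsmodels.stats.stattools import durbin_watson

from gaitresp.types import GaitError

DEFAULT_CANDIDATES = ("age", "sex", "disease_duration", "updrs2", "updrs3",
                      "hy_stage", "led")
DEFAULT_REMOVAL_ALPHA = 0.10


@dataclass(frozen=True)
class RegressionSpec:
    outcome: str  # delta variable name
    baseline_predictor: str  # column holding the outcome's baseline value
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    removal_alpha: float = DEFAULT_REMOVAL_ALPHA


@dataclass
class FittedModel:
    outcome: str
    predictors: list[str]  # retained, excluding the intercept
    coefficients: dict[str, float]  # includes "const"
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    adjusted_r2: float
    r2: float
    f_stat: float
    model_p: float
    n: int
    _result: object = field(default=None, repr=False)


@dataclass
class DiagnosticsReport:
    durbin_watson: float
    vif: dict[str, float]
    residual_normality_p: float
    heteroscedasticity_p: float
    outlier_ids: list

    def __post_init__(self) -> None:
        for name, v in self.vif.items():
            if v < 1.0 - 1e-9:
                raise GaitError(f"VIF for {name} below 1")


def _design(data: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    X = sm.add_constant(data[list(predictors)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = data[list(predictors)].astype(float).corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if len(predictors) > 1 else (predictors[0],)
        raise GaitError(f"rank-deficient design; near-collinear columns: {worst}")
    return X


def fit_ols(data: pd.DataFrame, outcome: str,
            predictors: list[str]) -> FittedModel:
    """Least-squares fit with classical SEs, t p-values, adjusted R^2, F."""
    if len(data) <= len(predictors) + 1:
        raise GaitError("need n > p + 1 observations")
    X = _design(data, predictors)
    y = data[outcome].astype(float)
    res = sm.OLS(y, X).fit()
    return FittedModel(
        outcome=outcome,
        predictors=list(predictors),
        coefficients=res.params.to_dict(),
        standard_errors=res.bse.to_dict(),
        p_values=res.pvalues.to_dict(),
        adjusted_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        model_p=float(res.f_pvalue),
        n=int(res.nobs),
        _result=res,
    )


def backward_eliminate(spec: RegressionSpec, data: pd.DataFrame
                       ) -> FittedModel:
    """Backward selection by p-value above ``removal_alpha``.

    At each round the removable predictor with the largest p above the
    threshold is dropped and the model refit, until every retained p is at
    or below the threshold or only the intercept and the baseline covariate
    remain.  The baseline covariate is never dropped.  Ties in p are broken
    by lexicographic name, making the procedure invariant to the order the
    candidates are supplied in.
    """
    current = sorted(set(spec.candidates) | {spec.baseline_predictor})
    model = fit_ols(data, spec.outcome, current)
    while True:
        removable = [p for p in model.predictors if p != spec.baseline_predictor]
        if not removable:
            break
        worst = max(removable,
                    key=lambda name: (round(model.p_values[name], 12), name))
        if model.p_values[worst] <= spec.removal_alpha:
            break
        current = [p for p in model.predictors if p != worst]
        model = fit_ols(data, spec.outcome, current)
    return model


def validate_model(model: FittedModel, data: pd.DataFrame,
                   outlier_z: float = 3.0) -> DiagnosticsReport:
    """Durbin-Watson, VIFs, residual normality, Breusch-Pagan, outliers."""
    res = model._result
    if res is None:
        raise GaitError("model carries no fit result")
    resid = np.asarray(res.resid)
    X = sm.add_constant(data[model.predictors].astype(float), has_constant="add")
    if len(model.predictors) > 1:
        vifs = {name: float(variance_inflation_factor(X.to_numpy(), i))
                for i, name in enumerate(X.columns) if name != "const"}
    else:
        vifs = {name: 1.0 for name in model.predictors}
    _, bp_p, _, _ = het_breuschpagan(resid, X.to_numpy())
    shapiro_p = float(sps.shapiro(resid).pvalue) if np.ptp(resid) > 0 else 0.0
    student = OLSInfluence(res).resid_studentized_external
    outliers = list(data.index[np.abs(student) > outlier_z])
    return DiagnosticsReport(
        durbin_watson=float(durbin_watson(resid)),
        vif=vifs,
        residual_normality_p=shapiro_p,
        heteroscedasticity_p=float(bp_p),
        outlier_ids=outliers,
    )


def regression_report(models: list[FittedModel]) -> list[dict]:
    """Serialisable report: one block per outcome, rows per retained term."""
    blocks = []
    for m in models:
        rows = [{"term": "const", "B": m.coefficients["const"],
                 "SE": m.standard_errors["const"], "p": m.p_values["const"]}]
        rows += [{"term": t, "B": m.coefficients[t],
                  "SE": m.standard_errors[t], "p": m.p_values[t]}
                 for t in m.predictors]
        blocks.append({"outcome": m.outcome, "terms": rows,
                       "adjusted_r2": m.adjusted_r2, "f": m.f_stat,
                       "model_p": m.model_p, "n": m.n})
    return blocks
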