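"""Stepwise multiple linear regression of the yield tolerance index on the
other trait indices.

Forward selection with backward elimination: at each step the candidate with
the smallest partial-F p-value below ``alpha_enter`` enters; any entered
predictor whose p-value rises above ``alpha_remove`` is dropped.  Partial R²
values are the R² increments along the final entry order, so they sum to the
total R².  The per-genotype prediction report mirrors the worked-example
layout: observed y, predicted, error (y - yhat), relative error and
evaluation accuracy 100 * (1 - |relative error|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class StepwiseModel:
    """Selected predictors with OLS coefficients and fit diagnostics."""

    predictors: list[str]                 # in entry order
    intercept: float
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    partial_r2: pd.Series                 # R2 increment per entry
    total_r2: float
    resid_se: float
    n_obs: int
    steps: list[dict] = field(default_factory=list)

    @property
    def cumulative_r2(self) -> pd.Series:
        return self.partial_r2.cumsum()

    @classmethod
    def from_coefficients(
        cls, intercept: float, coefficients: dict[str, float]
    ) -> "StepwiseModel":
        """Wrap an externally reported equation (no fit diagnostics)."""
        coefs = pd.Series(coefficients, dtype=float)
        nan = pd.Series(np.nan, index=coefs.index)
        return cls(
            predictors=list(coefs.index),
            intercept=float(intercept),
            coefficients=coefs,
            std_errors=nan.copy(),
            p_values=nan.copy(),
            partial_r2=nan.copy(),
            total_r2=float("nan"),
            resid_se=float("nan"),
            n_obs=0,
        )

    def predict(self, X: pd.DataFrame) -> pd.Series:
        missing = [p for p in self.predictors if p not in X.columns]
        if missing:
            raise KeyError(f"missing predictors: {missing}")
        return self.intercept + X[self.predictors] @ self.coefficients

    def summary(self) -> str:
        tab = pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.std_errors,
                "p": self.p_values,
                "partial_R2": self.partial_r2,
                "cumulative_R2": self.cumulative_r2,
            }
        )
        return (
            f"Stepwise OLS — n={self.n_obs}, total R2={self.total_r2:.3f}, "
            f"residual SE={self.resid_se:.3f}\n"
            f"intercept {self.intercept:.3f}\n"
            + tab.to_string(float_format=lambda v: f"{v:.3f}")
        )


def _ols(y: pd.Series, X: pd.DataFrame):
    return sm.OLS(np.asarray(y, dtype=float),
                  sm.add_constant(X.astype(float), has_constant="add")).fit()


def stepwise_fit(
    X: pd.DataFrame,
    y: pd.Series,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> StepwiseModel:
    """Forward-backward stepwise OLS over the candidate columns of X."""
    candidates = list(X.columns)
    included: list[str] = []
    steps: list[dict] = []
    while True:
        changed = False
        remaining = [c for c in candidates if c not in included]
        if remaining and len(included) + 2 < len(y):
            pvals = {}
            for c in remaining:
                fit = _ols(y, X[included + [c]])
                pvals[c] = fit.pvalues[c]
            best = min(pvals, key=pvals.get)
            if pvals[best] < alpha_enter:
                included.append(best)
                steps.append({"action": "enter", "predictor": best,
                              "p": float(pvals[best])})
                changed = True
        if included:
            fit = _ols(y, X[included])
            worst = fit.pvalues[included].idxmax()
            if fit.pvalues[worst] > alpha_remove:
                included.remove(worst)
                steps.append({"action": "remove", "predictor": worst,
                              "p": float(fit.pvalues[worst])})
                changed = True
        if not changed:
            break
    if not included:
        warnings.warn("no candidate passed the entry threshold; "
                      "intercept-only model")
        ybar = float(np.mean(y))
        return StepwiseModel(
            predictors=[], intercept=ybar,
            coefficients=pd.Series(dtype=float),
            std_errors=pd.Series(dtype=float),
            p_values=pd.Series(dtype=float),
            partial_r2=pd.Series(dtype=float),
            total_r2=0.0,
            resid_se=float(np.std(np.asarray(y) - ybar, ddof=1)),
            n_obs=len(y), steps=steps,
        )
    final = _ols(y, X[included])
    partial = {}
    prev = 0.0
    for i in range(len(included)):
        r2 = _ols(y, X[included[: i + 1]]).rsquared
        partial[included[i]] = r2 - prev
        prev = r2
    return StepwiseModel(
        predictors=included,
        intercept=float(final.params["const"]),
        coefficients=final.params[included],
        std_errors=final.bse[included],
        p_values=final.pvalues[included],
        partial_r2=pd.Series(partial),
        total_r2=float(final.rsquared),
        resid_se=float(np.sqrt(final.mse_resid)),
        n_obs=len(y),
        steps=steps,
    )


def predict_report(
    model: StepwiseModel,
    X: pd.DataFrame,
    y: pd.Series,
    round_predictions: int | None = None,
) -> pd.DataFrame:
    """Per-row prediction diagnostics plus the population average accuracy
    (stored in ``attrs['average_accuracy']``).

    ``round_predictions`` rounds the predicted values to that many decimals
    before the diagnostics are formed — the convention of the worked-example
    table, whose errors and accuracies derive from its 3-decimal
    predictions.  The relative error itself is never rounded before the
    accuracy is computed.
    """
    yhat = model.predict(X)
    if round_predictions is not None:
        yhat = yhat.round(round_predictions)
    return prediction_diagnostics(pd.Series(y, index=X.index, dtype=float),
                                  yhat)


def prediction_diagnostics(
    observed: pd.Series, predicted: pd.Series
) -> pd.DataFrame:
    """Error, relative error and evaluation accuracy per row.

    error = observed - predicted; relative error = error / observed;
    accuracy = 100 * (1 - |relative error|).  The population average
    accuracy is stored in ``attrs['average_accuracy']``.
    """
    y = pd.Series(observed, dtype=float)
    yhat = pd.Series(predicted, index=y.index, dtype=float)
    err = y - yhat
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = err / y
    undefined = y == 0
    if undefined.any():
        warnings.warn(
            f"zero observed value for {list(y.index[undefined])}; "
            "relative error undefined"
        )
        rel[undefined] = np.nan
    acc = 100.0 * (1.0 - rel.abs())
    out = pd.DataFrame(
        {
            "observed": y,
            "predicted": yhat,
            "error": err,
            "relative_error": rel,
            "accuracy_%": acc,
        }
    )
    out.attrs["average_accuracy"] = float(acc.mean())
    return out


class StepwiseOLS:
    """Model object over a candidate matrix and response; ``fit()`` runs the
    forward-backward selection and returns a :class:`StepwiseModel`."""

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        alpha_enter: float = 0.05,
        alpha_remove: float = 0.10,
    ):
        self.X = X
        self.y = y
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove

    def fit(self) -> StepwiseModel:
        return stepwise_fit(self.X, self.y, self.alpha_enter,
                            self.alpha_remove)
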