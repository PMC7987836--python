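"""Behavioral analysis of the phoneme categorization task.

Covers trial bookkeeping (step filtering, optional restriction to
unrepaired-response trials for the connectivity branch), descriptive
unrepaired-response rates per condition/context/step, and a fixed-effects
logistic test of the word-learning (Condition) effect via a likelihood-ratio
test against the model without Condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_io import AnalysisConfig, TrialTable, ValidationError

logger = logging.getLogger("phonoflux")


def filter_analysis_trials(table: TrialTable, cfg: AnalysisConfig,
                           unrepaired_only: bool = False) -> TrialTable:
    """Restrict to the continuum steps entering analysis.

    With the default config this keeps steps 2-5 (108 trials per
    participant per condition in the full design).  ``unrepaired_only``
    additionally keeps only trials whose response left the illegal onset
    cluster intact — the trial selection used for effective connectivity.
    """
    df = table.df
    mask = df["step"].isin(cfg.steps_included)
    if unrepaired_only:
        mask &= df["unrepaired"]
    out = df.loc[mask]
    if out.empty:
        logger.warning("trial filter left an empty table")
    return TrialTable(out.reset_index(drop=True))


def repair_rates(table: TrialTable) -> pd.DataFrame:
    """Unrepaired-response rate per (condition, context, step).

    Returns columns condition, context, step, n_trials, n_unrepaired,
    rate, standard_error, where standard_error is the binomial
    sqrt(rate * (1 - rate) / n).
    """
    if len(table) == 0:
        raise ValidationError("repair_rates requires a non-empty table")
    grp = table.df.groupby(["condition", "context", "step"], observed=True)
    out = grp["unrepaired"].agg(n_trials="size", n_unrepaired="sum")
    out = out.reset_index()
    out["rate"] = out["n_unrepaired"] / out["n_trials"]
    out["standard_error"] = np.sqrt(out["rate"] * (1 - out["rate"])
                                    / out["n_trials"])
    return out


@dataclass
class ConditionEffect:
    """Result of the likelihood-ratio test of the Condition term."""

    estimate: float          # log-odds coefficient for Trained vs Naive
    lr_statistic: float
    df: int
    p_value: float
    n_trials: int
    converged: bool
    separation: bool = False

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "lr_statistic": self.lr_statistic,
                "df": self.df, "p_value": self.p_value,
                "n_trials": self.n_trials, "converged": self.converged,
                "separation": self.separation}


def _design_matrix(df: pd.DataFrame, include_condition: bool,
                   include_subject: bool) -> np.ndarray:
    def _indicator(mask):
        col = mask.to_numpy(float)
        return col if 0.0 < col.mean() < 1.0 else None   # drop degenerate

    cols = [np.ones(len(df))]
    maybe = [_indicator(df["context"] == "_r")]
    steps = sorted(df["step"].unique())
    maybe += [_indicator(df["step"] == s) for s in steps[1:]]
    if include_subject:
        subjects = sorted(df["subject_id"].unique())
        maybe += [_indicator(df["subject_id"] == s) for s in subjects[1:]]
    if include_condition:
        maybe.append(_indicator(df["condition"] == "Trained"))
    cols += [c for c in maybe if c is not None]
    return np.column_stack(cols)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
            return res.llf, res.params, res.mle_retvals.get("converged", True)
        except Exception:
            return None, None, False


def _fit_logit_penalized(y: np.ndarray, X: np.ndarray,
                         alpha: float = 1e-3):
    """Ridge-penalized fallback for separated/degenerate data.

    Maximizes the log-likelihood minus 0.5 * alpha * ||beta||^2 with
    L-BFGS; the weak penalty keeps the optimum finite under complete
    separation.  Returns the unpenalized log-likelihood at the optimum.
    """
    from scipy.optimize import minimize

    def negloglik(beta):
        eta = X @ beta
        # log(1 + exp(eta)) - y*eta, computed stably
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return -(ll - 0.5 * alpha * beta @ beta)

    def grad(beta):
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return -(X.T @ (y - mu) - alpha * beta)

    res = minimize(negloglik, np.zeros(X.shape[1]), jac=grad,
                   method="L-BFGS-B", options={"maxiter": 500})
    beta = res.x
    eta = X @ beta
    llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return llf, beta


def test_condition_effect(table: TrialTable,
                          subject_effects: bool = False) -> ConditionEffect:
    """Likelihood-ratio test of the training-condition effect on repair.

    Fits a fixed-effects logistic regression of the unrepaired-response
    indicator on Condition + Context + Step (categorical), optionally with
    subject indicator covariates, and compares it against the same model
    without Condition: LR = 2 (ll_full - ll_null), p from chi-square with
    1 df.  Complete separation is handled by a documented ridge-penalized
    refit; the result is then flagged with ``separation=True``.
    """
    df = table.df
    if df["condition"].nunique() < 2:
        raise ValidationError("both conditions must be present")
    y = df["unrepaired"].to_numpy(float)
    X_full = _design_matrix(df, include_condition=True,
                            include_subject=subject_effects)
    X_null = _design_matrix(df, include_condition=False,
                            include_subject=subject_effects)
    llf, params_full, conv_f = _fit_logit(y, X_full)
    lln, _, conv_n = _fit_logit(y, X_null)
    separation = False
    if llf is None or lln is None or not (conv_f and conv_n) \
            or (params_full is not None
                and np.max(np.abs(params_full)) > 15):
        separation = True
        logger.warning("possible separation in logistic fit; "
                       "using ridge-penalized likelihoods")
        llf, params_full = _fit_logit_penalized(y, X_full)
        lln, _ = _fit_logit_penalized(y, X_null)
    lr = max(0.0, 2.0 * (llf - lln))
    p = float(stats.chi2.sf(lr, df=1))
    return ConditionEffect(estimate=float(params_full[-1]),
                           lr_statistic=float(lr), df=1, p_value=p,
                           n_trials=len(df),
                           converged=not separation, separation=separation)
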