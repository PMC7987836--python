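"""Kalman-filter estimation of time-varying MVAR prediction models.

Each channel (ROI) is modeled as a linear prediction from the ``p``
preceding samples of a set of predictor channels.  The regression
coefficients are treated as a random-walk state vector and tracked by a
scalar-observation Kalman filter, yielding per-timepoint coefficient
estimates and a per-timepoint prediction-error scale (exponentially
weighted SD of the one-step innovations).  The *full model* for a target
uses all channels as predictors; a *counter-model* omits one candidate
causal channel.  The log ratio of counter-model to full-model error scale
is the Granger causality index computed downstream.

The filter itself is deterministic given data and settings.  The first
``warmup`` samples (default 100, matching filter convergence at a 1000 Hz
sampling rate) are excluded from downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core_io import AnalysisConfig, MultiTimeSeries, ValidationError

logger = logging.getLogger("phonoflux")


@dataclass
class KalmanSettings:
    """Filter constants.

    * ``process_noise_scale`` — variance added to each coefficient per
      step (random-walk drift rate).  Small values approach a recursive
      least-squares / OLS fit on stationary data; larger values track
      faster coefficient changes at the cost of estimation variance.
    * ``initial_covariance_scale`` — diagonal of the initial state
      covariance; large values let early observations dominate.
    * ``error_smoothing`` — exponential decay of the innovation-variance
      estimate underlying the prediction-error scale.
    * ``warmup`` — samples excluded from downstream statistics while the
      filter converges.
    """

    process_noise_scale: float = 2e-5
    initial_covariance_scale: float = 1.0
    error_smoothing: float = 0.98
    warmup: int = 100

    def __post_init__(self):
        if self.process_noise_scale < 0:
            raise ValidationError("process_noise_scale must be >= 0")
        if self.initial_covariance_scale <= 0:
            raise ValidationError("initial_covariance_scale must be > 0")
        if not 0.0 < self.error_smoothing <= 1.0:
            raise ValidationError("error_smoothing must lie in (0, 1]")
        if self.warmup < 0:
            raise ValidationError("warmup must be >= 0")


@dataclass
class TvMvarModel:
    """One fitted prediction model (full or counter) for one target.

    ``coeffs[t, j, k]`` is the filtered coefficient of predictor ``j`` at
    lag ``k+1`` for output timepoint ``t``; timepoints before ``order``
    hold the initial (zero) state.  ``error_scale[t]`` is the running
    prediction-error SD, strictly positive.
    """

    target: str
    predictors: list[str]
    order: int
    coeffs: np.ndarray
    error_scale: np.ndarray
    innovations: np.ndarray
    warmup: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.coeffs)):
            raise ValidationError("fitted coefficients must be finite")
        if np.any(self.error_scale[self.warmup:] <= 0):
            raise ValidationError("error_scale must be positive post-warmup")

    @property
    def n_timepoints(self) -> int:
        return self.coeffs.shape[0]


@njit(cache=True)
def _kalman_scalar_obs(y, X, q, p0, decay, v0):  # pragma: no cover (numba)
    T, d = X.shape
    w = np.zeros(d)
    P = np.eye(d) * p0
    coeffs = np.zeros((T, d))
    innov = np.zeros(T)
    err = np.empty(T)
    v = v0
    for t in range(T):
        for i in range(d):
            P[i, i] += q
        h = X[t]
        g = P @ h
        s = h @ g + v
        e = y[t] - h @ w
        k = g / s
        w = w + k * e
        P = P - np.outer(k, g)
        P = 0.5 * (P + P.T)
        v = decay * v + (1.0 - decay) * e * e
        if v < 1e-12:
            v = 1e-12
        coeffs[t] = w
        innov[t] = e
        err[t] = np.sqrt(v)
    return coeffs, innov, err


def _lag_matrix(values: np.ndarray, predictor_rows: np.ndarray,
                p: int) -> np.ndarray:
    """Regressors X[t] = (x_j(t-1..t-p) for j in predictors); zero for t<p."""
    n_t = values.shape[1]
    d = len(predictor_rows) * p
    X = np.zeros((n_t, d))
    for jj, j in enumerate(predictor_rows):
        for k in range(p):
            X[p:, jj * p + k] = values[j, p - k - 1:n_t - k - 1]
    return X


def _fit_target(ts: MultiTimeSeries, target: str, predictors: list[str],
                cfg: AnalysisConfig, ks: KalmanSettings) -> TvMvarModel:
    p = cfg.model_order
    if ts.n_timepoints <= p + ks.warmup:
        raise ValidationError("series shorter than model order + warmup")
    ti = ts.channel(target)
    rows = np.array([ts.channel(c) for c in predictors], dtype=np.int64)
    y = ts.values[ti]
    if np.std(y) < 1e-12:
        logger.warning("target channel %r is constant", target)
    X = _lag_matrix(ts.values, rows, p)
    v0 = float(max(np.var(y), 1e-6))
    coeffs, innov, err = _kalman_scalar_obs(
        y, X, ks.process_noise_scale, ks.initial_covariance_scale,
        ks.error_smoothing, v0)
    coeffs = coeffs.reshape(ts.n_timepoints, len(predictors), p)
    return TvMvarModel(target=target, predictors=list(predictors), order=p,
                       coeffs=coeffs, error_scale=err, innovations=innov,
                       warmup=ks.warmup)


def fit_full_model(ts: MultiTimeSeries, cfg: AnalysisConfig,
                   ks: KalmanSettings | None = None) -> list[TvMvarModel]:
    """Fit the full MVAR model: every channel predicted from all channels.

    Returns one :class:`TvMvarModel` per target channel, in channel order.
    """
    if ts.n_channels < 2:
        raise ValidationError("full model needs >= 2 channels")
    ks = ks or KalmanSettings()
    return [_fit_target(ts, tgt, list(ts.labels), cfg, ks)
            for tgt in ts.labels]


def fit_target_model(ts: MultiTimeSeries, target: str, cfg: AnalysisConfig,
                     ks: KalmanSettings | None = None) -> TvMvarModel:
    """Full model for a single target channel (all channels as predictors)."""
    return _fit_target(ts, target, list(ts.labels), cfg,
                       ks or KalmanSettings())


def fit_counter_model(ts: MultiTimeSeries, omit: str, target: str,
                      cfg: AnalysisConfig,
                      ks: KalmanSettings | None = None) -> TvMvarModel:
    """Reduced model with the candidate causal channel's lags removed."""
    if omit == target:
        raise ValidationError("cannot omit the target channel itself")
    if omit not in ts.labels:
        raise ValidationError(f"channel {omit!r} not in series")
    predictors = [c for c in ts.labels if c != omit]
    return _fit_target(ts, target, predictors, cfg, ks or KalmanSettings())


def coefficient_tensor(models: list[TvMvarModel],
                       labels: list[str]) -> np.ndarray:
    """Assemble A[t, k, i, j] from per-target full models.

    Entry [t, k, i, j] is the filtered influence of channel j at lag k+1
    on channel i at timepoint t — the generator layout, so fitted models
    can be iterated as surrogate-data generators.
    """
    n = len(labels)
    by_target = {m.target: m for m in models}
    T = models[0].n_timepoints
    p = models[0].order
    A = np.zeros((T, p, n, n))
    for i, tgt in enumerate(labels):
        m = by_target[tgt]
        if m.predictors != labels:
            raise ValidationError("coefficient_tensor requires full models")
        # m.coeffs: (T, n, p) -> [t, k, i, j]
        A[:, :, i, :] = m.coeffs.transpose(0, 2, 1)
    return A


def residual_pool(models: list[TvMvarModel]) -> np.ndarray:
    """Post-warmup innovations per channel, shape (n_channels, n_kept)."""
    start = max(models[0].warmup, models[0].order)
    return np.array([m.innovations[start:] for m in models])
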