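"""Granger causality indices, bootstrap significance, and edge statistics.

For a directed pair source → target, the Granger causality index at time t
is

    GCi(t) = ln( sigma_reduced(t) / sigma_full(t) )

where sigma_full is the prediction-error scale of the full MVAR model for
the target and sigma_reduced that of the counter-model omitting the source.
Positive GCi means the source carries unique predictive information.

Significance is assessed with a residual-randomization bootstrap: surrogate
data are reconstructed by iterating the fitted time-varying full model with
the source→target coefficients set to zero and innovations resampled (with
replacement) from the fitted residual pool; running the full + counter-model
fit on each surrogate yields a per-timepoint null distribution of GCi.
Per-timepoint one-sided p-values (upper tail) are thresholded at alpha and
the number of significant timepoints in the analysis window summarizes the
edge.  Between-condition differences in those counts are compared with an
exact conditional binomial (sign-test style) test, and edge-wise decisions
are corrected by Benjamini–Hochberg FDR.

Edge *detection* in a single condition uses the window-mean GCi against its
bootstrap null (one number per edge), which is robust to the strong
autocorrelation of per-timepoint significance indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import (AnalysisConfig, MultiTimeSeries, StabilityError,
                      ValidationError)
from .tvmvar import (KalmanSettings, TvMvarModel, _kalman_scalar_obs,
                     _lag_matrix, coefficient_tensor, fit_counter_model,
                     fit_full_model, residual_pool)

logger = logging.getLogger("phonoflux")


def gci(full_error: np.ndarray, reduced_error: np.ndarray) -> np.ndarray:
    """Per-timepoint log ratio of reduced- to full-model error scales."""
    full_error = np.asarray(full_error, float)
    reduced_error = np.asarray(reduced_error, float)
    if full_error.shape != reduced_error.shape:
        raise ValidationError("error-scale series must have equal length")
    bad = (full_error <= 0) | (reduced_error <= 0)
    if np.any(bad):
        t = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"non-positive error scale at timepoint {t}")
    return np.log(reduced_error / full_error)


@dataclass
class GciSeries:
    """Observed GCi for one directed edge over the analysis window."""

    source: str
    target: str
    condition: str
    gci: np.ndarray                  # window-restricted
    p: np.ndarray | None = None      # per-timepoint bootstrap p
    window: tuple[int, int] = (0, 0)  # inclusive sample indices
    edge_p: float | None = None      # window-mean GCi vs. bootstrap null
    mean_gci: float = field(default=np.nan)
    alpha: float = 0.05

    def __post_init__(self):
        self.gci = np.asarray(self.gci, float)
        if not np.all(np.isfinite(self.gci)):
            raise ValidationError("GCi must be finite")
        if self.p is not None:
            self.p = np.asarray(self.p, float)
            if self.p.shape != self.gci.shape:
                raise ValidationError("p series must match gci length")
            if np.any((self.p < 0) | (self.p > 1)):
                raise ValidationError("p-values must lie in [0, 1]")
        if np.isnan(self.mean_gci):
            self.mean_gci = float(self.gci.mean())

    @property
    def sig(self) -> np.ndarray:
        if self.p is None:
            raise ValidationError("no bootstrap p-values attached")
        return self.p < self.alpha


@njit(cache=True)
def _simulate_fitted(A, x0, eps):  # pragma: no cover (numba)
    T, p, n, _ = A.shape
    x = np.zeros((T, n))
    for t in range(p):
        for j in range(n):
            x[t, j] = x0[t, j]
    for t in range(p, T):
        acc = eps[t].copy()
        for k in range(p):
            acc += A[t, k] @ x[t - k - 1]
        x[t] = acc
    return x


def _gci_on_values(values: np.ndarray, t_idx: int, s_idx: int, p: int,
                   ks: KalmanSettings) -> np.ndarray:
    """Full-length GCi for edge s->t on a raw (n, T) value array."""
    n = values.shape[0]
    y = values[t_idx]
    v0 = float(max(np.var(y), 1e-6))
    X_full = _lag_matrix(values, np.arange(n), p)
    keep = np.array([j for j in range(n) if j != s_idx], dtype=np.int64)
    X_red = _lag_matrix(values, keep, p)
    _, _, err_full = _kalman_scalar_obs(y, X_full, ks.process_noise_scale,
                                        ks.initial_covariance_scale,
                                        ks.error_smoothing, v0)
    _, _, err_red = _kalman_scalar_obs(y, X_red, ks.process_noise_scale,
                                       ks.initial_covariance_scale,
                                       ks.error_smoothing, v0)
    return np.log(err_red / err_full)


def bootstrap_edge(ts: MultiTimeSeries, source: str, target: str,
                   cfg: AnalysisConfig, ks: KalmanSettings | None = None,
                   seed: int = 0,
                   full_models: list[TvMvarModel] | None = None,
                   n_bootstrap: int | None = None,
                   condition: str = "") -> GciSeries:
    """Observed GCi + bootstrap p-values for one directed edge.

    ``full_models`` (one per target, from :func:`fit_full_model`) may be
    shared across edges to avoid refitting.  ``n_bootstrap`` overrides
    ``cfg.n_bootstrap``.  Surrogate replicates that diverge are redrawn
    (up to 5x the replicate budget) and the rejection count is logged.
    """
    ks = ks or KalmanSettings()
    B = int(n_bootstrap or cfg.n_bootstrap)
    p = cfg.model_order
    s_idx, t_idx = ts.channel(source), ts.channel(target)
    if s_idx == t_idx:
        raise ValidationError("source and target must differ")
    if full_models is None:
        full_models = fit_full_model(ts, cfg, ks)
    obs_gci_full = gci(full_models[t_idx].error_scale,
                       fit_counter_model(ts, source, target, cfg, ks)
                       .error_scale)
    lo, hi = ts.window_indices(cfg.window_ms)
    lo = max(lo, ks.warmup, p)
    T = ts.n_timepoints

    A = coefficient_tensor(full_models, list(ts.labels))
    A_null = A.copy()
    A_null[:, :, t_idx, s_idx] = 0.0
    pool = residual_pool(full_models)
    n_pool = pool.shape[1]
    x0 = ts.values[:, :p].T.copy()

    rng = np.random.default_rng(seed)
    null = np.empty((B, hi - lo + 1))
    null_mean = np.empty(B)
    rejected = 0
    b = 0
    max_draws = 5 * B
    draws = 0
    while b < B:
        if draws >= max_draws:
            raise StabilityError(
                f"surrogate iteration diverged in {rejected} of {draws} "
                f"replicates for edge {source}->{target}")
        draws += 1
        idx = rng.integers(0, n_pool, size=(T, ts.n_channels))
        eps = pool.T[idx, np.arange(ts.n_channels)]
        surr = _simulate_fitted(A_null, x0, eps)
        if not np.all(np.isfinite(surr)) or np.max(np.abs(surr)) > 1e6:
            rejected += 1
            continue
        g = _gci_on_values(surr.T.copy(), t_idx, s_idx, p, ks)
        null[b] = g[lo:hi + 1]
        null_mean[b] = g[lo:hi + 1].mean()
        b += 1
    if rejected:
        logger.info("edge %s->%s: redrew %d diverging surrogate replicates",
                    source, target, rejected)

    obs = obs_gci_full[lo:hi + 1]
    # empirical upper-tail fraction; 0 when the observed GCi beats every
    # null replicate
    pvals = (null >= obs[None, :]).sum(axis=0) / B
    edge_p = float((null_mean >= obs.mean()).sum() / B)
    return GciSeries(source=source, target=target, condition=condition,
                     gci=obs, p=pvals, window=(lo, hi), edge_p=edge_p,
                     alpha=cfg.alpha)


def scan_edges(ts: MultiTimeSeries, cfg: AnalysisConfig,
               ks: KalmanSettings | None = None, seed: int = 0,
               condition: str = "",
               n_bootstrap: int | None = None) -> list[GciSeries]:
    """Bootstrap GCi for every ordered channel pair."""
    ks = ks or KalmanSettings()
    full_models = fit_full_model(ts, cfg, ks)
    pairs = [(s, t) for t in ts.labels for s in ts.labels if s != t]
    seeds = np.random.SeedSequence(seed).generate_state(len(pairs)) % (2**31)
    return [bootstrap_edge(ts, s, t, cfg, ks, seed=int(es),
                           full_models=full_models, n_bootstrap=n_bootstrap,
                           condition=condition)
            for (s, t), es in zip(pairs, seeds)]


def count_significant(g: GciSeries, cfg: AnalysisConfig) -> int:
    """Number of analysis-window timepoints with bootstrap p < alpha."""
    if g.p is None:
        raise ValidationError("bootstrap p-values required")
    return int(np.sum(g.p < cfg.alpha))


def compare_conditions(count_a: int, count_b: int,
                       n_window: int) -> tuple[float, str | None]:
    """Exact conditional binomial test on significant-timepoint counts.

    Given k = count_a + count_b significant timepoints overall, tests
    count_a against Binomial(k, 1/2) two-sided.  Returns (p, favored)
    where favored is "a"/"b" for the larger count or None on a tie.
    k = 0 gives p = 1.
    """
    if not (0 <= count_a <= n_window and 0 <= count_b <= n_window):
        raise ValidationError("counts must lie in [0, n_window]")
    k = count_a + count_b
    if k == 0:
        return 1.0, None
    p = stats.binomtest(count_a, k, 0.5, alternative="two-sided").pvalue
    favored = None if count_a == count_b else ("a" if count_a > count_b
                                               else "b")
    return float(p), favored


def fdr_correct(pvalues, cfg: AnalysisConfig) -> np.ndarray:
    """Benjamini–Hochberg step-up decisions at level alpha."""
    pvalues = np.asarray(list(pvalues), float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(pvalues, alpha=cfg.alpha,
                                    method="fdr_bh")
    return reject


def detect_edges(series: list[GciSeries], cfg: AnalysisConfig) -> pd.DataFrame:
    """Single-condition edge detection table with FDR decisions.

    Uses each edge's window-mean GCi bootstrap p-value; columns: source,
    target, mean_gci, n_sig_timepoints, edge_p, fdr_significant.
    """
    rows = [{"source": g.source, "target": g.target,
             "mean_gci": g.mean_gci,
             "n_sig_timepoints": count_significant(g, cfg),
             "edge_p": g.edge_p} for g in series]
    df = pd.DataFrame(rows)
    df["fdr_significant"] = fdr_correct(df["edge_p"], cfg) \
        if len(df) else pd.Series(dtype=bool)
    return df


def compare_edge_sets(series_a: list[GciSeries], series_b: list[GciSeries],
                      cfg: AnalysisConfig,
                      labels: tuple[str, str] = ("Trained", "Naive"),
                      ) -> pd.DataFrame:
    """Between-condition comparison of significant-timepoint counts.

    Edges are matched by (source, target); for each, the exact conditional
    binomial test compares the two counts, and decisions are FDR-corrected
    across all edges.  Columns: source, target, count_a, count_b, diff,
    n_window, binomial_p, fdr_significant, favored_condition.
    """
    by_edge_b = {(g.source, g.target): g for g in series_b}
    rows = []
    for ga in series_a:
        key = (ga.source, ga.target)
        if key not in by_edge_b:
            raise ValidationError(f"edge {key} missing from second condition")
        gb = by_edge_b[key]
        n_window = len(ga.gci)
        ca, cb = count_significant(ga, cfg), count_significant(gb, cfg)
        p, favored = compare_conditions(ca, cb, n_window)
        rows.append({"source": ga.source, "target": ga.target,
                     "count_a": ca, "count_b": cb, "diff": ca - cb,
                     "n_window": n_window, "binomial_p": p,
                     "favored_condition": {None: None, "a": labels[0],
                                           "b": labels[1]}[favored]})
    df = pd.DataFrame(rows)
    df["fdr_significant"] = fdr_correct(df["binomial_p"], cfg) \
        if len(df) else pd.Series(dtype=bool)
    return df


def influence_report(edge_comparisons: pd.DataFrame, focus: str,
                     direction: str = "onto") -> pd.DataFrame:
    """FDR-significant influences onto / from a focus channel.

    The tabular analogue of a bubble plot: edges with ``target == focus``
    (direction "onto") or ``source == focus`` ("from"), restricted to
    FDR-significant comparisons and sorted by |count difference|.
    """
    if direction not in ("onto", "from"):
        raise ValidationError("direction must be 'onto' or 'from'")
    known = set(edge_comparisons["source"]) | set(edge_comparisons["target"])
    if focus not in known:
        raise ValidationError(f"unknown focus channel {focus!r}")
    col = "target" if direction == "onto" else "source"
    sel = edge_comparisons[(edge_comparisons[col] == focus)
                           & edge_comparisons["fdr_significant"]]
    return sel.reindex(sel["diff"].abs().sort_values(ascending=False).index
                       ).reset_index(drop=True)
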