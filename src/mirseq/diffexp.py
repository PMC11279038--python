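"""Moderated differential expression for miRNA counts.

The model follows the standard microarray-style workflow adapted to counts:
counts are transformed to log2 counts-per-million, a mean-variance trend is
fitted and inverted into per-observation precision weights, each miRNA is
fitted by weighted least squares against a two-column design (intercept,
group), residual variances are shrunk toward a scaled-F prior estimated by
method of moments on log variances, and moderated t-statistics with
augmented degrees of freedom give per-miRNA p-values, adjusted by
Benjamini-Hochberg. A miRNA is called differentially expressed when the
adjusted p is below 0.05 and the linear fold change is at least 1.5.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_FC_THRESHOLD = 1.5
LOWESS_SPAN = 0.5
MIN_ROWS_FOR_TREND = 10
# Posterior df stand-in when the prior df is infinite; t with 1e6 df is
# numerically the normal limit.
INF_DF_CAP = 1e6


@dataclass
class ModerationParams:
    """Hyperparameters of the scaled-F variance prior."""

    d0: float            # prior degrees of freedom, may be math.inf
    s0_sq: float         # prior variance
    df_residual: float   # residual df of each per-miRNA fit

    def __post_init__(self) -> None:
        # d0 = 0 is the no-moderation limit (ordinary t-test).
        if not (self.d0 >= 0 or math.isinf(self.d0)):
            raise ValueError("d0 must be non-negative or infinite")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be positive")


def log_cpm(counts, lib_sizes=None) -> np.ndarray:
    """log2 counts-per-million with a half-count offset:
    log2((count + 0.5) / (libsize + 1) * 1e6)."""
    if isinstance(counts, CountMatrix):
        mat = counts.counts.to_numpy(dtype=float)
        lib = counts.library_sizes().to_numpy(dtype=float)
    else:
        mat = np.asarray(counts, dtype=float)
        lib = (np.asarray(lib_sizes, dtype=float) if lib_sizes is not None
               else mat.sum(axis=0))
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    return np.log2((mat + 0.5) / (lib + 1.0) * 1e6)


def design_matrix(group: np.ndarray) -> np.ndarray:
    """Two-column design: intercept and frozen-group indicator."""
    group = np.asarray(group, dtype=float)
    return np.column_stack([np.ones_like(group), group])


def _ols_row_stats(y: np.ndarray, design: np.ndarray):
    """Per-row OLS fitted values and residual standard deviations."""
    pinv = np.linalg.pinv(design)
    beta = y @ pinv.T
    fitted = beta @ design.T
    resid = y - fitted
    df = y.shape[1] - design.shape[1]
    sd = np.sqrt((resid ** 2).sum(axis=1) / df)
    return fitted, sd


def voom_weights(logcpm: np.ndarray, counts: np.ndarray,
                 design: np.ndarray) -> np.ndarray:
    """Precision weights from a fitted mean-variance trend.

    Square-rooted per-row residual standard deviations are smoothed against
    mean log-count with a locally weighted linear smoother (span 0.5); the
    trend is interpolated at each observation's fitted log-count (clamped to
    the trend's range) and inverted as trend**(-4) to give per-observation
    weights.
    """
    logcpm = np.asarray(logcpm, dtype=float)
    n_rows = logcpm.shape[0]
    if n_rows < MIN_ROWS_FOR_TREND:
        logger.warning(
            "only %d rows: too few to fit a mean-variance trend, using unit weights",
            n_rows,
        )
        return np.ones_like(logcpm)
    fitted, sd = _ols_row_stats(logcpm, design)
    sqrt_sd = np.sqrt(sd)
    mean_logcount = logcpm.mean(axis=1)
    trend = lowess(sqrt_sd, mean_logcount, frac=LOWESS_SPAN, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # np.interp clamps outside [tx.min(), tx.max()] by construction.
    pred = np.interp(fitted, tx, ty)
    pred = np.clip(pred, max(ty.min(), 1e-6), None)
    return pred ** (-4.0)


def fit_group_model(logcpm: np.ndarray, weights: np.ndarray,
                    design: np.ndarray, row_ids=None):
    """Row-wise weighted least squares against (intercept, group).

    Returns arrays ``(coef, stdev_unscaled, s_sq, df_residual)`` where
    ``coef`` is the group-effect (frozen minus control) in log2 units and
    ``stdev_unscaled`` is the unscaled standard deviation of that
    coefficient, i.e. sqrt([(X'WX)^-1]_gg).
    """
    logcpm = np.asarray(logcpm, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n_rows, n_samples = logcpm.shape
    p = design.shape[1]
    df_residual = n_samples - p
    if df_residual < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    coef = np.empty(n_rows)
    stdev_unscaled = np.empty(n_rows)
    s_sq = np.empty(n_rows)
    for i in range(n_rows):
        w = weights[i]
        xtwx = design.T @ (w[:, None] * design)
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            rid = row_ids[i] if row_ids is not None else i
            raise np.linalg.LinAlgError(
                f"singular weighted design for row {rid}"
            ) from exc
        beta = xtwx_inv @ design.T @ (w * logcpm[i])
        resid = logcpm[i] - design @ beta
        coef[i] = beta[1]
        stdev_unscaled[i] = math.sqrt(xtwx_inv[1, 1])
        s_sq[i] = float(w @ resid ** 2) / df_residual
    return coef, stdev_unscaled, s_sq, df_residual


def estimate_prior(s_sq, df_residual: float) -> ModerationParams:
    """Method-of-moments fit of the scaled-F variance prior.

    Matches the mean and variance of log(s^2) to their digamma/trigamma
    expressions under s^2 ~ s0^2 * F(df, d0); d0 solves a trigamma equation
    by monotone root finding on [0.1, 500]. When the log-variances show no
    excess spread beyond trigamma(df/2), d0 is infinite and s0^2 is the
    bias-corrected geometric-mean estimate.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq) & (s_sq > 0)]
    if s_sq.size < 2:
        raise ValueError("need at least 2 finite positive variances")
    df = float(df_residual)
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))

    def spread(d0: float) -> float:
        return float(special.polygamma(1, d0 / 2.0))

    if e_var <= 0 or e_var < spread(500.0):
        return ModerationParams(d0=math.inf, s0_sq=math.exp(e_mean), df_residual=df)
    if e_var >= spread(0.1):
        d0 = 0.1
    else:
        d0 = brentq(lambda d: spread(d) - e_var, 0.1, 500.0, xtol=1e-10)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return ModerationParams(d0=float(d0), s0_sq=s0_sq, df_residual=df)


def moderated_test(coef, stdev_unscaled, s_sq, df_residual: float,
                   prior: ModerationParams):
    """Moderated t-statistics and two-sided p-values.

    The posterior variance shrinks each residual variance toward the prior:
    s_post^2 = (d0*s0^2 + df*s^2) / (d0 + df); the t-statistic
    coef / (stdev_unscaled * s_post) is referred to a t distribution with
    df + d0 degrees of freedom (capped at a large finite value when d0 is
    infinite).
    """
    coef = np.asarray(coef, dtype=float)
    stdev_unscaled = np.asarray(stdev_unscaled, dtype=float)
    s_sq = np.asarray(s_sq, dtype=float)
    df = float(df_residual)
    if math.isinf(prior.d0):
        s_post_sq = np.full_like(s_sq, prior.s0_sq)
        df_total = INF_DF_CAP
    else:
        s_post_sq = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        df_total = df + prior.d0
    t_mod = coef / (stdev_unscaled * np.sqrt(s_post_sq))
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return t_mod, p_raw


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_de(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
            fc_threshold: float = DEFAULT_FC_THRESHOLD) -> pd.DataFrame:
    """Flag significance: adjusted p strictly below ``alpha`` AND linear
    fold change at least ``fc_threshold`` (inclusive)."""
    table = table.copy()
    lfc_cut = math.log2(fc_threshold)
    table["significant"] = (table["p_adj"] < alpha) & (
        table["log2fc"].abs() >= lfc_cut
    )
    return table


def run_diffexp(counts: CountMatrix, alpha: float = DEFAULT_ALPHA,
                fc_threshold: float = DEFAULT_FC_THRESHOLD,
                use_weights: bool = True) -> pd.DataFrame:
    """Full DE analysis on a filtered count matrix.

    Returns a per-miRNA table with columns mirna_id, log2fc, fc,
    avg_logcpm, t_mod, p_raw, p_adj, significant, sorted by input order.
    """
    group = counts.group_vector().to_numpy()
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    design = design_matrix(group)
    lcpm = log_cpm(counts)
    raw = counts.counts.to_numpy(dtype=float)
    weights = voom_weights(lcpm, raw, design) if use_weights else np.ones_like(lcpm)
    coef, stdev_unscaled, s_sq, df_residual = fit_group_model(
        lcpm, weights, design, row_ids=counts.mirna_ids
    )
    prior = estimate_prior(s_sq, df_residual)
    t_mod, p_raw = moderated_test(coef, stdev_unscaled, s_sq, df_residual, prior)
    p_adj = bh_adjust(p_raw)
    table = pd.DataFrame(
        {
            "mirna_id": counts.mirna_ids,
            "log2fc": coef,
            "fc": np.exp2(coef),
            "avg_logcpm": lcpm.mean(axis=1),
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    return call_de(table, alpha=alpha, fc_threshold=fc_threshold)
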