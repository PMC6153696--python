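"""Rubin's rules for combining estimates from multiply imputed data.

Given m per-imputation estimates q_i with within-imputation variances u_i:

    qbar = mean(q_i)
    W    = mean(u_i)                     (within-imputation variance)
    B    = sample variance of the q_i    (between-imputation variance)
    T    = W + (1 + 1/m) B               (total variance)
    df   = (m - 1) (1 + W / ((1 + 1/m) B))^2

and the two-sided p-value comes from the t reference distribution of
qbar / sqrt(T).  Correlations are pooled on the Fisher-z scale (variance
1/(n - 3 - k) with k conditioned variables) and back-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PooledEstimate", "rubin_pool", "pool_correlation_fisher"]


@dataclass
class PooledEstimate:
    qbar: float
    W: float
    B: float
    T: float
    df: float
    p: float
    m: int


def rubin_pool(
    estimates: np.ndarray,
    variances: np.ndarray,
    barnard_rubin: bool = False,
    n_complete_df: float | None = None,
) -> PooledEstimate:
    """Combine m estimates and their variances by Rubin's rules.

    Uses the classical large-sample degrees of freedom by default;
    ``barnard_rubin=True`` (with ``n_complete_df``, the complete-data df)
    switches to the Barnard–Rubin small-sample adjustment.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m < 2:
        raise ValueError("need m >= 2 estimates to pool")
    if u.size != m:
        raise ValueError("estimates and variances must have equal length")
    if np.any(u <= 0):
        raise ValueError("variances must be positive")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1 + 1 / m) * B
    # a vanishing between-imputation spread sends df to infinity; use the
    # normal reference there (and when df overflows numerically)
    with np.errstate(over="ignore", divide="ignore"):
        df_raw = (
            (m - 1)
            * (1 + np.float64(W) / ((1 + 1 / m) * np.float64(max(B, 5e-324))))
            ** 2
        )
    if B == 0 or not np.isfinite(df_raw):
        df = np.inf
        z = qbar / np.sqrt(T)
        p = 2 * stats.norm.sf(abs(z))
    else:
        df = float(df_raw)
        if barnard_rubin:
            if n_complete_df is None:
                raise ValueError("barnard_rubin needs n_complete_df")
            lam = (1 + 1 / m) * B / T
            df_obs = (n_complete_df + 1) / (n_complete_df + 3) * (
                n_complete_df * (1 - lam)
            )
            df = 1 / (1 / df + 1 / df_obs)
        t = qbar / np.sqrt(T)
        p = 2 * stats.t.sf(abs(t), df)
    return PooledEstimate(qbar, W, B, float(T), float(df), float(p), m)


def pool_correlation_fisher(
    correlations: np.ndarray, n_eff: int, k: int = 0
) -> PooledEstimate:
    """Pool m (partial) correlations via Fisher z and Rubin's rules.

    ``n_eff`` is the effective sample size and ``k`` the number of
    conditioned variables; the within-imputation variance on the z scale is
    1/(n_eff - 3 - k).  The returned ``qbar`` is back-transformed to the
    correlation scale; variances and the p-value stay on the z scale.
    """
    r = np.asarray(correlations, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| = 1 cannot be Fisher-transformed")
    if n_eff <= 3 + k:
        raise ValueError(f"need n_eff > {3 + k} for k={k} conditioned variables")
    z = np.arctanh(r)
    w = 1.0 / (n_eff - 3 - k)
    pooled = rubin_pool(z, np.full(r.size, w))
    return PooledEstimate(
        qbar=float(np.tanh(pooled.qbar)),
        W=pooled.W,
        B=pooled.B,
        T=pooled.T,
        df=pooled.df,
        p=pooled.p,
        m=pooled.m,
    )
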