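"""Univariate and LOD-assuming imputation.

These methods operate column by column and assume (except mean imputation)
that missing values are left-censored: the metabolite was present but below
the limit of detection, so its observed values follow a left-truncated
normal distribution.  Since the LOD itself is not recorded by the platform,
the minimum observed value within the fitting scope stands in for it.

Methods
-------
``impute_mean`` / ``impute_min``
    constant fill by the observed mean / minimum of the column.
``impute_rc``
    Richardson–Ciampi: maximum-likelihood fit of the truncated normal, then
    fill every missing cell with E[x | x <= LOD] (a constant).
``impute_its``
    imputation by truncated sampling: random draws from the censored part of
    the fitted distribution.
``impute_mits``
    multiple-imputation ITS (m independent fills sharing one fit).
``rundaywise``
    applies RC/ITS/MITS per run day (>= 17 observations required), with the
    documented fallbacks for the remaining cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .matrix import MetaboliteMatrix

__all__ = [
    "CensoredNormalFit",
    "ImputedData",
    "fit_censored_normal",
    "impute_mean",
    "impute_min",
    "impute_rc",
    "impute_its",
    "impute_mits",
    "rundaywise",
]

DEFAULT_M = 20  # imputations per multiple-imputation method
MIN_RUNDAY_OBS = 17


@dataclass
class CensoredNormalFit:
    """ML fit of the untruncated parent of left-truncated observations."""

    mu: float
    sigma: float
    lod: float
    loglik: float
    converged: bool
    n_obs: int
    n_missing: int


@dataclass
class ImputedData:
    """One or m completed matrices produced by an imputation method.

    Observed cells are identical to the input in every fill; the
    ``imputed_mask`` marks the cells that were filled in.
    """

    fills: list[np.ndarray]
    method: str
    imputed_mask: np.ndarray
    sample_ids: list[str]
    metabolite_ids: list[str]
    runday: np.ndarray
    seed: int | None = None

    @property
    def m(self) -> int:
        return len(self.fills)

    def single(self) -> np.ndarray:
        if self.m != 1:
            raise ValueError(f"{self.method}: {self.m} fills, expected 1")
        return self.fills[0]

    def column(self, metabolite_id: str) -> int:
        return self.metabolite_ids.index(metabolite_id)


def _new_imputed(
    m: MetaboliteMatrix, fills: list[np.ndarray], method: str, seed=None
) -> ImputedData:
    for f in fills:
        if np.isnan(f).any():
            raise AssertionError(f"{method}: fill contains undefined cells")
    return ImputedData(
        fills=fills,
        method=method,
        imputed_mask=m.mask.copy(),
        sample_ids=list(m.sample_ids),
        metabolite_ids=list(m.metabolite_ids),
        runday=m.runday.copy(),
        seed=seed,
    )


def _constant_fill(m: MetaboliteMatrix, stat, method: str) -> ImputedData:
    vals = m.values.copy()
    for j in range(m.n_metabolites):
        miss = m.mask[:, j]
        if not miss.any():
            continue
        obs = m.observed(j)
        if obs.size == 0:
            raise ValueError(
                f"{method}: column {m.metabolite_ids[j]!r} is fully missing"
            )
        vals[miss, j] = stat(obs)
    return _new_imputed(m, [vals], method)


def impute_mean(m: MetaboliteMatrix) -> ImputedData:
    """Fill each missing cell with the observed mean of its column."""
    return _constant_fill(m, np.mean, "mean")


def impute_min(m: MetaboliteMatrix) -> ImputedData:
    """Fill each missing cell with the smallest observed value of its column."""
    return _constant_fill(m, np.min, "min")


def _truncated_negloglik(
    params: np.ndarray, x: np.ndarray, lod: float, n_missing: int, censored: bool
) -> float:
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    # truncated density: phi((x-mu)/sigma) / (sigma * P(X > lod))
    ll = np.sum(stats.norm.logpdf(x, mu, sigma))
    ll -= x.size * stats.norm.logsf(lod, mu, sigma)
    if censored and n_missing > 0:
        # censored variant additionally scores the mass below the LOD
        ll += x.size * stats.norm.logsf(lod, mu, sigma)  # undo truncation term
        ll += n_missing * stats.norm.logcdf(lod, mu, sigma)
    return -ll


def fit_censored_normal(
    observed: np.ndarray,
    n_missing: int,
    lod: float,
    censored: bool = False,
) -> CensoredNormalFit:
    """ML estimate of the normal parent from left-truncated observations.

    By default maximizes the truncated likelihood of the observed values
    only; ``censored=True`` switches to the censored likelihood, which also
    scores the ``n_missing`` values known to lie below the LOD.
    """
    x = np.asarray(observed, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct observed values")
    if np.any(x < lod):
        raise ValueError("observed values below the stated LOD")
    start = np.array([x.mean(), np.log(max(x.std(), 1e-8))])
    res = optimize.minimize(
        _truncated_negloglik,
        start,
        args=(x, lod, n_missing, censored),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-8, "maxiter": 2000},
    )
    converged = bool(res.success)
    if converged:
        mu, sigma = res.x[0], float(np.exp(res.x[1]))
        loglik = -res.fun
    else:
        warnings.warn(
            "truncated-normal fit did not converge; "
            "falling back to observed moments"
        )
        mu, sigma = float(x.mean()), float(max(x.std(), 1e-8))
        loglik = -_truncated_negloglik(
            np.array([mu, np.log(sigma)]), x, lod, n_missing, censored
        )
    return CensoredNormalFit(
        mu=float(mu),
        sigma=float(sigma),
        lod=float(lod),
        loglik=float(loglik),
        converged=converged,
        n_obs=x.size,
        n_missing=int(n_missing),
    )


def conditional_mean_below(fit: CensoredNormalFit) -> float:
    """E[x | x <= LOD] for the fitted parent (inverse-Mills-ratio formula)."""
    a = (fit.lod - fit.mu) / fit.sigma
    logcdf = stats.norm.logcdf(a)
    if logcdf < -700:  # Phi(a) underflows; conditional mean ~ lod itself
        warnings.warn("LOD deep in the lower tail; imputing the LOD itself")
        return fit.lod
    mills = np.exp(stats.norm.logpdf(a) - logcdf)
    return float(fit.mu - fit.sigma * mills)


def _draw_below(
    fit: CensoredNormalFit, size: int, rng: np.random.Generator
) -> np.ndarray:
    a = (fit.lod - fit.mu) / fit.sigma
    if stats.norm.logcdf(a) < -700:
        return np.full(size, fit.lod)
    return stats.truncnorm.rvs(
        -np.inf, a, loc=fit.mu, scale=fit.sigma, size=size, random_state=rng
    )


def _column_scopes(
    m: MetaboliteMatrix, scope: str
) -> list[tuple[object, np.ndarray]]:
    if scope == "global":
        return [("all", np.arange(m.n_samples))]
    if scope == "runday":
        return list(m.runday_groups().items())
    raise ValueError(f"unknown scope {scope!r}")


def _fit_column(
    m: MetaboliteMatrix, j: int, rows: np.ndarray, censored: bool
) -> CensoredNormalFit:
    obs_rows = rows[~m.mask[rows, j]]
    obs = m.values[obs_rows, j]
    return fit_censored_normal(
        obs, n_missing=int(m.mask[rows, j].sum()), lod=float(obs.min()),
        censored=censored,
    )


def impute_rc(
    m: MetaboliteMatrix, scope: str = "global", censored: bool = False
) -> ImputedData:
    """Richardson–Ciampi fill: all missing cells get E[x | x <= LOD]."""
    vals = m.values.copy()
    for j in range(m.n_metabolites):
        for _, rows in _column_scopes(m, scope):
            miss = rows[m.mask[rows, j]]
            if miss.size == 0:
                continue
            fit = _fit_column(m, j, rows, censored)
            vals[miss, j] = conditional_mean_below(fit)
    return _new_imputed(m, [vals], "RC" if scope == "global" else "RC-R")


def impute_its(
    m: MetaboliteMatrix,
    scope: str = "global",
    seed: int | None = None,
    censored: bool = False,
    rng: np.random.Generator | None = None,
) -> ImputedData:
    """Truncated sampling: missing cells drawn from the censored part."""
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = m.values.copy()
    for j in range(m.n_metabolites):
        for _, rows in _column_scopes(m, scope):
            miss = rows[m.mask[rows, j]]
            if miss.size == 0:
                continue
            fit = _fit_column(m, j, rows, censored)
            vals[miss, j] = _draw_below(fit, miss.size, rng)
    return _new_imputed(m, [vals], "ITS", seed=seed)


def impute_mits(
    m: MetaboliteMatrix,
    scope: str = "global",
    m_imputations: int = DEFAULT_M,
    seed: int | None = None,
    censored: bool = False,
) -> ImputedData:
    """Multiple ITS: ``m_imputations`` independent fills sharing one fit."""
    rng = np.random.default_rng(seed)
    fits: dict[tuple[int, object], CensoredNormalFit] = {}
    scopes = _column_scopes(m, scope)
    for j in range(m.n_metabolites):
        for d, rows in scopes:
            if m.mask[rows, j].any():
                fits[(j, d)] = _fit_column(m, j, rows, censored)
    fills = []
    for _ in range(m_imputations):
        vals = m.values.copy()
        for (j, d), fit in fits.items():
            rows = dict(scopes)[d]
            miss = rows[m.mask[rows, j]]
            vals[miss, j] = _draw_below(fit, miss.size, rng)
        fills.append(vals)
    return _new_imputed(m, fills, "MITS", seed=seed)


def rundaywise(
    m: MetaboliteMatrix,
    base: str,
    min_runday_obs: int = MIN_RUNDAY_OBS,
    m_imputations: int = DEFAULT_M,
    seed: int | None = None,
    censored: bool = False,
) -> ImputedData:
    """Run-day-wise RC/ITS/MITS with the documented fallbacks (RC-R etc.).

    The base method is fitted and applied within every run day providing at
    least ``min_runday_obs`` observed values of the column.  Cells on days
    below the threshold are filled by: the mean of the available per-day
    conditional expectations (RC); a chained-equations ICE-norm fill
    (ITS/MITS, one per fill).
    """
    if base not in ("RC", "ITS", "MITS"):
        raise ValueError("base must be RC, ITS or MITS")
    rng = np.random.default_rng(seed)
    n_fills = m_imputations if base == "MITS" else 1
    groups = m.runday_groups()

    fills = [m.values.copy() for _ in range(n_fills)]
    leftover = np.zeros_like(m.mask)
    for j in range(m.n_metabolites):
        if not m.mask[:, j].any():
            continue
        day_constants: list[float] = []
        col_leftover_rows: list[np.ndarray] = []
        for d, rows in groups.items():
            obs_ct = int((~m.mask[rows, j]).sum())
            miss = rows[m.mask[rows, j]]
            if obs_ct < min_runday_obs:
                if miss.size:
                    col_leftover_rows.append(miss)
                continue
            fit = _fit_column(m, j, rows, censored)
            if base == "RC":
                day_constants.append(conditional_mean_below(fit))
            if miss.size == 0:
                continue
            if base == "RC":
                for f in fills:
                    f[miss, j] = day_constants[-1]
            else:
                for f in fills:
                    f[miss, j] = _draw_below(fit, miss.size, rng)
        if col_leftover_rows:
            rows = np.concatenate(col_leftover_rows)
            leftover[rows, j] = True
            if base == "RC":
                if day_constants:
                    for f in fills:
                        f[rows, j] = float(np.mean(day_constants))
                else:
                    warnings.warn(
                        f"RC-R: no run day meets the {min_runday_obs}-"
                        f"observation rule for {m.metabolite_ids[j]!r}; "
                        "column filled with its observed mean"
                    )
                    for f in fills:
                        f[rows, j] = float(m.observed(j).mean())

    method = {"RC": "RC-R", "ITS": "ITS-R", "MITS": "MITS-R"}[base]
    if base != "RC" and leftover.any():
        # leftover cells get a chained-equations fill, one per ITS fill
        from .multivariate import ice_impute

        for k, f in enumerate(fills):
            partial = MetaboliteMatrix(
                np.where(leftover, np.nan, f),
                leftover.copy(),
                m.sample_ids,
                m.metabolite_ids,
                m.runday,
                scale=m.scale,
            )
            sub_seed = int(rng.integers(2**31 - 1))
            ice = ice_impute(partial, model="norm", seed=sub_seed)
            fills[k] = ice.single()
    return _new_imputed(m, fills, method, seed=seed)
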