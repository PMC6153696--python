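"""Multivariate imputation: chained equations (ICE/MICE) and K-nearest
neighbors.

Chained equations visit the incomplete columns in random order, each time
regressing the column on the other variables and replacing its missing
entries with draws from the fitted imputation model:

``norm``
    Bayesian linear regression — residual variance drawn from its scaled
    inverse-chi-squared posterior, coefficients from their normal posterior,
    plus residual noise; propagates parameter uncertainty.
``pmm``
    predictive mean matching — each missing entry receives an *observed*
    donor value whose prediction is closest to the missing entry's
    prediction, so fills stay in the support of the data.
``adjR``
    the norm model plus a per-run-day random intercept, shrunk toward the
    global intercept, to exploit batch structure.

KNN imputation replaces a missing cell with the ``e^(-d)``-weighted average
of its K nearest neighbors under Euclidean distance: nearest *variables*
(``var``), nearest *observations* (``obs``), or nearest observations with
distances computed only over a pre-selected set of 5–10 variables most
correlated with the target (``obs-sel``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lod import DEFAULT_M, ImputedData, _new_imputed
from .matrix import MetaboliteMatrix

__all__ = [
    "KnnConfig",
    "ice_impute",
    "mice_impute",
    "mice_avg",
    "knn_impute",
]

PMM_DONORS = 5  # donor-pool size for predictive mean matching


@dataclass
class KnnConfig:
    """Configuration of the KNN imputation family."""

    mode: str = "obs-sel"
    k: int = 10
    sel_corr: float = 0.2
    sel_min: int = 5
    sel_max: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("var", "obs", "obs-sel"):
            raise ValueError(f"unknown KNN mode {self.mode!r}")
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.sel_min > self.sel_max:
            raise ValueError("sel_min must be <= sel_max")


# ---------------------------------------------------------------------------
# chained equations


def _screen_predictors(
    m: MetaboliteMatrix, j: int, min_corr: float
) -> np.ndarray:
    """Columns with pairwise-complete |corr| >= min_corr to column j."""
    keep = []
    x = m.values[:, j]
    for other in range(m.n_metabolites):
        if other == j:
            continue
        both = ~np.isnan(x) & ~m.mask[:, other]
        if both.sum() < 3:
            continue
        xs = x[both]
        ys = m.values[both, other]
        if xs.std() == 0 or ys.std() == 0:
            continue
        if abs(np.corrcoef(xs, ys)[0, 1]) >= min_corr:
            keep.append(other)
    return np.asarray(keep, dtype=int)


def _bayes_lm_draw(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior draw (beta_hat, beta_star, sigma_star) of a linear model.

    Uses the standard noninformative-prior draw: sigma^2* from the scaled
    inverse-chi-squared, beta* ~ N(beta_hat, sigma^2* (X'X)^-1).  A small
    ridge keeps singular designs workable.
    """
    n, q = X.shape
    xtx = X.T @ X
    ridge = 0.0
    try:
        L = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError:
        warnings.warn("singular design in imputation model; ridge fallback")
        ridge = 1e-6 * max(np.trace(xtx) / q, 1.0)
        L = np.linalg.cholesky(xtx + ridge * np.eye(q))
    xtx_inv = np.linalg.inv(L @ L.T)
    beta_hat = xtx_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - q, 1)
    sigma2_star = float(resid @ resid) / rng.chisquare(dof)
    chol = np.linalg.cholesky(xtx_inv + 1e-14 * np.eye(q))
    beta_star = beta_hat + np.sqrt(sigma2_star) * (chol @ rng.standard_normal(q))
    return beta_hat, beta_star, float(np.sqrt(sigma2_star))


def _runday_intercepts(
    resid: np.ndarray, days: np.ndarray, rng: np.random.Generator
) -> dict[object, float]:
    """Shrunken per-day mean residuals (method-of-moments random intercept).

    Day effects b_d = (n_d / (n_d + lam)) * mean(resid_d) with
    lam = sigma_e^2 / sigma_b^2 estimated from the between/within residual
    variance decomposition; a simple stand-in for a full mixed model.
    """
    labels = list(dict.fromkeys(days))
    means = {}
    counts = {}
    for d in labels:
        sel = days == d
        counts[d] = int(sel.sum())
        means[d] = float(resid[sel].mean()) if counts[d] else 0.0
    sigma_e2 = float(np.var(resid)) if resid.size else 1.0
    nbar = np.mean(list(counts.values())) if counts else 1.0
    between = float(np.var(list(means.values()))) if len(labels) > 1 else 0.0
    sigma_b2 = max(between - sigma_e2 / max(nbar, 1.0), 1e-12)
    lam = sigma_e2 / sigma_b2
    return {
        d: counts[d] / (counts[d] + lam) * means[d] for d in labels
    }


def ice_impute(
    m: MetaboliteMatrix,
    model: str = "norm",
    n_iter: int = 10,
    predictor_min_corr: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ImputedData:
    """Single chained-equations fill (ICE-norm / ICE-pmm / ICE-adjR).

    ``predictor_min_corr`` screens covariates per target column (the
    high-dimensional default is 0.1; 0 keeps all columns, as appropriate
    for low-dimensional simulated data).
    """
    if model not in ("norm", "pmm", "adjR"):
        raise ValueError(f"unknown ICE model {model!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = m.values.copy()
    incomplete = [j for j in range(m.n_metabolites) if m.mask[:, j].any()]
    if not incomplete:
        return _new_imputed(m, [vals], f"ICE-{model}", seed=seed)
    # initial fill: observed column means
    col_means = {}
    for j in incomplete:
        obs = m.observed(j)
        if obs.size == 0:
            raise ValueError(
                f"column {m.metabolite_ids[j]!r} has no observed value"
            )
        col_means[j] = float(obs.mean())
        vals[m.mask[:, j], j] = col_means[j]

    predictors: dict[int, np.ndarray] = {}
    for j in incomplete:
        if predictor_min_corr > 0:
            pred = _screen_predictors(m, j, predictor_min_corr)
        else:
            pred = np.asarray(
                [c for c in range(m.n_metabolites) if c != j], dtype=int
            )
        predictors[j] = pred

    for _ in range(n_iter):
        for j in rng.permutation(incomplete):
            miss = m.mask[:, j]
            pred = predictors[j]
            if pred.size == 0:
                warnings.warn(
                    f"no predictor passes screening for "
                    f"{m.metabolite_ids[j]!r}; mean-imputed"
                )
                vals[miss, j] = col_means[j]
                continue
            X = np.column_stack([np.ones(m.n_samples), vals[:, pred]])
            y_obs = vals[~miss, j]
            beta_hat, beta_star, sigma_star = _bayes_lm_draw(
                X[~miss], y_obs, rng
            )
            if model == "norm":
                vals[miss, j] = X[miss] @ beta_star + sigma_star * (
                    rng.standard_normal(int(miss.sum()))
                )
            elif model == "pmm":
                # type-1 matching: observed predicted with beta_hat,
                # missing predicted with the posterior draw beta_star
                pred_obs = X[~miss] @ beta_hat
                pred_mis = X[miss] @ beta_star
                order = np.argsort(
                    np.abs(pred_obs[None, :] - pred_mis[:, None]),
                    axis=1,
                    kind="stable",
                )
                k_pool = min(PMM_DONORS, pred_obs.size)
                donors = order[:, :k_pool]
                pick = rng.integers(0, k_pool, size=donors.shape[0])
                vals[miss, j] = y_obs[donors[np.arange(len(pick)), pick]]
            else:  # adjR
                resid = y_obs - X[~miss] @ beta_hat
                b = _runday_intercepts(resid, m.runday[~miss], rng)
                day_shift = np.asarray(
                    [b.get(d, 0.0) for d in m.runday[miss]]
                )
                vals[miss, j] = (
                    X[miss] @ beta_star
                    + day_shift
                    + sigma_star * rng.standard_normal(int(miss.sum()))
                )
    return _new_imputed(m, [vals], f"ICE-{model}", seed=seed)


def mice_impute(
    m: MetaboliteMatrix,
    model: str = "norm",
    m_imputations: int = DEFAULT_M,
    n_iter: int = 10,
    predictor_min_corr: float = 0.0,
    seed: int | None = None,
) -> ImputedData:
    """m parallel independent ICE chains (estimates pooled downstream)."""
    rng = np.random.default_rng(seed)
    fills = []
    for _ in range(m_imputations):
        chain = ice_impute(
            m,
            model=model,
            n_iter=n_iter,
            predictor_min_corr=predictor_min_corr,
            rng=np.random.default_rng(int(rng.integers(2**31 - 1))),
        )
        fills.append(chain.single())
    return _new_imputed(m, fills, f"MICE-{model}", seed=seed)


def mice_avg(
    m: MetaboliteMatrix,
    model: str = "norm",
    m_imputations: int = DEFAULT_M,
    n_iter: int = 10,
    predictor_min_corr: float = 0.0,
    seed: int | None = None,
) -> ImputedData:
    """Cellwise average of m ICE fills, returned as a single dataset.

    Popular for its simplicity, but averaging shrinks the within-cell
    variability, so downstream variances are underestimated.
    """
    if model not in ("norm", "pmm"):
        raise ValueError("MICE-avg supports norm and pmm")
    multi = mice_impute(
        m,
        model=model,
        m_imputations=m_imputations,
        n_iter=n_iter,
        predictor_min_corr=predictor_min_corr,
        seed=seed,
    )
    avg = np.mean(multi.fills, axis=0)
    avg[~m.mask] = m.values[~m.mask]
    return _new_imputed(m, [avg], f"MICE-avg-{model}", seed=seed)


# ---------------------------------------------------------------------------
# K-nearest neighbors


def _standardize(m: MetaboliteMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = np.empty(m.n_metabolites)
    sd = np.empty(m.n_metabolites)
    for j in range(m.n_metabolites):
        obs = m.observed(j)
        mu[j] = obs.mean()
        sd[j] = obs.std() if obs.std() > 0 else 1.0
    z = (m.values - mu) / sd
    return z, mu, sd


def _partial_distance(
    a: np.ndarray, b: np.ndarray, p_full: int
) -> float:
    """Euclidean distance over shared coordinates, rescaled to p_full dims."""
    both = ~np.isnan(a) & ~np.isnan(b)
    p_shared = int(both.sum())
    if p_shared == 0:
        return np.inf
    ss = float(np.sum((a[both] - b[both]) ** 2))
    return float(np.sqrt(p_full / p_shared * ss))


def _select_columns(
    m: MetaboliteMatrix, j: int, cfg: KnnConfig
) -> np.ndarray:
    """obs-sel variable pre-selection for target column j.

    Rank candidates by |pairwise-complete correlation| with the target; keep
    those >= sel_corr, constrained to [sel_min, sel_max] columns (topping up
    with the best-ranked below the cutoff when fewer than sel_min pass).
    """
    x = m.values[:, j]
    scored = []
    for other in range(m.n_metabolites):
        if other == j:
            continue
        both = ~np.isnan(x) & ~m.mask[:, other]
        if both.sum() < 3:
            continue
        xs, ys = x[both], m.values[both, other]
        if xs.std() == 0 or ys.std() == 0:
            continue
        scored.append((abs(float(np.corrcoef(xs, ys)[0, 1])), -other))
    scored.sort(reverse=True)
    ranked = [-o for _, o in scored]
    passing = sum(1 for r, _ in scored if r >= cfg.sel_corr)
    take = min(max(passing, cfg.sel_min), cfg.sel_max, len(ranked))
    return np.asarray(ranked[:take], dtype=int)


def knn_impute(
    m: MetaboliteMatrix, cfg: KnnConfig, seed: int | None = None
) -> ImputedData:
    """KNN imputation in one of the three neighbor definitions.

    Columns are standardized by their observed mean/SD before distances so
    the ``e^(-d)`` weights are scale-free; fills are returned on the
    original scale.  Neighbor ties at equal distance break by index.
    """
    z, mu, sd = _standardize(m)
    p = m.n_metabolites
    n = m.n_samples
    out = z.copy()
    method = f"KNN-{cfg.mode}({cfg.k})"

    if cfg.mode == "var":
        # pairwise column distances over rows where both observed
        col_dist = np.full((p, p), np.inf)
        for a in range(p):
            for b in range(a + 1, p):
                d = _partial_distance(z[:, a], z[:, b], p_full=n)
                col_dist[a, b] = col_dist[b, a] = d
        for j in range(p):
            miss_rows = np.nonzero(m.mask[:, j])[0]
            if miss_rows.size == 0:
                continue
            order = np.argsort(col_dist[j], kind="stable")
            for i in miss_rows:
                elig = [c for c in order
                        if np.isfinite(col_dist[j, c]) and not m.mask[i, c]]
                if not elig:
                    warnings.warn(
                        f"{method}: no eligible neighbor for cell "
                        f"({m.sample_ids[i]}, {m.metabolite_ids[j]}); "
                        "column-mean fallback"
                    )
                    out[i, j] = 0.0  # standardized column mean
                    continue
                if len(elig) < cfg.k:
                    warnings.warn(
                        f"{method}: fewer than K eligible neighbors; "
                        "using all available"
                    )
                use = np.asarray(elig[: cfg.k])
                w = np.exp(-col_dist[j, use])
                out[i, j] = float(np.sum(w * z[i, use]) / np.sum(w))
    else:
        sel: dict[int, np.ndarray] = {}
        if cfg.mode == "obs-sel":
            for j in range(p):
                if m.mask[:, j].any():
                    sel[j] = _select_columns(m, j, cfg)
        for j in range(p):
            miss_rows = np.nonzero(m.mask[:, j])[0]
            if miss_rows.size == 0:
                continue
            feat = sel.get(j) if cfg.mode == "obs-sel" else np.asarray(
                [c for c in range(p) if c != j], dtype=int
            )
            if feat is None or feat.size == 0:
                warnings.warn(
                    f"{method}: no selectable variable for "
                    f"{m.metabolite_ids[j]!r}; column-mean fallback"
                )
                out[miss_rows, j] = 0.0
                continue
            donor_rows = np.nonzero(~m.mask[:, j])[0]
            donor_block = z[np.ix_(donor_rows, feat)]
            donor_valid = ~np.isnan(donor_block)
            for i in miss_rows:
                zi = z[i, feat]
                valid = ~np.isnan(zi)[None, :] & donor_valid
                diff = np.where(valid, donor_block - zi[None, :], 0.0)
                p_shared = valid.sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    dists = np.sqrt(
                        feat.size / p_shared * (diff**2).sum(axis=1)
                    )
                dists[p_shared == 0] = np.inf
                finite = np.isfinite(dists)
                if not finite.any():
                    warnings.warn(
                        f"{method}: no eligible neighbor for cell "
                        f"({m.sample_ids[i]}, {m.metabolite_ids[j]}); "
                        "column-mean fallback"
                    )
                    out[i, j] = 0.0
                    continue
                cand = donor_rows[finite]
                cd = dists[finite]
                if cand.size < cfg.k:
                    warnings.warn(
                        f"{method}: fewer than K eligible neighbors; "
                        "using all available"
                    )
                order = np.lexsort((cand, cd))[: cfg.k]
                w = np.exp(-cd[order])
                out[i, j] = float(
                    np.sum(w * z[cand[order], j]) / np.sum(w)
                )
    vals = out * sd + mu
    vals[~m.mask] = m.values[~m.mask]
    return _new_imputed(m, [vals], method, seed=seed)
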