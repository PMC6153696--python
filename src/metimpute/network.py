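"""Gaussian graphical models and pathway-based modularity.

A GGM draws an edge between two metabolites when their partial correlation
(conditioning on all other metabolites) differs significantly from zero.
Partial correlations come from the inverse of a shrinkage-regularized
correlation matrix (analytic shrinkage toward the identity, which keeps the
estimate well-conditioned when metabolites outnumber or approach the sample
count); significance uses the Fisher-z statistic with effective degrees of
freedom ``n - 3 - (p - 2)``, Bonferroni-corrected over all p(p-1)/2 pairs.

Biochemical pathways partition the metabolites, and a biologically faithful
network concentrates its edges within pathways.  The Newman–Girvan
modularity

    Q = sum_i [ A(V_i, V_i)/A(V, V) - (A(V_i, V)/A(V, V))^2 ]

(with A(X, Y) the number of adjacency entries between node sets, so
A(V, V) = 2·#edges) scores that concentration and serves as the evaluation
criterion for imputation methods on real-structured data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lod import ImputedData
from .matrix import MetaboliteMatrix, PathwayAnnotation
from .pooling import pool_correlation_fisher
from .registry import apply_method

__all__ = [
    "GGMNetwork",
    "ModularityResult",
    "estimate_ggm",
    "modularity_q",
    "bootstrap_q",
]


@dataclass
class GGMNetwork:
    partial_corr: np.ndarray
    p_values: np.ndarray
    adjacency: np.ndarray
    metabolite_ids: list[str]
    n_samples: int
    alpha: float
    shrinkage: float

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class ModularityResult:
    q: float
    per_pathway: dict[str, float]
    ci: tuple[float, float] | None = None
    n_bootstrap: int = 0
    n_failed: int = 0


def _shrinkage_correlation(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Analytic optimal shrinkage of the correlation matrix toward identity.

    lambda* = sum of estimated variances of the off-diagonal correlations
    over the sum of their squares (clipped to [0, 1]).
    """
    n, p = x.shape
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = (xs.T @ xs) / (n - 1)
    np.fill_diagonal(r, 1.0)
    # var_hat(r_ij) from the empirical variance of the score products
    w_bar = r * (n - 1) / n
    var_sum = 0.0
    r2_sum = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            w = xs[:, i] * xs[:, j]
            var_sum += n / (n - 1) ** 3 * np.sum((w - w_bar[i, j]) ** 2)
            r2_sum += r[i, j] ** 2
    lam = 1.0 if r2_sum == 0 else float(np.clip(var_sum / r2_sum, 0.0, 1.0))
    return (1 - lam) * r + lam * np.eye(p), lam


def _partial_from_corr(r: np.ndarray) -> np.ndarray:
    prec = np.linalg.inv(r)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def estimate_ggm(
    d: ImputedData | MetaboliteMatrix,
    alpha: float = 0.05,
    shrink: bool = True,
) -> GGMNetwork:
    """Estimate a GGM from completed data (pooled over fills if multiple).

    ``shrink=False`` uses the raw correlation matrix and falls back to
    shrinkage automatically (with a warning) when it is singular.
    """
    if isinstance(d, MetaboliteMatrix):
        if d.mask.any():
            raise ValueError("estimate_ggm needs complete data; impute first")
        fills = [d.values]
        ids = list(d.metabolite_ids)
        n = d.n_samples
    else:
        fills = d.fills
        ids = list(d.metabolite_ids)
        n = fills[0].shape[0]
    p = len(ids)
    k = p - 2  # conditioned variables per pair
    if n <= 3 + k:
        raise ValueError(
            f"n={n} too small for partial correlations among p={p} variables"
        )
    pcs = []
    lam_used = 0.0
    for f in fills:
        if shrink:
            r, lam = _shrinkage_correlation(f)
        else:
            r = np.corrcoef(f, rowvar=False)
            lam = 0.0
            if np.linalg.cond(r) > 1e10:
                warnings.warn("singular correlation matrix; shrinkage applied")
                r, lam = _shrinkage_correlation(f)
        lam_used = max(lam_used, lam)
        pcs.append(_partial_from_corr(r))
    if len(pcs) == 1:
        pc = pcs[0]
        z = np.arctanh(np.clip(pc, -1 + 1e-12, 1 - 1e-12)) * np.sqrt(n - 3 - k)
        pvals = 2 * stats.norm.sf(np.abs(z))
    else:
        pc = np.eye(p)
        pvals = np.zeros((p, p))
        stack = np.stack(pcs)
        for i in range(p):
            for j in range(i + 1, p):
                rs = np.clip(stack[:, i, j], -1 + 1e-12, 1 - 1e-12)
                pooled = pool_correlation_fisher(rs, n_eff=n, k=k)
                pc[i, j] = pc[j, i] = pooled.qbar
                pvals[i, j] = pvals[j, i] = pooled.p
    np.fill_diagonal(pvals, 1.0)
    n_tests = p * (p - 1) / 2
    adjacency = pvals < alpha / n_tests
    np.fill_diagonal(adjacency, False)
    adjacency &= adjacency.T
    return GGMNetwork(
        partial_corr=pc,
        p_values=pvals,
        adjacency=adjacency,
        metabolite_ids=ids,
        n_samples=n,
        alpha=alpha,
        shrinkage=lam_used,
    )


def modularity_q(net: GGMNetwork, ann: PathwayAnnotation) -> ModularityResult:
    """Pathway-based modularity Q of a network.

    Unannotated metabolites are dropped before scoring; a network with zero
    edges among annotated metabolites has no defined Q.
    """
    keep = [i for i, mid in enumerate(net.metabolite_ids) if mid in ann.mapping]
    if not keep:
        raise ValueError("no annotated metabolite in the network")
    ids = [net.metabolite_ids[i] for i in keep]
    a = net.adjacency[np.ix_(keep, keep)].astype(float)
    total = a.sum()  # = 2 * number of edges
    if total == 0:
        raise ValueError("network has no edges; Q undefined")
    per_pathway: dict[str, float] = {}
    q = 0.0
    groups: dict[str, list[int]] = {}
    for idx, mid in enumerate(ids):
        groups.setdefault(ann.pathway(mid), []).append(idx)
    for pw, members in groups.items():
        mem = np.asarray(members)
        within = a[np.ix_(mem, mem)].sum()
        degree = a[mem, :].sum()
        term = within / total - (degree / total) ** 2
        per_pathway[pw] = float(term)
        q += term
    return ModularityResult(q=float(q), per_pathway=per_pathway)


def bootstrap_q(
    m: MetaboliteMatrix,
    ann: PathwayAnnotation,
    method_id: str,
    b: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    shrink: bool = True,
) -> ModularityResult:
    """Point estimate and percentile bootstrap CI of Q for one method.

    Resamples samples with replacement ``b`` times, re-imputes, re-estimates
    the network and re-scores Q; failed replicates (e.g. zero-edge networks)
    are dropped and counted.
    """
    obs_sd = np.nanstd(m.values, axis=0)
    if np.any(obs_sd == 0):
        raise ValueError("zero-variance metabolite; bootstrap rejected")
    rng = np.random.default_rng(seed)

    def q_of(mat: MetaboliteMatrix, sub_seed: int) -> float:
        d = apply_method(mat, method_id, seed=sub_seed)
        net = estimate_ggm(d if d is not None else mat, alpha=alpha,
                           shrink=shrink)
        return modularity_q(net, ann).q

    point = q_of(m, int(rng.integers(2**31 - 1)))
    qs = []
    n_failed = 0
    for _ in range(b):
        rows = rng.integers(0, m.n_samples, size=m.n_samples)
        boot = MetaboliteMatrix(
            m.values[rows],
            m.mask[rows],
            [f"B{i}" for i in range(m.n_samples)],
            m.metabolite_ids,
            m.runday[rows],
            scale=m.scale,
        )
        try:
            qs.append(q_of(boot, int(rng.integers(2**31 - 1))))
        except Exception:
            n_failed += 1
    if qs:
        lo, hi = np.percentile(qs, [2.5, 97.5])
        lo, hi = min(lo, point), max(hi, point)
        ci = (float(lo), float(hi))
    else:
        ci = None
    per = modularity_q(
        estimate_ggm(
            apply_method(m, method_id, seed=int(rng.integers(2**31 - 1)))
            or m,
            alpha=alpha,
            shrink=shrink,
        ),
        ann,
    ).per_pathway
    return ModularityResult(
        q=point, per_pathway=per, ci=ci, n_bootstrap=len(qs), n_failed=n_failed
    )
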