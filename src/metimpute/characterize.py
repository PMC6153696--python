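"""Diagnostics of missing-value patterns.

Two mechanisms dominate missingness in untargeted MS metabolomics: values
below the limit of detection (LOD; left-censoring, missing-not-at-random)
and run-day (batch) effects that shift the effective LOD from day to day.
Because the censored values themselves are unobservable, LOD tendency is
diagnosed indirectly through an *auxiliary* metabolite — the most strongly
correlated partner of the target.  If the auxiliary's values are
systematically lower in samples where the target is missing, the target's
missing values most likely sat below the LOD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import MetaboliteMatrix

__all__ = [
    "AuxiliaryResult",
    "RunDayMissingness",
    "find_auxiliary",
    "lod_tendency_test",
    "runday_missingness_profile",
    "runday_mean_missingness_correlation",
]


@dataclass
class AuxiliaryResult:
    """Auxiliary-metabolite diagnosis for one target metabolite."""

    target: str
    auxiliary: str | None
    r: float
    p_wst: float = np.nan
    lod_tendency: bool | None = None


@dataclass
class RunDayMissingness:
    """Per run-day missingness statistics for all metabolites.

    ``normalized[m, d]`` is the missing fraction of metabolite ``m`` on day
    ``d`` divided by the median of that metabolite's per-day missing
    fractions, so 1 means "an average day for this metabolite".
    """

    metabolite_ids: list[str]
    rundays: list[object]
    raw_fraction: np.ndarray          # metabolites × days
    normalized: np.ndarray            # metabolites × days, NaN if undefined
    sd_across_days: np.ndarray        # per metabolite, of raw fractions


def _pairwise_complete_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    both = ~np.isnan(x) & ~np.isnan(y)
    n = int(both.sum())
    if n < 3:
        return np.nan, n
    xs, ys = x[both], y[both]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan, n
    return float(np.corrcoef(xs, ys)[0, 1]), n


def find_auxiliary(
    m: MetaboliteMatrix, target: str, min_corr: float = 0.3
) -> AuxiliaryResult | None:
    """Best-correlated partner of ``target`` with correlation >= ``min_corr``.

    Correlations use pairwise-complete observations (at least 3 shared
    points).  Ties are broken toward the lowest column index so the result
    is deterministic.  Returns ``None`` when no candidate reaches the
    cutoff.
    """
    jt = m.column(target)
    x = m.values[:, jt]
    best_j, best_r = None, -np.inf
    any_shared = False
    for j in range(m.n_metabolites):
        if j == jt:
            continue
        r, n = _pairwise_complete_corr(x, m.values[:, j])
        if n >= 3:
            any_shared = True
        if np.isnan(r):
            continue
        if r > best_r:
            best_j, best_r = j, r
    if not any_shared:
        warnings.warn(
            f"{target}: fewer than 3 shared observations with every candidate"
        )
        return None
    if best_j is None or best_r < min_corr:
        return None
    return AuxiliaryResult(target, m.metabolite_ids[best_j], best_r)


def lod_tendency_test(
    m: MetaboliteMatrix,
    target: str,
    aux: str,
    alpha: float = 0.05,
    family_size: int = 1,
    alternative: str = "less",
) -> AuxiliaryResult:
    """Wilcoxon–Mann–Whitney test for LOD tendency of ``target``.

    Compares auxiliary values in samples where the target is missing against
    samples where it is observed.  One-sided by default (``"less"``: aux
    values are *lower* where the target is missing, the signature of
    left-censoring).  The decision flag applies a Bonferroni correction
    over ``family_size`` tests.
    """
    jt, ja = m.column(target), m.column(aux)
    aux_vals = m.values[:, ja]
    grp_missing = aux_vals[m.mask[:, jt] & ~m.mask[:, ja]]
    grp_observed = aux_vals[~m.mask[:, jt] & ~m.mask[:, ja]]
    if grp_missing.size == 0 or grp_observed.size == 0:
        raise ValueError(
            f"{target}/{aux}: auxiliary must be observed in both groups"
        )
    if np.all(grp_missing == grp_missing[0]) and np.all(
        grp_observed == grp_missing[0]
    ):
        p = 1.0  # ties only: no evidence either way
    else:
        p = float(
            stats.mannwhitneyu(
                grp_missing, grp_observed, alternative=alternative
            ).pvalue
        )
    r, _ = _pairwise_complete_corr(m.values[:, jt], aux_vals)
    return AuxiliaryResult(
        target, aux, r, p_wst=p, lod_tendency=bool(p < alpha / max(family_size, 1))
    )


def runday_missingness_profile(m: MetaboliteMatrix) -> RunDayMissingness:
    """Raw and normalized per run-day missing fractions for every metabolite.

    ``normalized = (missing on day / samples on day) / median over days``;
    undefined (NaN, with a warning) when the median per-day missingness of a
    metabolite is zero.
    """
    groups = m.runday_groups()
    if len(groups) < 2:
        raise ValueError("need at least 2 run days")
    days = list(groups)
    raw = np.empty((m.n_metabolites, len(days)))
    for k, d in enumerate(days):
        raw[:, k] = m.mask[groups[d], :].mean(axis=0)
    med = np.median(raw, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = raw / med[:, None]
    normalized[med == 0, :] = np.nan
    if np.any(med == 0):
        zero = [m.metabolite_ids[j] for j in np.nonzero(med == 0)[0]]
        warnings.warn(
            f"median run-day missingness is 0 for {len(zero)} metabolite(s); "
            "normalized missingness undefined there"
        )
    return RunDayMissingness(
        metabolite_ids=list(m.metabolite_ids),
        rundays=days,
        raw_fraction=raw,
        normalized=normalized,
        sd_across_days=raw.std(axis=1, ddof=1),
    )


def runday_mean_missingness_correlation(
    m: MetaboliteMatrix, target: str
) -> float:
    """Pearson correlation across run days of day mean vs day missing fraction.

    A strongly negative value is the fingerprint of a run-day-dependent LOD:
    days on which the instrument reads low also lose more values below the
    detection limit.
    """
    j = m.column(target)
    means, fracs = [], []
    for rows in m.runday_groups().values():
        obs = rows[~m.mask[rows, j]]
        if obs.size == 0:
            continue
        means.append(m.values[obs, j].mean())
        fracs.append(m.mask[rows, j].mean())
    if len(means) < 3:
        raise ValueError(f"{target}: need >=3 run days with observed values")
    means_a, fracs_a = np.asarray(means), np.asarray(fracs)
    if np.ptp(means_a) == 0 or np.ptp(fracs_a) == 0:
        warnings.warn(f"{target}: zero variance across run days")
        return np.nan
    return float(np.corrcoef(means_a, fracs_a)[0, 1])
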