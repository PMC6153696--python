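"""Statistical evaluation of imputation methods on simulated data.

For each scenario × method the experiment measures, over repeated
simulations, whether downstream analyses on the imputed data keep their
nominal operating characteristics:

* type-1 error — fraction of null (rho = 0) replicates declared significant
  at level alpha;
* power — fraction of alternative (rho > 0) replicates declared significant;
* bias — mean difference between the estimate and the generating truth.

Analyses are Pearson correlation, partial correlation of the main pair
given the auxiliaries, linear regression, and logistic regression on the
median-dichotomized second main variable.  Multiply imputed data are
analyzed per fill and pooled by Rubin's rules (correlations on the Fisher-z
scale); the CCA baseline deletes incomplete rows before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lod import ImputedData
from .matrix import MetaboliteMatrix
from .pooling import pool_correlation_fisher, rubin_pool
from .registry import apply_method
from .simulate import (
    SimulationScenario,
    dichotomize_at_median,
    introduce_missingness,
    simulate_complete,
)

__all__ = ["AnalysisResult", "ScenarioReport", "analyze", "run_scenario",
           "true_partial_correlation"]

ANALYSES = ("pearson", "partial", "linreg", "logreg")


@dataclass
class AnalysisResult:
    estimate: float
    variance: float
    p: float
    n: int
    failed: bool = False


@dataclass
class ScenarioReport:
    """Tidy per-(method, analysis) metrics for one scenario."""

    scenario: SimulationScenario
    table: pd.DataFrame  # columns: method, analysis, type1, power, bias, ...
    alpha: float
    n_sim: int


def _complete_rows(values: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ~np.isnan(values[:, cols]).any(axis=1)


def _partial_corr(values: np.ndarray) -> float:
    """Partial correlation of columns 0 and 1 given the rest."""
    c = np.corrcoef(values, rowvar=False)
    prec = np.linalg.inv(c)
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def true_partial_correlation(s: SimulationScenario) -> float:
    """Generating partial correlation of the mains given all auxiliaries."""
    p = 2 + 2 * s.n_aux
    c2 = s.aux_corr**2
    sigma = np.eye(p)
    sigma[0, 1] = sigma[1, 0] = s.rho
    for k, main in enumerate((0, 1)):
        lo = 2 + k * s.n_aux
        block = slice(lo, lo + s.n_aux)
        sigma[main, block] = sigma[block, main] = s.aux_corr
        sigma[1 - main, block] = sigma[block, 1 - main] = s.rho * s.aux_corr
        sigma[block, block] = c2 + (1 - c2) * np.eye(s.n_aux)
    b1 = slice(2, 2 + s.n_aux)
    b2 = slice(2 + s.n_aux, p)
    sigma[b1, b2] = s.rho * c2
    sigma[b2, b1] = s.rho * c2
    prec = np.linalg.inv(sigma)
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def _analyze_single(
    values: np.ndarray, analysis: str, n_min: int = 10
) -> AnalysisResult:
    """One analysis on one complete (n × p) array; columns 0,1 are the mains."""
    n = values.shape[0]
    if n < n_min:
        raise ValueError(f"need >= {n_min} effective observations, got {n}")
    x, y = values[:, 0], values[:, 1]
    if analysis == "pearson":
        r, p = stats.pearsonr(x, y)
        return AnalysisResult(float(r), 1.0 / (n - 3), float(p), n)
    if analysis == "partial":
        k = values.shape[1] - 2
        r = _partial_corr(values)
        se_z = 1.0 / np.sqrt(n - 3 - k)
        z = np.arctanh(r) / se_z
        return AnalysisResult(
            float(r), se_z**2, float(2 * stats.norm.sf(abs(z))), n
        )
    if analysis == "linreg":
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        return AnalysisResult(
            float(fit.params[1]), float(fit.bse[1] ** 2), float(fit.pvalues[1]), n
        )
    if analysis == "logreg":
        resp = dichotomize_at_median(y)
        X = sm.add_constant(x)
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(resp, X).fit(disp=0, maxiter=100)
                converged = bool(fit.mle_retvals.get("converged", True))
            except Exception:
                converged = False
        if fit is None or not converged or not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
            return AnalysisResult(np.nan, np.nan, np.nan, n, failed=True)
        return AnalysisResult(
            float(fit.params[1]), float(fit.bse[1] ** 2), float(fit.pvalues[1]), n
        )
    raise ValueError(f"unknown analysis {analysis!r}; one of {ANALYSES}")


def analyze(
    d: ImputedData | MetaboliteMatrix,
    analysis: str,
    main_cols: tuple[str, str] = ("M1", "M2"),
) -> AnalysisResult:
    """Run one analysis on imputed data (pooled if multiple) or a matrix.

    A :class:`MetaboliteMatrix` with missing cells is treated as the CCA
    baseline: rows incomplete in the analyzed columns are deleted.  Partial
    correlation conditions on every column beyond the two mains.
    """
    if isinstance(d, MetaboliteMatrix):
        j0, j1 = d.column(main_cols[0]), d.column(main_cols[1])
        others = [j for j in range(d.n_metabolites) if j not in (j0, j1)]
        use = [j0, j1] + (others if analysis == "partial" else [])
        cols = np.asarray(use)
        rows = _complete_rows(d.values, cols)
        return _analyze_single(d.values[np.ix_(rows, cols)], analysis)

    j0, j1 = d.column(main_cols[0]), d.column(main_cols[1])
    others = [j for j in range(len(d.metabolite_ids)) if j not in (j0, j1)]
    use = [j0, j1] + (others if analysis == "partial" else [])
    cols = np.asarray(use)
    per_fill = [_analyze_single(f[:, cols], analysis) for f in d.fills]
    if any(r.failed for r in per_fill):
        return AnalysisResult(np.nan, np.nan, np.nan, per_fill[0].n, failed=True)
    if len(per_fill) == 1:
        return per_fill[0]
    n = per_fill[0].n
    if analysis in ("pearson", "partial"):
        k = len(others) if analysis == "partial" else 0
        rs = np.asarray([r.estimate for r in per_fill])
        rs = np.clip(rs, -1 + 1e-12, 1 - 1e-12)
        pooled = pool_correlation_fisher(rs, n_eff=n, k=k)
    else:
        pooled = rubin_pool(
            np.asarray([r.estimate for r in per_fill]),
            np.asarray([r.variance for r in per_fill]),
        )
    return AnalysisResult(pooled.qbar, pooled.T, pooled.p, n)


def _truths(s: SimulationScenario) -> dict[str, float]:
    return {
        "pearson": s.rho,
        # unit variances: the regression slope equals the correlation
        "linreg": s.rho,
        "partial": true_partial_correlation(s),
        "logreg": np.nan,  # generating log-odds scale has no closed truth here
    }


def run_scenario(
    s: SimulationScenario,
    methods: list[str],
    n_sim: int = 250,
    alpha: float = 0.05,
    seed: int | None = None,
    analyses: tuple[str, ...] = ANALYSES,
    target_columns: tuple[str, ...] = ("M1", "M2"),
    predictor_min_corr: float = 0.0,
    include_null: bool = True,
) -> ScenarioReport:
    """Simulate, impute and analyze ``n_sim`` replicates per truth condition.

    Each replicate runs a null twin (rho = 0, feeding the type-1 error) and,
    when the scenario's rho is positive, the alternative (feeding power);
    bias is measured on the alternative replicates against the generating
    values.  Replicates on which a method fails are dropped for that method
    only and counted.
    """
    master = np.random.default_rng(seed)
    conditions = [("null", 0.0)] if include_null else []
    if s.rho > 0:
        conditions.append(("alt", s.rho))
    records: dict[tuple[str, str, str], list[AnalysisResult]] = {}
    failures: dict[tuple[str, str, str], int] = {}

    for rep in range(n_sim):
        rep_seed = int(master.integers(2**31 - 1))
        for label, rho in conditions:
            rng = np.random.default_rng((rep_seed, 0 if label == "null" else 1))
            sc = replace(s, rho=rho, seed=None)
            mat, _ = simulate_complete(sc, rng=rng)
            if s.missing_proportion > 0:
                mat = introduce_missingness(
                    mat, sc, target_columns=list(target_columns), rng=rng
                )
            for method in methods:
                key_seed = int(rng.integers(2**31 - 1))
                try:
                    d = apply_method(
                        mat, method, seed=key_seed,
                        predictor_min_corr=predictor_min_corr,
                    )
                except Exception:
                    for analysis in analyses:
                        failures[(method, analysis, label)] = (
                            failures.get((method, analysis, label), 0) + 1
                        )
                    continue
                data = mat if d is None else d
                for analysis in analyses:
                    key = (method, analysis, label)
                    try:
                        res = analyze(data, analysis)
                    except Exception:
                        failures[key] = failures.get(key, 0) + 1
                        continue
                    if res.failed:
                        failures[key] = failures.get(key, 0) + 1
                        continue
                    records.setdefault(key, []).append(res)

    truths_alt = _truths(s)
    rows = []
    for method in methods:
        for analysis in analyses:
            null_res = records.get((method, analysis, "null"), [])
            alt_res = records.get((method, analysis, "alt"), [])
            type1 = (
                float(np.mean([r.p < alpha for r in null_res]))
                if null_res
                else np.nan
            )
            power = (
                float(np.mean([r.p < alpha for r in alt_res]))
                if alt_res
                else np.nan
            )
            truth = truths_alt[analysis]
            bias = (
                float(np.mean([r.estimate - truth for r in alt_res]))
                if alt_res and np.isfinite(truth)
                else np.nan
            )
            n_failed = failures.get((method, analysis, "null"), 0) + failures.get(
                (method, analysis, "alt"), 0
            )
            rows.append(
                {
                    "method": method,
                    "analysis": analysis,
                    "mechanism": s.mechanism,
                    "proportion": s.missing_proportion,
                    "n": s.n,
                    "type1": type1,
                    "power": power,
                    "bias": bias,
                    "n_failed": n_failed,
                }
            )
    return ScenarioReport(
        scenario=s, table=pd.DataFrame(rows), alpha=alpha, n_sim=n_sim
    )
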