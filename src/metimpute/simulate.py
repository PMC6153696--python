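"""Synthetic data generation: complete matrices, run-day labels and the six
missingness mechanisms.

The generative design mirrors a typical untargeted-MS study: two "main"
metabolites drawn from a standard bivariate normal with correlation ``rho``
(0 to 0.4, the realistic range for metabolite pairs across pathways), each
accompanied by a block of auxiliary metabolites correlated with it, all
standardized (mean 0, variance 1).  Samples are assigned to run days of ~34
observations, the average batch size of a large cohort measured over weeks.

Missingness mechanisms (injected into the main pair):

``fixed_lod``
    a single global detection limit: exactly the lowest q·n values are lost.
``prob_lod``
    a blurred limit: P(missing | x) = Φ((c − x)/blur), the probability of
    loss rising smoothly at lower abundances.
``runday_fixed_lod`` / ``runday_prob_lod``
    the same with a run-day effect: instrument sensitivity drifts between
    days, so the recorded values acquire a day-level shift
    δ_d ~ N(0, runday_lod_sd²) while the detection limit stays put —
    equivalently, the effective LOD relative to the true concentrations is
    day-specific (c_d = c − δ_d).  Low-sensitivity days therefore read low
    *and* lose more values, reproducing the negative day-mean/day-missingness
    correlation observed in real data.
``random``
    missing completely at random.
``mixture``
    each lost cell follows runday_prob_lod with probability
    ``mixture_weight`` and the random mechanism otherwise.

All mechanisms are calibrated so the overall missing fraction equals the
requested proportion exactly (fixed variants) or in expectation (probabilistic
variants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .matrix import MetaboliteMatrix

__all__ = [
    "SimulationScenario",
    "MECHANISMS",
    "simulate_complete",
    "assign_rundays",
    "introduce_missingness",
    "dichotomize_at_median",
    "simulate_snp_fixture",
]

MECHANISMS = (
    "fixed_lod",
    "prob_lod",
    "runday_fixed_lod",
    "runday_prob_lod",
    "random",
    "mixture",
)


@dataclass
class SimulationScenario:
    """Parameters of one simulated data condition."""

    n: int = 250
    rho: float = 0.3
    missing_proportion: float = 0.3
    mechanism: str = "runday_prob_lod"
    runday_size: int = 34
    n_aux: int = 3
    aux_corr: float = 0.5
    runday_lod_sd: float = 0.3
    blur: float = 0.5
    mixture_weight: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; one of {MECHANISMS}"
            )
        if not 0 <= self.missing_proportion < 1:
            raise ValueError("missing_proportion must be in [0, 1)")
        if self.runday_size < 1:
            raise ValueError("runday_size must be >= 1")


def simulate_complete(
    s: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[MetaboliteMatrix, dict]:
    """Draw one complete dataset for a scenario.

    Returns an ``n × (2 + 2·n_aux)`` matrix (columns ``M1, M2, A1_*, A2_*``)
    with zero means, unit variances, main-pair correlation ``rho`` and each
    auxiliary at ``aux_corr`` with its main, plus a ground-truth record.

    The joint distribution is the multivariate normal realized by the factor
    construction ``aux = aux_corr·main + sqrt(1−aux_corr²)·noise``, which is
    positive definite whenever |rho| < 1 and |aux_corr| < 1.
    """
    if abs(s.rho) >= 1 or abs(s.aux_corr) >= 1:
        raise ValueError(
            f"covariance for rho={s.rho}, aux_corr={s.aux_corr} "
            "is not positive definite"
        )
    if rng is None:
        rng = np.random.default_rng(s.seed)
    n = s.n
    z = rng.standard_normal((n, 2))
    m1 = z[:, 0]
    m2 = s.rho * z[:, 0] + np.sqrt(1 - s.rho**2) * z[:, 1]
    cols = [m1, m2]
    names = ["M1", "M2"]
    lam = np.sqrt(1 - s.aux_corr**2)
    for k, main in enumerate((m1, m2), start=1):
        for a in range(s.n_aux):
            noise = rng.standard_normal(n)
            cols.append(s.aux_corr * main + lam * noise)
            names.append(f"A{k}_{a + 1}")
    values = np.column_stack(cols)
    runday = assign_rundays(n, s.runday_size, rng=rng)
    mat = MetaboliteMatrix(
        values,
        np.zeros(values.shape, dtype=bool),
        [f"S{i + 1}" for i in range(n)],
        names,
        runday,
        scale="log",
    )
    truth = {"rho": s.rho, "aux_corr": s.aux_corr, "n_aux": s.n_aux}
    return mat, truth


def assign_rundays(
    n: int,
    runday_size: int = 34,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Randomly partition ``n`` samples into run days of ~``runday_size``.

    The number of days is ``round(n / runday_size)`` (at least 1); sizes are
    as even as possible, with the remainder spread one sample per day.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_days = max(1, round(n / runday_size))
    base, extra = divmod(n, n_days)
    sizes = [base + 1 if d < extra else base for d in range(n_days)]
    labels = np.concatenate(
        [np.full(sz, f"D{d + 1}", dtype=object) for d, sz in enumerate(sizes)]
    )
    return labels[rng.permutation(n)]


def _solve_prob_lod_threshold(x: np.ndarray, q: float, blur: float) -> float:
    """Bisection for c with mean_i Φ((c − x_i)/blur) = q."""

    def frac(c: float) -> float:
        return float(stats.norm.cdf((c - x) / blur).mean())

    lo = float(x.min() - 10 * blur)
    hi = float(x.max() + 10 * blur)
    return float(optimize.brentq(lambda c: frac(c) - q, lo, hi, xtol=1e-12))


def _mask_lowest(x: np.ndarray, k: int) -> np.ndarray:
    mask = np.zeros(x.size, dtype=bool)
    if k > 0:
        mask[np.argsort(x, kind="stable")[:k]] = True
    return mask


def _day_offsets(
    runday: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    days = list(dict.fromkeys(runday))
    eps = {d: rng.normal(0.0, sd) for d in days}
    return np.asarray([eps[d] for d in runday])


def _column_mask(
    x: np.ndarray,
    runday: np.ndarray,
    s: SimulationScenario,
    mechanism: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask for one column; returns (mask, recorded values).

    Run-day mechanisms add the day sensitivity shift δ_d to the recorded
    values before thresholding at the (calibrated) global limit, so the day
    effect is visible in the data exactly as a batch effect would be.
    """
    q = s.missing_proportion
    n = x.size
    k = round(q * n)
    if mechanism == "fixed_lod":
        return _mask_lowest(x, k), x
    if mechanism == "prob_lod":
        c = _solve_prob_lod_threshold(x, q, s.blur)
        return rng.random(n) < stats.norm.cdf((c - x) / s.blur), x
    if mechanism == "runday_fixed_lod":
        y = x + _day_offsets(runday, s.runday_lod_sd, rng)
        return _mask_lowest(y, k), y
    if mechanism == "runday_prob_lod":
        y = x + _day_offsets(runday, s.runday_lod_sd, rng)
        c = _solve_prob_lod_threshold(y, q, s.blur)
        return rng.random(n) < stats.norm.cdf((c - y) / s.blur), y
    if mechanism == "random":
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        return mask, x
    if mechanism == "mixture":
        lod_mask, y = _column_mask(x, runday, s, "runday_prob_lod", rng)
        rand_mask, _ = _column_mask(y, runday, s, "random", rng)
        use_lod = rng.random(n) < s.mixture_weight
        return np.where(use_lod, lod_mask, rand_mask), y
    raise ValueError(f"unknown mechanism {mechanism!r}")


def introduce_missingness(
    m: MetaboliteMatrix,
    s: SimulationScenario,
    target_columns: list[str] | None = None,
    rng: np.random.Generator | None = None,
    mechanisms: dict[str, str] | None = None,
) -> MetaboliteMatrix:
    """Inject missing values into the target columns of a complete matrix.

    ``mechanisms`` optionally overrides the scenario mechanism per column
    (e.g. the logistic-regression design uses a mixture for the predictor
    only).  Columns not listed as targets stay complete.
    """
    if s.missing_proportion >= 1:
        raise ValueError("missing proportion must be < 1")
    if rng is None:
        rng = np.random.default_rng(s.seed)
    if target_columns is None:
        target_columns = ["M1", "M2"]
    out = m.copy()
    q = s.missing_proportion
    if q == 0:
        return out
    for name in target_columns:
        j = out.column(name)
        if out.mask[:, j].any():
            raise ValueError(f"target column {name!r} is not complete")
        if q * out.n_samples < 1:
            warnings.warn(
                f"{name}: q*n < 1, no cells masked"
            )
            continue
        mech = (mechanisms or {}).get(name, s.mechanism)
        col_mask, recorded = _column_mask(
            out.values[:, j], out.runday, s, mech, rng
        )
        out.values[:, j] = recorded
        out.mask[:, j] = col_mask
        out.values[col_mask, j] = np.nan
    return out


def dichotomize_at_median(x: np.ndarray) -> np.ndarray:
    """0/1 split at the median: 1 strictly above, 0 at or below.

    With continuous data at most one point sits exactly on the median, so
    the tie rule (median → 0) is measure-zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.all(x == x[0]):
        raise ValueError("all values identical; dichotomization undefined")
    return (x > np.median(x)).astype(int)


def simulate_snp_fixture(
    n: int,
    maf: float,
    beta1: float,
    seed: int | None = None,
    beta2: float = 0.01,
    beta3: float = 0.1,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Genotype/covariate/metabolite fixture for the SNP evaluation scheme.

    Additive model: ``metabolite = beta1·SNP + beta2·age + beta3·sex + ε``
    with genotype ~ Binomial(2, maf), age ~ N(61, 8.8²) (a typical adult
    cohort), sex ~ Bernoulli(0.5) coded 0/1.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)
    snp = rng.binomial(2, maf, size=n).astype(float)
    age = rng.normal(61.0, 8.8, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    metabolite = (
        beta1 * snp + beta2 * age + beta3 * sex + rng.normal(0, noise_sd, size=n)
    )
    return {
        "snp": snp,
        "age": age,
        "sex": sex,
        "metabolite": metabolite,
        "truth": {"beta1": beta1, "beta2": beta2, "beta3": beta3, "maf": maf},
    }
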