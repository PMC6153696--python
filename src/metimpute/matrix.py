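"""Data model, file I/O and preprocessing for metabolite abundance matrices.

The central container is :class:`MetaboliteMatrix`: a samples × metabolites
abundance table with an explicit boolean missingness mask and a per-sample
run-day (batch) label.  Untargeted MS runs of large cohorts are spread over
many run days; instrument sensitivity — and therefore the effective limit of
detection — varies between days, so the run-day label travels with the data
through every downstream step.

Preprocessing follows the standard metabolomics pipeline: divide each
metabolite by its run-day median (batch correction), natural-log transform
(metabolite abundances are approximately log-normal), and exclude samples
whose Mahalanobis distance is an extreme outlier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN"})

__all__ = [
    "MetaboliteMatrix",
    "PathwayAnnotation",
    "read_matrix",
    "write_matrix",
    "read_pathway_annotation",
    "preprocess",
    "filter_missingness_range",
]


@dataclass
class MetaboliteMatrix:
    """Samples × metabolites abundance matrix with missingness mask.

    Parameters
    ----------
    values
        Float array of shape ``(n_samples, n_metabolites)``.  Entries where
        ``mask`` is true are undefined (stored as NaN).
    mask
        Boolean array, true where the measurement is missing.
    sample_ids, metabolite_ids
        Unique string identifiers for rows and columns.
    runday
        Per-sample categorical batch label (one per row).
    scale
        One of ``"raw"``, ``"runday_normalized"``, ``"log"``.
    """

    values: np.ndarray
    mask: np.ndarray
    sample_ids: list[str]
    metabolite_ids: list[str]
    runday: np.ndarray
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.runday = np.asarray(self.runday, dtype=object)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        n, p = self.values.shape
        if self.mask.shape != (n, p):
            raise ValueError("mask shape does not match values")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match values")
        if len(self.metabolite_ids) != p:
            raise ValueError("metabolite_ids length does not match values")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.metabolite_ids)) != p:
            raise ValueError("duplicate metabolite ids")
        if self.runday.shape != (n,):
            raise ValueError("every sample needs a run-day label")
        if self.scale not in ("raw", "runday_normalized", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        # undefined cells are stored as NaN so they can never leak into stats
        self.values = self.values.copy()
        self.values[self.mask] = np.nan

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Overall missing fraction per metabolite."""
        return self.mask.mean(axis=0)

    def column(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite {metabolite_id!r}") from None

    def observed(self, j: int) -> np.ndarray:
        """Observed values of column ``j``."""
        return self.values[~self.mask[:, j], j]

    def copy(self) -> "MetaboliteMatrix":
        return replace(
            self,
            values=self.values.copy(),
            mask=self.mask.copy(),
            sample_ids=list(self.sample_ids),
            metabolite_ids=list(self.metabolite_ids),
            runday=self.runday.copy(),
        )

    def runday_groups(self) -> dict[object, np.ndarray]:
        """Map run-day label -> row indices, in order of first appearance."""
        groups: dict[object, list[int]] = {}
        for i, d in enumerate(self.runday):
            groups.setdefault(d, []).append(i)
        return {d: np.asarray(ix, dtype=int) for d, ix in groups.items()}


@dataclass
class PathwayAnnotation:
    """One-to-one mapping metabolite id → pathway name."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def pathway(self, metabolite_id: str) -> str:
        return self.mapping[metabolite_id]

    def pathways(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.mapping.values():
            seen.setdefault(v)
        return list(seen)

    def annotated(self, metabolite_ids: list[str]) -> list[str]:
        """Subset of ids that carry a pathway annotation, order preserved."""
        return [m for m in metabolite_ids if m in self.mapping]


def _detect_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(
    path: str,
    runday_column: str,
    missing_tokens: frozenset[str] | set[str] = DEFAULT_MISSING_TOKENS,
    sample_column: str | None = None,
    sep: str | None = None,
) -> MetaboliteMatrix:
    """Read a delimited abundance table into a :class:`MetaboliteMatrix`.

    The table has samples as rows: a sample-id column (the first column by
    default), a run-day column, and one column per metabolite.  A cell is
    missing iff it is empty or equals one of ``missing_tokens``.
    """
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if sample_column is None:
        sample_column = df.columns[0]
    if runday_column not in df.columns:
        raise ValueError(f"run-day column {runday_column!r} not found in {path}")
    sample_ids = df[sample_column].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in input")
    runday = df[runday_column].to_numpy(dtype=object)
    met_cols = [c for c in df.columns if c not in (sample_column, runday_column)]
    if len(set(met_cols)) != len(met_cols):
        raise ValueError("duplicate metabolite ids in input")
    tokens = set(missing_tokens)
    raw = df[met_cols].to_numpy(dtype=object)
    mask = np.zeros(raw.shape, dtype=bool)
    values = np.full(raw.shape, np.nan)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell in tokens:
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at sample "
                        f"{sample_ids[i]!r}, metabolite {met_cols[j]!r}"
                    ) from None
    return MetaboliteMatrix(values, mask, sample_ids, met_cols, runday)


def write_matrix(
    m: MetaboliteMatrix,
    path: str,
    runday_column: str = "RUN_DAY",
    sample_column: str = "SAMPLE_ID",
    sep: str = "\t",
) -> None:
    """Write a matrix as delimited text; masked cells become empty fields."""
    df = pd.DataFrame(m.values, columns=m.metabolite_ids)
    df = df.where(~pd.DataFrame(m.mask, columns=m.metabolite_ids), other=np.nan)
    df.insert(0, runday_column, m.runday)
    df.insert(0, sample_column, m.sample_ids)
    df.to_csv(path, sep=sep, index=False, na_rep="", float_format="%.12g")


def read_pathway_annotation(path: str, sep: str | None = None) -> PathwayAnnotation:
    """Read a two-column (metabolite_id, pathway) table."""
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation needs two columns (metabolite_id, pathway)")
    ids = df.iloc[:, 0]
    if ids.duplicated().any():
        raise ValueError("a metabolite maps to more than one pathway")
    return PathwayAnnotation(dict(zip(ids, df.iloc[:, 1])))


def _mahalanobis_distances(m: MetaboliteMatrix) -> np.ndarray:
    """Mahalanobis distance per sample on the log-scale data.

    Computed on the submatrix of fully observed metabolites; if none exist,
    falls back to pairwise-complete covariance with diagonal shrinkage.
    """
    complete = ~m.mask.any(axis=0)
    if complete.any():
        x = m.values[:, complete]
        mu = x.mean(axis=0)
        cov = np.cov(x, rowvar=False)
    else:
        warnings.warn(
            "no fully observed metabolite; using pairwise-complete covariance "
            "with diagonal shrinkage for Mahalanobis distances"
        )
        df = pd.DataFrame(m.values)
        mu = df.mean().to_numpy()
        cov = df.cov(min_periods=2).to_numpy()
        cov = np.where(np.isfinite(cov), cov, 0.0)
        cov = 0.9 * cov + 0.1 * np.diag(np.diag(cov))
        x = np.where(m.mask, mu, m.values)
    cov = np.atleast_2d(cov)
    # ridge for numerically singular covariance
    cov = cov + 1e-10 * np.eye(cov.shape[0]) * max(np.trace(cov), 1.0)
    xc = np.where(np.isnan(x), mu, x) - mu
    sol = np.linalg.solve(cov, xc.T)
    return np.sqrt(np.einsum("ij,ji->i", xc, sol))


def preprocess(
    m: MetaboliteMatrix, mahalanobis_sd: float = 4.0
) -> tuple[MetaboliteMatrix, list[str]]:
    """Run-day median normalization, natural-log transform, outlier exclusion.

    Each observed value is divided by the run-day median of its metabolite
    (computed on observed values of that run day), then log-transformed.
    Samples whose Mahalanobis distance exceeds
    ``mean(distance) + mahalanobis_sd * SD(distance)`` are excluded.

    Returns the cleaned matrix and the list of excluded sample ids.  The
    missingness mask of retained samples is unchanged.
    """
    if m.scale != "raw":
        raise ValueError(f"preprocess expects raw-scale data, got {m.scale!r}")
    vals = m.values.copy()
    obs = ~m.mask
    if np.any(vals[obs] <= 0):
        raise ValueError("non-positive observed abundance; cannot log-transform")
    for d, rows in m.runday_groups().items():
        for j in range(m.n_metabolites):
            o = rows[obs[rows, j]]
            if o.size == 0:
                logger.warning(
                    "metabolite %s has no observed value on run day %r; "
                    "left unnormalized there",
                    m.metabolite_ids[j],
                    d,
                )
                continue
            vals[o, j] = vals[o, j] / np.median(vals[o, j])
    vals[obs] = np.log(vals[obs])
    out = MetaboliteMatrix(
        vals, m.mask.copy(), m.sample_ids, m.metabolite_ids, m.runday, scale="log"
    )
    dist = _mahalanobis_distances(out)
    sd = dist.std()
    if sd == 0:
        keep = np.ones(m.n_samples, dtype=bool)
    else:
        keep = dist <= dist.mean() + mahalanobis_sd * sd
    excluded = [s for s, k in zip(out.sample_ids, keep) if not k]
    cleaned = MetaboliteMatrix(
        out.values[keep],
        out.mask[keep],
        [s for s, k in zip(out.sample_ids, keep) if k],
        out.metabolite_ids,
        out.runday[keep],
        scale="log",
    )
    return cleaned, excluded


def filter_missingness_range(
    m: MetaboliteMatrix, low: float = 0.10, high: float = 0.70
) -> list[str]:
    """Metabolite ids with overall missing fraction strictly inside (low, high).

    The conventional analysis window keeps metabolites with more than 10% and
    less than 70% missing values: below the window there is too little signal
    about the missingness mechanism, above it too little observed data.
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    frac = m.missing_fraction()
    return [
        mid
        for mid, f in zip(m.metabolite_ids, frac)
        if low < f < high
    ]
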