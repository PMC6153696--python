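"""Name-resolved registry of the 31 imputation method variants (+ CCA).

Registry ids::

    mean, min
    RC, ITS, MITS
    RC-R, ITS-R, MITS-R
    ICE-norm, ICE-pmm, ICE-adjR
    MICE-norm, MICE-pmm, MICE-adjR
    MICE-avg-norm, MICE-avg-pmm
    KNN-var(K), KNN-obs(K), KNN-obs-sel(K)   for K in {1, 3, 5, 10, 20}

plus ``CCA``, the non-imputing complete-case baseline (listwise deletion is
applied at analysis time, not here).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import lod, multivariate
from .lod import ImputedData
from .matrix import MetaboliteMatrix

__all__ = ["MethodSpec", "METHOD_IDS", "resolve", "apply_method"]

KNN_KS = (1, 3, 5, 10, 20)


@dataclass
class MethodSpec:
    """Executable description of one registry method."""

    id: str
    family: str
    parameters: dict = field(default_factory=dict)
    multiplicity: int = 1

    @property
    def is_multiple(self) -> bool:
        return self.multiplicity > 1


def _build_registry() -> dict[str, MethodSpec]:
    m = lod.DEFAULT_M
    reg: dict[str, MethodSpec] = {}

    def add(spec: MethodSpec) -> None:
        reg[spec.id] = spec

    add(MethodSpec("mean", "constant"))
    add(MethodSpec("min", "constant"))
    add(MethodSpec("RC", "lod", {"scope": "global"}))
    add(MethodSpec("ITS", "lod", {"scope": "global"}))
    add(MethodSpec("MITS", "lod", {"scope": "global"}, multiplicity=m))
    add(MethodSpec("RC-R", "lod-runday", {"base": "RC"}))
    add(MethodSpec("ITS-R", "lod-runday", {"base": "ITS"}))
    add(MethodSpec("MITS-R", "lod-runday", {"base": "MITS"}, multiplicity=m))
    for model in ("norm", "pmm", "adjR"):
        add(MethodSpec(f"ICE-{model}", "ice", {"model": model}))
        add(MethodSpec(f"MICE-{model}", "mice", {"model": model}, multiplicity=m))
    for model in ("norm", "pmm"):
        add(MethodSpec(f"MICE-avg-{model}", "mice-avg", {"model": model}))
    for mode in ("var", "obs", "obs-sel"):
        for k in KNN_KS:
            add(MethodSpec(f"KNN-{mode}({k})", "knn", {"mode": mode, "k": k}))
    add(MethodSpec("CCA", "baseline"))
    return reg


_REGISTRY = _build_registry()
METHOD_IDS = tuple(i for i in _REGISTRY if i != "CCA")  # the 31 imputations
ALL_IDS = tuple(_REGISTRY)

_KNN_RE = re.compile(r"^KNN-(var|obs|obs-sel)\((\d+)\)$")


def resolve(method_id: str) -> MethodSpec:
    """Look up a method id, raising with the list of valid ids if unknown."""
    if method_id in _REGISTRY:
        return _REGISTRY[method_id]
    raise KeyError(
        f"unknown method {method_id!r}; valid ids: {', '.join(ALL_IDS)}"
    )


def apply_method(
    m: MetaboliteMatrix,
    method_id: str,
    seed: int | None = None,
    predictor_min_corr: float = 0.0,
) -> ImputedData | None:
    """Run one registry method on a matrix.

    Returns the :class:`ImputedData`, or ``None`` for the CCA baseline
    (complete-case analysis deletes rows at analysis time instead of
    filling cells).
    """
    spec = resolve(method_id)
    fam = spec.family
    if fam == "baseline":
        return None
    if fam == "constant":
        return lod.impute_mean(m) if spec.id == "mean" else lod.impute_min(m)
    if fam == "lod":
        if spec.id == "RC":
            return lod.impute_rc(m, scope="global")
        if spec.id == "ITS":
            return lod.impute_its(m, scope="global", seed=seed)
        return lod.impute_mits(
            m, scope="global", m_imputations=spec.multiplicity, seed=seed
        )
    if fam == "lod-runday":
        return lod.rundaywise(
            m,
            base=spec.parameters["base"],
            m_imputations=spec.multiplicity,
            seed=seed,
        )
    if fam == "ice":
        return multivariate.ice_impute(
            m,
            model=spec.parameters["model"],
            predictor_min_corr=predictor_min_corr,
            seed=seed,
        )
    if fam == "mice":
        return multivariate.mice_impute(
            m,
            model=spec.parameters["model"],
            m_imputations=spec.multiplicity,
            predictor_min_corr=predictor_min_corr,
            seed=seed,
        )
    if fam == "mice-avg":
        return multivariate.mice_avg(
            m,
            model=spec.parameters["model"],
            predictor_min_corr=predictor_min_corr,
            seed=seed,
        )
    if fam == "knn":
        cfg = multivariate.KnnConfig(
            mode=spec.parameters["mode"], k=spec.parameters["k"]
        )
        return multivariate.knn_impute(m, cfg, seed=seed)
    raise AssertionError(f"unhandled family {fam!r}")
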