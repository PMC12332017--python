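"""Candidate proliferation-model structures and their parameter encodings.

Four competing hypotheses about the subpopulation structure of a tumour
undergoing a label-dilution chase:

1. one proliferating population (division-time mean 21-504 h);
2. one quiescent + one proliferating population;
3. one quiescent + one fast-cycling (21-63 h) + one slow-cycling
   (63-504 h) population;
4. one fast-cycling + one slow-cycling population, no quiescent cells.

A quiescent subpopulation never divides within the simulated chase (it is
a no-division sentinel rather than a large finite division time).  Each
proliferating subpopulation draws division times from a normal
distribution truncated to the search-range support of its mean.

Optimizer vectors are laid out as: the first ``k - 1`` subpopulation
proportions (the last is the remainder), then the division-time means of
the non-quiescent subpopulations in order, then their standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "QUIESCENT",
    "DomainError",
    "DivisionLaw",
    "Subpopulation",
    "ProliferationModel",
    "standard_models",
    "free_parameter_count",
    "parameter_bounds",
    "parameter_names",
    "decode",
    "encode",
    "validate",
]

QUIESCENT = "quiescent"

PROPORTION_BOUNDS = (0.0, 1.0)


class DomainError(ValueError):
    """A parameter value outside its admissible domain."""


@dataclass(frozen=True)
class DivisionLaw:
    """Truncated-normal division-time distribution (hours)."""

    mean: float
    sd: float
    support_lo: float
    support_hi: float


@dataclass(frozen=True)
class Subpopulation:
    """One cell subpopulation: a name, a proportion and a division law.

    ``law`` is ``None`` for quiescent cells.  ``mean_bounds``/``sd_bounds``
    define the calibration search space (``None`` for quiescent).
    ``proportion`` and ``law`` are ``None`` in an unparameterized template.
    """

    name: str
    mean_bounds: Optional[tuple[float, float]] = None
    sd_bounds: Optional[tuple[float, float]] = None
    proportion: Optional[float] = None
    law: Optional[DivisionLaw] = None

    @property
    def is_quiescent(self) -> bool:
        return self.name == QUIESCENT


@dataclass(frozen=True)
class ProliferationModel:
    """A subpopulation structure with its calibration search space."""

    model_id: int
    subpopulations: tuple[Subpopulation, ...]

    @property
    def is_parameterized(self) -> bool:
        return all(sp.proportion is not None for sp in self.subpopulations)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([sp.proportion for sp in self.subpopulations], dtype=float)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "subpopulations": [
                {
                    "name": sp.name,
                    "proportion": sp.proportion,
                    "mean_bounds": list(sp.mean_bounds) if sp.mean_bounds else None,
                    "sd_bounds": list(sp.sd_bounds) if sp.sd_bounds else None,
                    "law": None
                    if sp.law is None
                    else {
                        "mean": sp.law.mean,
                        "sd": sp.law.sd,
                        "support_lo": sp.law.support_lo,
                        "support_hi": sp.law.support_hi,
                    },
                }
                for sp in self.subpopulations
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProliferationModel":
        subs = []
        for s in d["subpopulations"]:
            law = None
            if s.get("law") is not None:
                law = DivisionLaw(**s["law"])
            subs.append(
                Subpopulation(
                    name=s["name"],
                    mean_bounds=tuple(s["mean_bounds"]) if s.get("mean_bounds") else None,
                    sd_bounds=tuple(s["sd_bounds"]) if s.get("sd_bounds") else None,
                    proportion=s.get("proportion"),
                    law=law,
                )
            )
        return cls(model_id=d["model_id"], subpopulations=tuple(subs))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProliferationModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def standard_models() -> list[ProliferationModel]:
    """The four candidate structures with their search-space boundaries."""
    prolif = Subpopulation("proliferating", (21.0, 504.0), (0.01, 40.0))
    fast = Subpopulation("fast", (21.0, 63.0), (0.01, 30.0))
    slow = Subpopulation("slow", (63.0, 504.0), (0.01, 40.0))
    q = Subpopulation(QUIESCENT)
    return [
        ProliferationModel(1, (replace(prolif, proportion=None),)),
        ProliferationModel(2, (q, prolif)),
        ProliferationModel(3, (q, fast, slow)),
        ProliferationModel(4, (fast, slow)),
    ]


def standard_model(model_id: int) -> ProliferationModel:
    for m in standard_models():
        if m.model_id == model_id:
            return m
    raise DomainError(f"no standard model with id {model_id}")


def free_parameter_count(model: ProliferationModel) -> int:
    """Number of free parameters: k-1 proportions + (mean, sd) per dividing subpopulation."""
    k = len(model.subpopulations)
    n_laws = sum(1 for sp in model.subpopulations if not sp.is_quiescent)
    return (k - 1) + 2 * n_laws


def parameter_names(model: ProliferationModel) -> list[str]:
    names = [f"p_{sp.name}" for sp in model.subpopulations[:-1]]
    names += [f"mean_{sp.name}" for sp in model.subpopulations if not sp.is_quiescent]
    names += [f"sd_{sp.name}" for sp in model.subpopulations if not sp.is_quiescent]
    return names


def parameter_bounds(model: ProliferationModel) -> list[tuple[float, float]]:
    """Box bounds for the optimizer vector, in vector order."""
    k = len(model.subpopulations)
    bounds = [PROPORTION_BOUNDS] * (k - 1)
    bounds += [sp.mean_bounds for sp in model.subpopulations if not sp.is_quiescent]
    bounds += [sp.sd_bounds for sp in model.subpopulations if not sp.is_quiescent]
    return bounds


def decode(vector, model: ProliferationModel) -> ProliferationModel:
    """Turn an optimizer vector into a fully parameterized model.

    The last subpopulation receives the remainder proportion; a negative
    remainder or an out-of-bounds value raises :class:`DomainError` naming
    the offending parameter.
    """
    vector = np.asarray(vector, dtype=float)
    n = free_parameter_count(model)
    if vector.size != n:
        raise DomainError(f"expected {n} parameters for model {model.model_id}, got {vector.size}")
    names = parameter_names(model)
    for name, val, (lo, hi) in zip(names, vector, parameter_bounds(model)):
        if not (lo <= val <= hi):
            raise DomainError(f"{name}={val} outside bounds [{lo}, {hi}]")
    k = len(model.subpopulations)
    free_props = vector[: k - 1]
    remainder = 1.0 - float(free_props.sum())
    if remainder < -1e-12:
        raise DomainError(
            f"proportions {free_props.tolist()} leave a negative remainder {remainder}"
        )
    props = np.append(free_props, max(remainder, 0.0))
    dividing = [sp for sp in model.subpopulations if not sp.is_quiescent]
    means = vector[k - 1 : k - 1 + len(dividing)]
    sds = vector[k - 1 + len(dividing) :]
    laws = {
        sp.name: DivisionLaw(float(mu), float(sd), sp.mean_bounds[0], sp.mean_bounds[1])
        for sp, mu, sd in zip(dividing, means, sds)
    }
    subs = tuple(
        replace(sp, proportion=float(p), law=laws.get(sp.name))
        for sp, p in zip(model.subpopulations, props)
    )
    return ProliferationModel(model.model_id, subs)


def encode(model: ProliferationModel) -> np.ndarray:
    """Inverse of :func:`decode` on parameterized models."""
    if not model.is_parameterized:
        raise DomainError("cannot encode an unparameterized model")
    props = [sp.proportion for sp in model.subpopulations[:-1]]
    means = [sp.law.mean for sp in model.subpopulations if not sp.is_quiescent]
    sds = [sp.law.sd for sp in model.subpopulations if not sp.is_quiescent]
    return np.array(props + means + sds, dtype=float)


def validate(model: ProliferationModel) -> list[str]:
    """Check all structural invariants; return violations (empty = ok)."""
    v: list[str] = []
    for sp in model.subpopulations:
        if sp.is_quiescent and sp.law is not None:
            v.append(f"quiescent subpopulation {sp.name!r} carries a division law")
        if not sp.is_quiescent and sp.mean_bounds is None:
            v.append(f"dividing subpopulation {sp.name!r} lacks mean bounds")
        if sp.proportion is not None and not (0.0 <= sp.proportion <= 1.0):
            v.append(f"proportion of {sp.name!r} is {sp.proportion}, outside [0, 1]")
        law = sp.law
        if law is not None:
            if law.support_lo <= 0:
                v.append(f"{sp.name}: support_lo {law.support_lo} must be > 0")
            if not (law.support_lo <= law.mean <= law.support_hi):
                v.append(
                    f"{sp.name}: mean {law.mean} outside support "
                    f"[{law.support_lo}, {law.support_hi}]"
                )
            if law.sd <= 0:
                v.append(f"{sp.name}: sd {law.sd} must be > 0")
    if model.is_parameterized:
        s = float(model.proportions.sum())
        if abs(s - 1.0) > 1e-9:
            v.append(f"proportions sum to {s}, not 1")
    return v
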