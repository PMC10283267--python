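"""Synthetic clinical datasets with planted effects.

Generates tables that mimic the structure of a paediatric-sedation
cohort: a binary outcome at roughly 24% prevalence, a binary subgroup
variable (``Healthy``) near a 47/53 split, and a mix of binary, ternary
categorical, count, continuous and tooth-list predictors.  The outcome
is drawn from a logistic model over standardized planted features (a
tooth-list contributes through its cardinality), with optional
multiplicative interaction terms; the intercept is auto-calibrated by
bisection so that the expected prevalence matches the request.

These fixtures emulate marginal structure only: they make no attempt to
reproduce any real cohort's joint distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    ALL_TOOTH_CODES,
    ClinicalTable,
    DatasetSchema,
    VariableKind,
    VariableSpec,
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Feature names are generated as ``Healthy, Bin2..``, ``Cat1..``
    (ternary, coded 0-2), ``Num1..`` (counts 0-8), ``Cont1..`` and
    ``ListTeeth1..``; planted effects and interactions refer to these
    names.  Coefficients are log-odds per standard deviation of the
    (cardinality-valued, for tooth-lists) feature.
    """

    n: int = 230
    prevalence: float = 0.24
    subgroup_fraction: float = 0.474
    n_binary: int = 5  # includes the Healthy subgroup variable
    n_categorical: int = 2
    n_integer: int = 3
    n_continuous: int = 1
    n_toothlist: int = 1
    target: str = "SecondSedation"
    planted_effects: Mapping[str, float] = field(
        default_factory=lambda: {"Num1": 1.5, "Bin2": 1.2, "ListTeeth1": 1.0}
    )
    interactions: Mapping[tuple[str, str], float] = field(default_factory=dict)
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise SimulationError("prevalence must lie in (0, 1)")
        if not 0.0 < self.subgroup_fraction < 1.0:
            raise SimulationError("subgroup_fraction must lie in (0, 1)")
        for coef in list(self.planted_effects.values()) + list(self.interactions.values()):
            if not np.isfinite(coef):
                raise SimulationError("planted coefficients must be finite")

    @property
    def feature_names(self) -> list[str]:
        names = ["Healthy"] + [f"Bin{i}" for i in range(2, self.n_binary + 1)]
        names += [f"Cat{i}" for i in range(1, self.n_categorical + 1)]
        names += [f"Num{i}" for i in range(1, self.n_integer + 1)]
        names += [f"Cont{i}" for i in range(1, self.n_continuous + 1)]
        names += [f"ListTeeth{i}" for i in range(1, self.n_toothlist + 1)]
        return names

    def ground_truth(self) -> dict:
        return {
            "target": self.target,
            "prevalence": self.prevalence,
            "planted_effects": dict(self.planted_effects),
            "interactions": {f"{a}*{b}": c for (a, b), c in self.interactions.items()},
            "seed": self.seed,
        }


def _build_schema(spec: SyntheticSpec) -> DatasetSchema:
    variables = [VariableSpec(spec.target, VariableKind.BINARY, legend={0: "no", 1: "yes"})]
    for name in spec.feature_names:
        if name.startswith("Healthy") or name.startswith("Bin"):
            variables.append(VariableSpec(name, VariableKind.BINARY))
        elif name.startswith("Cat"):
            variables.append(VariableSpec(name, VariableKind.CATEGORICAL, valid_range=(0, 2)))
        elif name.startswith("Num"):
            variables.append(VariableSpec(name, VariableKind.INTEGER_BOUNDED, valid_range=(0, 8)))
        elif name.startswith("Cont"):
            variables.append(VariableSpec(name, VariableKind.CONTINUOUS))
        else:
            variables.append(VariableSpec(name, VariableKind.TOOTHLIST))
    return DatasetSchema(tuple(variables))


#: Per-quadrant tooth inclusion probabilities: deciduous quadrants (5-8)
#: dominate in a paediatric cohort.
_QUADRANT_P = {1: 0.04, 2: 0.04, 3: 0.04, 4: 0.04, 5: 0.15, 6: 0.15, 7: 0.15, 8: 0.15}


def _draw_features(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, np.ndarray | list]:
    cols: dict[str, np.ndarray | list] = {}
    for name in spec.feature_names:
        if name == "Healthy":
            cols[name] = (rng.random(spec.n) < spec.subgroup_fraction).astype(int)
        elif name.startswith("Bin"):
            p = 0.25 + 0.5 * ((hash_stable(name) % 7) / 6.0)  # fixed per variable, in [0.25, 0.75]
            cols[name] = (rng.random(spec.n) < p).astype(int)
        elif name.startswith("Cat"):
            cols[name] = rng.choice(3, size=spec.n, p=[0.5, 0.3, 0.2])
        elif name.startswith("Num"):
            cols[name] = rng.binomial(8, 0.25, size=spec.n)
        elif name.startswith("Cont"):
            cols[name] = np.round(rng.uniform(2.0, 16.0, size=spec.n), 2)
        else:  # tooth-list
            lists = []
            for _ in range(spec.n):
                teeth = frozenset(
                    code for code in ALL_TOOTH_CODES if rng.random() < _QUADRANT_P[code // 10]
                )
                lists.append(teeth)
            cols[name] = lists
    return cols


def hash_stable(text: str) -> int:
    """Deterministic small hash (Python's ``hash`` is salted per process)."""
    value = 0
    for ch in text:
        value = (value * 31 + ord(ch)) % 1_000_003
    return value


def _numeric_view(cols: Mapping[str, np.ndarray | list], names: Sequence[str]) -> np.ndarray:
    out = np.empty((len(next(iter(cols.values()))), len(names)))
    for j, name in enumerate(names):
        col = cols[name]
        if isinstance(col, list):  # tooth-list -> cardinality
            out[:, j] = [len(c) for c in col]
        else:
            out[:, j] = np.asarray(col, dtype=float)
    return out


def _standardize(matrix: np.ndarray) -> np.ndarray:
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0)
    std[std == 0] = 1.0
    return (matrix - mean) / std


def _calibrate_intercept(score: np.ndarray, prevalence: float) -> float:
    """Bisection on the intercept so mean sigmoid(score + b) = prevalence."""
    lo, hi = -30.0, 30.0

    def mean_p(b: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(score + b)))))

    if not mean_p(lo) <= prevalence <= mean_p(hi):
        raise SimulationError("requested prevalence unreachable given planted coefficients")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_case_study_like(spec: SyntheticSpec) -> tuple[ClinicalTable, DatasetSchema]:
    """Draw one synthetic cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    schema = _build_schema(spec)
    cols = _draw_features(spec, rng)
    names = spec.feature_names
    for key in spec.planted_effects:
        if key not in cols:
            raise SimulationError(f"planted effect on unknown feature {key!r}")
    z = _standardize(_numeric_view(cols, names))
    zcol = {name: z[:, j] for j, name in enumerate(names)}
    score = np.zeros(spec.n)
    for name, coef in spec.planted_effects.items():
        score += coef * zcol[name]
    for (a, b), coef in spec.interactions.items():
        score += coef * zcol[a] * zcol[b]
    intercept = _calibrate_intercept(score, spec.prevalence)
    p = 1.0 / (1.0 + np.exp(-(score + intercept)))
    target = (rng.random(spec.n) < p).astype(int)

    data: dict[str, list] = {spec.target: [int(v) for v in target]}
    for name in names:
        col = cols[name]
        data[name] = list(col) if isinstance(col, list) else [
            float(v) if name.startswith("Cont") else int(v) for v in col
        ]
    values = pd.DataFrame(data, dtype=object)[[spec.target] + names]
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    for name, rate in spec.missing_rates.items():
        hit = rng.random(spec.n) < rate
        mask.loc[hit, name] = True
        values.loc[hit, name] = None
    return ClinicalTable(values, mask), schema


def generate_null(spec: SyntheticSpec) -> tuple[ClinicalTable, DatasetSchema]:
    """Negative control: same marginals, target independent of predictors."""
    null_spec = SyntheticSpec(
        n=spec.n,
        prevalence=spec.prevalence,
        subgroup_fraction=spec.subgroup_fraction,
        n_binary=spec.n_binary,
        n_categorical=spec.n_categorical,
        n_integer=spec.n_integer,
        n_continuous=spec.n_continuous,
        n_toothlist=spec.n_toothlist,
        target=spec.target,
        planted_effects={},
        interactions={},
        missing_rates=spec.missing_rates,
        seed=spec.seed,
    )
    return generate_case_study_like(null_spec)


def strong_signal_spec(seed: int = 0, n: int = 230) -> SyntheticSpec:
    """The planted-recovery benchmark: 20 candidate features of mixed
    kinds, three of them with strong (2.5 log-odds / SD) effects."""
    return SyntheticSpec(
        n=n,
        n_binary=8,
        n_categorical=4,
        n_integer=5,
        n_continuous=2,
        n_toothlist=1,
        planted_effects={"Bin2": 2.5, "Num1": 2.5, "Cont1": 2.5},
        seed=seed,
    )


def interaction_spec(seed: int = 0, n: int = 400) -> SyntheticSpec:
    """Fixture with a planted multiplicative interaction between Num1
    and Bin2 on top of their main effects."""
    return SyntheticSpec(
        n=n,
        n_binary=3,
        n_categorical=1,
        n_integer=2,
        n_continuous=1,
        n_toothlist=1,
        planted_effects={"Num1": 1.0, "Bin2": 0.5},
        interactions={("Num1", "Bin2"): 2.0},
        seed=seed,
    )
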