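"""Imputation and design-matrix construction.

Everything here is fitted on training rows only and then applied
unchanged to any conforming table, so no statistic of held-out data can
leak into the encoded features:

* continuous variables -> min-max rescale to [0, 1] (constant columns
  map to 0; out-of-range values at apply time are NOT clipped);
* tooth-lists -> a fixed 52-column 0/1 indicator layout over the FDI codes;
* categorical variables -> optional one-hot over the declared code range
  (default: on for >2 levels, off for binary);
* binary and integer variables pass through unscaled.

The fitted :class:`TransformPlan` is JSON-serializable and records a
``column_map`` from every encoded column back to its parent variable,
which downstream explanation code uses to aggregate one-hot children.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    ALL_TOOTH_CODES,
    ClinicalTable,
    DatasetSchema,
    VariableKind,
    VariableSpec,
    is_valid_tooth_code,
    tooth_code_index,
)


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImputationStrategy:
    """How to treat missing values in one variable.

    ``mean`` is only admissible for continuous variables and
    ``most_frequent`` only for discrete scalar kinds; ``drop_rows`` and
    ``constant`` apply to any kind.
    """

    mode: str  # {"drop_rows", "constant", "mean", "most_frequent"}
    constant_value: Any = None

    _MODES = ("drop_rows", "constant", "mean", "most_frequent")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise PreprocessError(f"unknown imputation mode {self.mode!r}")
        if self.mode == "constant" and self.constant_value is None:
            raise PreprocessError("constant imputation requires constant_value")

    def check_admissible(self, spec: VariableSpec) -> None:
        if self.mode == "mean" and spec.kind is not VariableKind.CONTINUOUS:
            raise PreprocessError(
                f"mean imputation requires a continuous variable; {spec.name!r} is {spec.kind.value}"
            )
        if self.mode == "most_frequent" and spec.kind in (VariableKind.CONTINUOUS, VariableKind.TOOTHLIST):
            raise PreprocessError(
                f"most_frequent imputation requires a discrete variable; {spec.name!r} is {spec.kind.value}"
            )


def default_strategy(spec: VariableSpec) -> ImputationStrategy:
    """Per-kind default: mean for continuous, empty set for tooth-lists,
    most frequent value for the discrete scalar kinds."""
    if spec.kind is VariableKind.CONTINUOUS:
        return ImputationStrategy("mean")
    if spec.kind is VariableKind.TOOTHLIST:
        return ImputationStrategy("constant", frozenset())
    return ImputationStrategy("most_frequent")


def _fill_value(table: ClinicalTable, column: str, spec: VariableSpec, strategy: ImputationStrategy) -> Any:
    observed = [
        v for v, m in zip(table.values[column], table.missing_mask[column]) if not m
    ]
    if strategy.mode == "constant":
        value = strategy.constant_value
        if spec.kind is VariableKind.TOOTHLIST:
            value = frozenset(value)
        return value
    if not observed:
        raise PreprocessError(f"variable {column!r} has no observed values to impute from")
    if strategy.mode == "mean":
        return float(np.mean([float(v) for v in observed]))
    # most_frequent: ties broken by smallest code for determinism
    counts: dict[int, int] = {}
    for v in observed:
        counts[int(v)] = counts.get(int(v), 0) + 1
    best = max(sorted(counts), key=lambda k: counts[k])
    return best


def impute_target(table: ClinicalTable, target: str, strategy: ImputationStrategy, schema: DatasetSchema) -> ClinicalTable:
    """Resolve missing values in the target column.

    ``drop_rows`` removes exactly the rows whose target is missing; the
    fill modes preserve the row count and clear the mask.
    """
    if target not in schema:
        raise PreprocessError(f"unknown target variable {target!r}")
    spec = schema[target]
    strategy.check_admissible(spec)
    mask = table.missing_mask[target].to_numpy(dtype=bool)
    if strategy.mode == "drop_rows":
        keep = table.values.index[~mask]
        return table.take_rows(keep)
    out = table.copy()
    if mask.any():
        out.values.loc[out.values.index[mask], target] = _fill_value(table, target, spec, strategy)
        out.missing_mask[target] = False
    return out


def impute_predictors(
    table: ClinicalTable,
    schema: DatasetSchema,
    predictors: Sequence[str],
    strategies: Mapping[str, ImputationStrategy] | None = None,
    fill_values: Mapping[str, Any] | None = None,
) -> tuple[ClinicalTable, dict[str, Any]]:
    """Fill missing predictor cells; returns the table and the fill values
    actually used (so a plan fitted on training rows can be replayed on
    new data without refitting)."""
    strategies = dict(strategies or {})
    out = table.copy()
    used: dict[str, Any] = {}
    for name in predictors:
        spec = schema[name]
        mask = out.missing_mask[name].to_numpy(dtype=bool)
        if fill_values is not None and name in fill_values:
            value = fill_values[name]
            if spec.kind is VariableKind.TOOTHLIST:
                value = frozenset(int(c) for c in value)
        else:
            strategy = strategies.get(name, default_strategy(spec))
            if strategy.mode == "drop_rows":
                raise PreprocessError("drop_rows is not admissible for predictor imputation")
            strategy.check_admissible(spec)
            value = _fill_value(out, name, spec, strategy)
        used[name] = value
        if mask.any():
            idx = out.values.index[mask]
            out.values.loc[idx, name] = pd.Series([value] * len(idx), index=idx, dtype=object)
            out.missing_mask[name] = False
    return out, used


# ---------------------------------------------------------------------------
# Tooth-list encoding
# ---------------------------------------------------------------------------


def encode_toothlist(cell: frozenset[int] | set[int]) -> np.ndarray:
    """0/1 indicator vector of length 52 over the canonical FDI layout."""
    vec = np.zeros(len(ALL_TOOTH_CODES), dtype=float)
    for code in cell:
        vec[tooth_code_index(int(code))] = 1.0
    return vec


def decode_toothlist(vector: np.ndarray) -> frozenset[int]:
    """Inverse of :func:`encode_toothlist`."""
    return frozenset(ALL_TOOTH_CODES[i] for i in np.flatnonzero(np.asarray(vector) != 0))


# ---------------------------------------------------------------------------
# Transform plan
# ---------------------------------------------------------------------------


@dataclass
class TransformPlan:
    """Fitted, serializable recipe turning a ClinicalTable into a numeric
    design matrix."""

    predictors: list[str]
    kinds: dict[str, str]
    continuous_ranges: dict[str, tuple[float, float]]
    categorical_levels: dict[str, list[int]]  # one-hot encoded categoricals only
    fill_values: dict[str, Any]
    encoded_columns: list[str] = field(default_factory=list)
    column_map: dict[str, str] = field(default_factory=dict)

    def _layout(self) -> None:
        cols: list[str] = []
        cmap: dict[str, str] = {}
        for name in self.predictors:
            kind = VariableKind(self.kinds[name])
            if kind is VariableKind.TOOTHLIST:
                for code in ALL_TOOTH_CODES:
                    col = f"{name}={code}"
                    cols.append(col)
                    cmap[col] = name
            elif kind is VariableKind.CATEGORICAL and name in self.categorical_levels:
                for level in self.categorical_levels[name]:
                    col = f"{name}={level}"
                    cols.append(col)
                    cmap[col] = name
            else:
                cols.append(name)
                cmap[name] = name
        self.encoded_columns = cols
        self.column_map = cmap

    def to_dict(self) -> dict:
        fills = {}
        for k, v in self.fill_values.items():
            fills[k] = sorted(int(c) for c in v) if isinstance(v, frozenset) else v
        return {
            "predictors": self.predictors,
            "kinds": self.kinds,
            "continuous_ranges": {k: list(v) for k, v in self.continuous_ranges.items()},
            "categorical_levels": self.categorical_levels,
            "fill_values": fills,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "TransformPlan":
        fills = {}
        for k, v in data["fill_values"].items():
            kind = VariableKind(data["kinds"][k])
            fills[k] = frozenset(v) if kind is VariableKind.TOOTHLIST else v
        plan = cls(
            predictors=list(data["predictors"]),
            kinds=dict(data["kinds"]),
            continuous_ranges={k: (float(v[0]), float(v[1])) for k, v in data["continuous_ranges"].items()},
            categorical_levels={k: [int(x) for x in v] for k, v in data["categorical_levels"].items()},
            fill_values=fills,
        )
        plan._layout()
        return plan


def build_transform_plan(
    train: ClinicalTable,
    schema: DatasetSchema,
    predictors: Sequence[str],
    encode_categoricals: bool = True,
    strategies: Mapping[str, ImputationStrategy] | None = None,
) -> TransformPlan:
    """Fit the transformation recipe on training rows only.

    ``encode_categoricals=True`` one-hot encodes categoricals with more
    than two declared levels; binary variables always pass through.
    """
    predictors = list(predictors)
    for name in predictors:
        if name not in schema:
            raise PreprocessError(f"unknown predictor {name!r}")
    imputed, fill_values = impute_predictors(train, schema, predictors, strategies)
    kinds = {name: schema[name].kind.value for name in predictors}
    continuous_ranges: dict[str, tuple[float, float]] = {}
    categorical_levels: dict[str, list[int]] = {}
    for name in predictors:
        spec = schema[name]
        if spec.kind is VariableKind.CONTINUOUS:
            col = np.asarray([float(v) for v in imputed.values[name]], dtype=float)
            if col.size == 0:
                raise PreprocessError(f"predictor {name!r} has no rows to fit on")
            continuous_ranges[name] = (float(col.min()), float(col.max()))
        elif spec.kind is VariableKind.CATEGORICAL and encode_categoricals:
            lo, hi = spec.valid_range  # type: ignore[misc]
            if hi - lo + 1 > 2:
                categorical_levels[name] = list(range(lo, hi + 1))
    plan = TransformPlan(
        predictors=predictors,
        kinds=kinds,
        continuous_ranges=continuous_ranges,
        categorical_levels=categorical_levels,
        fill_values=fill_values,
    )
    plan._layout()
    return plan


def apply_transform(plan: TransformPlan, table: ClinicalTable, schema: DatasetSchema) -> pd.DataFrame:
    """Apply a fitted plan; deterministic, returns the encoded design
    matrix as a float DataFrame whose columns are ``plan.encoded_columns``.

    Missing predictor cells are filled with the plan's fitted fill values.
    A categorical code outside the declared range yields an all-zero
    indicator block and a warning rather than an error.
    """
    missing_cols = [p for p in plan.predictors if p not in table.columns]
    if missing_cols:
        raise PreprocessError(f"table lacks predictor column(s): {missing_cols}")
    filled, _ = impute_predictors(table, schema, plan.predictors, fill_values=plan.fill_values)
    n = filled.n_rows
    blocks: list[np.ndarray] = []
    for name in plan.predictors:
        kind = VariableKind(plan.kinds[name])
        cells = filled.values[name].to_numpy(dtype=object)
        if kind is VariableKind.TOOTHLIST:
            block = np.zeros((n, len(ALL_TOOTH_CODES)))
            for i, cell in enumerate(cells):
                block[i] = encode_toothlist(cell)
            blocks.append(block)
        elif kind is VariableKind.CATEGORICAL and name in plan.categorical_levels:
            levels = plan.categorical_levels[name]
            block = np.zeros((n, len(levels)))
            index = {lvl: j for j, lvl in enumerate(levels)}
            for i, cell in enumerate(cells):
                j = index.get(int(cell))
                if j is None:
                    warnings.warn(
                        f"unseen categorical code {cell!r} for {name!r}; emitting all-zero indicators",
                        stacklevel=2,
                    )
                else:
                    block[i, j] = 1.0
            blocks.append(block)
        elif kind is VariableKind.CONTINUOUS:
            lo, hi = plan.continuous_ranges[name]
            col = np.asarray([float(v) for v in cells])
            if hi > lo:
                col = (col - lo) / (hi - lo)  # unclipped beyond [0,1] by design
            else:
                col = np.zeros(n)
            blocks.append(col[:, None])
        else:
            blocks.append(np.asarray([float(v) for v in cells])[:, None])
    matrix = np.hstack(blocks) if blocks else np.empty((n, 0))
    return pd.DataFrame(matrix, columns=plan.encoded_columns, index=filled.values.index)
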