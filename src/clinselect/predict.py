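"""Scoring and explaining new samples against a saved model bundle.

A new sample is a JSON-style mapping from predictor name to value
(tooth-lists as lists of two-digit codes).  Validation is strict —
missing predictors, extraneous fields, out-of-domain values and invalid
tooth codes are each reported by name — and any sample that validates
is guaranteed to score without further errors.
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np
import pandas as pd

from .evaluate import ModelBundle
from .explain import ExplainConfig, compute_shap, waterfall
from .schema import ClinicalTable, VariableKind, is_valid_tooth_code


class PredictionError(ValueError):
    pass


def sample_to_table(bundle: ModelBundle, sample: Mapping[str, Any]) -> ClinicalTable:
    """Validate one new sample and lift it into a one-row ClinicalTable."""
    predictors = bundle.predictors
    missing = [p for p in predictors if p not in sample]
    if missing:
        raise PredictionError(f"missing predictor(s): {missing}")
    extraneous = [k for k in sample if k not in predictors]
    if extraneous:
        raise PredictionError(f"unknown field(s): {extraneous}")
    row: dict[str, Any] = {}
    for name in predictors:
        spec = bundle.schema[name]
        value = sample[name]
        if spec.kind is VariableKind.TOOTHLIST:
            if not isinstance(value, (list, tuple, set, frozenset)):
                raise PredictionError(f"{name!r}: tooth-list value must be a list of codes")
            try:
                codes = frozenset(int(c) for c in value)
            except (TypeError, ValueError):
                raise PredictionError(f"{name!r}: unparseable tooth code in {value!r}") from None
            bad = sorted(c for c in codes if not is_valid_tooth_code(c))
            if bad:
                raise PredictionError(f"{name!r}: invalid tooth code(s) {bad}")
            row[name] = codes
        elif spec.kind is VariableKind.CONTINUOUS:
            try:
                row[name] = float(value)
            except (TypeError, ValueError):
                raise PredictionError(f"{name!r}: expected a number, got {value!r}") from None
        else:
            try:
                iv = int(value)
            except (TypeError, ValueError):
                raise PredictionError(f"{name!r}: expected an integer, got {value!r}") from None
            if not spec.is_valid_value(iv):
                raise PredictionError(
                    f"{name!r}: value {iv} outside the valid domain"
                    + (f" {list(spec.valid_range)}" if spec.valid_range else "")
                )
            row[name] = iv
    values = pd.DataFrame([[row[p] for p in predictors]], columns=predictors, dtype=object)
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return ClinicalTable(values, mask)


def predict_new(bundle: ModelBundle, sample: Mapping[str, Any], explain: bool = True) -> dict:
    """Predicted class, calibrated per-class probabilities and (optionally)
    a waterfall explanation for one new sample."""
    table = sample_to_table(bundle, sample)
    proba = bundle.predict_proba(table)[0]
    predicted = int(bundle.classes[int(np.argmax(proba))])
    result = {
        "predicted_class": predicted,
        "probabilities": {str(c): float(p) for c, p in zip(bundle.classes, proba)},
    }
    target_spec = bundle.schema[bundle.config.target]
    result["predicted_label"] = target_spec.display_value(predicted)
    if explain:
        explanation = compute_shap(bundle, table, ExplainConfig())
        result["explanation"] = waterfall(explanation, 0)
    return result


def input_template(bundle: ModelBundle) -> list[dict]:
    """Form specification for the bundle's predictors, in schema order."""
    entries = []
    for name in bundle.predictors:
        spec = bundle.schema[name]
        entry: dict[str, Any] = {"name": name, "kind": spec.kind.value}
        if spec.valid_range is not None:
            entry["range"] = list(spec.valid_range)
        if spec.legend:
            entry["legend"] = {str(k): v for k, v in spec.legend.items()}
        if spec.kind is VariableKind.TOOTHLIST:
            from .schema import ALL_TOOTH_CODES

            entry["codes"] = list(ALL_TOOTH_CODES)
        entries.append(entry)
    return entries
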