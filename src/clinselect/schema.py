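"""Typed data model for clinical tabular datasets.

A dataset is a plain CSV of patient records accompanied by a metadata CSV
that types every column.  Six variable kinds are supported: binary,
categorical (integer-coded, with an inclusive valid range and an optional
legend), bounded and unbounded integers, continuous, and *tooth-lists* —
set-valued variables whose elements are two-digit FDI / ISO 3950 tooth
codes (first digit: quadrant 1-8; second digit: position, 1-8 for the
permanent quadrants 1-4 and 1-5 for the deciduous quadrants 5-8).

The metadata dialect is a CSV with header ``name,type,min,max,legend``
where ``legend`` is a ``;``-joined list of ``code=label`` pairs.  Tooth-list
cells inside the dataset CSV are ``;``-joined two-digit codes; an empty
cell is the empty set (no teeth), which is distinct from the missing
sentinel (default ``NA``).
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MISSING_SENTINEL = "NA"
TOOTHLIST_SEPARATOR = ";"

# ---------------------------------------------------------------------------
# Tooth codes (FDI / ISO 3950)
# ---------------------------------------------------------------------------

#: All 52 admissible two-digit tooth codes: 32 permanent + 20 deciduous.
ALL_TOOTH_CODES: tuple[int, ...] = tuple(
    sorted(
        [10 * q + p for q in range(1, 5) for p in range(1, 9)]
        + [10 * q + p for q in range(5, 9) for p in range(1, 6)]
    )
)

_TOOTH_CODE_SET = frozenset(ALL_TOOTH_CODES)
_TOOTH_CODE_INDEX = {code: i for i, code in enumerate(ALL_TOOTH_CODES)}


def is_valid_tooth_code(code: int) -> bool:
    """True iff ``code`` is one of the 52 FDI two-digit tooth codes."""
    return code in _TOOTH_CODE_SET


def tooth_code_index(code: int) -> int:
    """Position of a tooth code in the canonical sorted 52-code layout."""
    try:
        return _TOOTH_CODE_INDEX[code]
    except KeyError:
        raise ValueError(f"invalid tooth code {code}") from None


# ---------------------------------------------------------------------------
# Variable specifications
# ---------------------------------------------------------------------------


class VariableKind(str, Enum):
    BINARY = "binary"
    CATEGORICAL = "categorical"
    INTEGER_BOUNDED = "integer_bounded"
    INTEGER_UNBOUNDED = "integer_unbounded"
    CONTINUOUS = "continuous"
    TOOTHLIST = "toothlist"


#: Kinds whose cells are scalar integers.
INTEGER_KINDS = frozenset(
    {VariableKind.BINARY, VariableKind.CATEGORICAL, VariableKind.INTEGER_BOUNDED, VariableKind.INTEGER_UNBOUNDED}
)

#: Kinds that carry an inclusive [min, max] range in the metadata.
RANGED_KINDS = frozenset(
    {VariableKind.BINARY, VariableKind.CATEGORICAL, VariableKind.INTEGER_BOUNDED}
)


class SchemaError(ValueError):
    """Raised for malformed metadata or dataset/schema mismatches."""


@dataclass(frozen=True)
class VariableSpec:
    """Typed description of one dataset column."""

    name: str
    kind: VariableKind
    valid_range: tuple[int, int] | None = None
    legend: Mapping[int, str] | None = None
    missing_sentinel: str = DEFAULT_MISSING_SENTINEL

    def __post_init__(self) -> None:
        if self.kind is VariableKind.BINARY:
            rng = self.valid_range or (0, 1)
            if tuple(rng) != (0, 1):
                raise SchemaError(f"binary variable {self.name!r} must have range [0, 1]")
            object.__setattr__(self, "valid_range", (0, 1))
        elif self.kind in RANGED_KINDS:
            if self.valid_range is None:
                raise SchemaError(f"{self.kind.value} variable {self.name!r} requires a [min, max] range")
            lo, hi = self.valid_range
            if lo > hi:
                raise SchemaError(f"variable {self.name!r}: range min {lo} exceeds max {hi}")
        elif self.kind is VariableKind.TOOTHLIST and self.valid_range is not None:
            raise SchemaError(f"toothlist variable {self.name!r} admits no scalar range")
        if self.legend:
            legend = {int(k): str(v) for k, v in self.legend.items()}
            for code in legend:
                if not self.is_valid_value(code):
                    raise SchemaError(f"variable {self.name!r}: legend key {code} outside the valid domain")
            object.__setattr__(self, "legend", legend)

    def is_valid_value(self, value: Any) -> bool:
        """Domain membership test for a single non-missing cell value."""
        if self.kind is VariableKind.TOOTHLIST:
            return isinstance(value, frozenset) and all(is_valid_tooth_code(c) for c in value)
        if self.kind is VariableKind.CONTINUOUS:
            return isinstance(value, (int, float)) and math.isfinite(float(value))
        if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
            return False
        if self.kind in RANGED_KINDS:
            lo, hi = self.valid_range  # type: ignore[misc]
            return lo <= value <= hi
        return True  # integer_unbounded

    def display_value(self, value: Any) -> str:
        """Human-readable rendering using the legend when present."""
        if self.kind is VariableKind.TOOTHLIST:
            return TOOTHLIST_SEPARATOR.join(str(c) for c in sorted(value))
        if self.legend and int(value) in self.legend:
            return self.legend[int(value)]
        return str(value)


@dataclass(frozen=True)
class DatasetSchema:
    """Ordered collection of :class:`VariableSpec`, one per dataset column."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate variable name(s): {sorted(dupes)}")
        object.__setattr__(self, "variables", tuple(self.variables))

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __iter__(self):
        return iter(self.variables)


@dataclass
class ClinicalTable:
    """Records x variables with an explicit missing-value mask.

    ``values`` holds typed cells (ints, floats, frozensets of tooth codes);
    missing cells hold ``None`` and are flagged in ``missing_mask``.
    Both frames share index and columns.
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.missing_mask.columns):
            raise SchemaError("values and missing_mask must share columns")
        if not self.values.index.equals(self.missing_mask.index):
            raise SchemaError("values and missing_mask must share index")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(self.values.copy(), self.missing_mask.copy())

    def take_rows(self, index) -> "ClinicalTable":
        return ClinicalTable(self.values.loc[index], self.missing_mask.loc[index])


@dataclass(frozen=True)
class Violation:
    """One in-domain failure found by :func:`validate_dataset`."""

    row: int
    column: str
    message: str


# ---------------------------------------------------------------------------
# Metadata parsing / writing
# ---------------------------------------------------------------------------

_METADATA_HEADER = ["name", "type", "min", "max", "legend"]


def _parse_legend(text: str, row: int) -> dict[int, str] | None:
    if not text:
        return None
    legend: dict[int, str] = {}
    for pair in text.split(";"):
        if not pair:
            continue
        if "=" not in pair:
            raise SchemaError(f"malformed legend pair {pair!r} at row {row}")
        code, label = pair.split("=", 1)
        try:
            legend[int(code)] = label
        except ValueError:
            raise SchemaError(f"malformed legend pair {pair!r} at row {row}") from None
    return legend or None


def parse_metadata(text: str, missing_sentinel: str = DEFAULT_MISSING_SENTINEL) -> DatasetSchema:
    """Parse the metadata CSV dialect into a :class:`DatasetSchema`.

    Row numbers in error messages count data rows from 1 (header excluded).
    """
    reader = csv.reader(io.StringIO(text))
    rows = [r for r in reader if any(cell.strip() for cell in r)]
    if not rows:
        raise SchemaError("empty metadata document")
    header = [c.strip().lower() for c in rows[0]]
    if header[: len(_METADATA_HEADER)] != _METADATA_HEADER:
        raise SchemaError(f"metadata header must be {','.join(_METADATA_HEADER)!r}, got {','.join(header)!r}")
    specs: list[VariableSpec] = []
    seen: set[str] = set()
    for i, row in enumerate(rows[1:], start=1):
        row = list(row) + [""] * (5 - len(row))
        name, kind_token, lo, hi, legend_text = (c.strip() for c in row[:5])
        if not name:
            raise SchemaError(f"empty variable name at row {i}")
        if name in seen:
            raise SchemaError(f"duplicate name {name!r} at row {i}")
        seen.add(name)
        try:
            kind = VariableKind(kind_token)
        except ValueError:
            raise SchemaError(f"unknown kind {kind_token!r} at row {i}") from None
        valid_range = None
        if kind in RANGED_KINDS:
            if kind is VariableKind.BINARY and not lo and not hi:
                valid_range = (0, 1)
            else:
                if not lo or not hi:
                    raise SchemaError(f"{kind.value} variable {name!r} at row {i} requires min and max")
                try:
                    valid_range = (int(lo), int(hi))
                except ValueError:
                    raise SchemaError(f"non-integer range bound at row {i}") from None
        try:
            specs.append(
                VariableSpec(
                    name=name,
                    kind=kind,
                    valid_range=valid_range,
                    legend=_parse_legend(legend_text, i),
                    missing_sentinel=missing_sentinel,
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{exc} (row {i})") from None
    return DatasetSchema(tuple(specs))


def write_metadata(schema: DatasetSchema) -> str:
    """Serialize a schema back to the metadata CSV dialect (round-trips)."""
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(_METADATA_HEADER)
    for v in schema:
        lo, hi = ("", "")
        if v.valid_range is not None:
            lo, hi = str(v.valid_range[0]), str(v.valid_range[1])
        legend = ""
        if v.legend:
            legend = ";".join(f"{k}={v.legend[k]}" for k in sorted(v.legend))
        writer.writerow([v.name, v.kind.value, lo, hi, legend])
    return out.getvalue()


def lint_schema(schema: DatasetSchema) -> list[str]:
    """Naming-convention warnings: integer counts should carry a ``Num``
    prefix and tooth-lists a ``List`` prefix.  Advisory only."""
    warnings: list[str] = []
    for v in schema:
        if v.kind is VariableKind.TOOTHLIST and not v.name.startswith("List"):
            warnings.append(f"tooth-list variable {v.name!r} should be prefixed 'List'")
        if v.kind in (VariableKind.INTEGER_BOUNDED, VariableKind.INTEGER_UNBOUNDED) and not v.name.startswith("Num"):
            warnings.append(f"integer variable {v.name!r} should be prefixed 'Num'")
    return warnings


# ---------------------------------------------------------------------------
# Dataset loading
# ---------------------------------------------------------------------------


def _parse_cell(raw: str, spec: VariableSpec, row: int) -> tuple[Any, bool]:
    """Parse one raw CSV cell -> (typed value, is_missing)."""
    raw = raw.strip()
    if spec.kind is VariableKind.TOOTHLIST:
        if raw == spec.missing_sentinel:
            return None, True
        if raw == "":
            return frozenset(), False  # empty set, not missing
        codes = []
        for token in raw.split(TOOTHLIST_SEPARATOR):
            token = token.strip()
            try:
                codes.append(int(token))
            except ValueError:
                raise SchemaError(
                    f"unparseable tooth code {token!r} at row {row}, column {spec.name!r}"
                ) from None
        return frozenset(codes), False
    if raw == "" or raw == spec.missing_sentinel:
        return None, True
    try:
        if spec.kind is VariableKind.CONTINUOUS:
            return float(raw), False
        as_float = float(raw)
        if as_float != int(as_float):
            raise ValueError(raw)
        return int(as_float), False
    except ValueError:
        raise SchemaError(f"unparseable cell {raw!r} at row {row}, column {spec.name!r}") from None


def load_dataset(source: str | io.TextIOBase, schema: DatasetSchema) -> ClinicalTable:
    """Load a dataset CSV (text or open stream) against a schema.

    Every header name must be declared in the schema; columns may appear
    in any order but the returned table follows schema order restricted
    to the columns present.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    reader = csv.reader(source)
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError("empty dataset: header row required") from None
    header = [h.strip() for h in header]
    unknown = [h for h in header if h not in schema]
    if unknown:
        raise SchemaError(f"column(s) not declared in schema: {unknown}")
    if len(set(header)) != len(header):
        raise SchemaError("duplicate column in dataset header")
    specs = {h: schema[h] for h in header}
    records: list[list[Any]] = []
    mask_rows: list[list[bool]] = []
    for row_num, row in enumerate(reader, start=1):
        if not any(cell.strip() for cell in row) and len(row) <= 1:
            continue
        if len(row) != len(header):
            raise SchemaError(f"row {row_num} has {len(row)} cells, expected {len(header)}")
        rec, msk = [], []
        for raw, col in zip(row, header):
            value, missing = _parse_cell(raw, specs[col], row_num)
            rec.append(value)
            msk.append(missing)
        records.append(rec)
        mask_rows.append(msk)
    ordered = [n for n in schema.names if n in header]
    values = pd.DataFrame(records, columns=header, dtype=object)[ordered]
    mask = pd.DataFrame(mask_rows, columns=header, dtype=bool)[ordered]
    return ClinicalTable(values, mask)


def write_dataset(table: ClinicalTable, schema: DatasetSchema) -> str:
    """Serialize a table back to the dataset CSV conventions."""
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(table.columns)
    for i in range(table.n_rows):
        row = []
        for col in table.columns:
            spec = schema[col]
            if bool(table.missing_mask.iloc[i][col]):
                row.append(spec.missing_sentinel)
                continue
            value = table.values.iloc[i][col]
            if spec.kind is VariableKind.TOOTHLIST:
                row.append(TOOTHLIST_SEPARATOR.join(str(c) for c in sorted(value)))
            elif spec.kind is VariableKind.CONTINUOUS:
                row.append(repr(float(value)))
            else:
                row.append(str(int(value)))
        writer.writerow(row)
    return out.getvalue()


# ---------------------------------------------------------------------------
# Validation and summaries
# ---------------------------------------------------------------------------


def validate_dataset(table: ClinicalTable, schema: DatasetSchema) -> list[Violation]:
    """Check every non-missing cell against its variable's domain.

    Returns violations as data; never raises on bad values.
    """
    violations: list[Violation] = []
    for col in table.columns:
        spec = schema[col]
        col_values = table.values[col].to_numpy(dtype=object)
        col_mask = table.missing_mask[col].to_numpy(dtype=bool)
        for i in range(table.n_rows):
            if col_mask[i]:
                continue
            value = col_values[i]
            if spec.kind is VariableKind.TOOTHLIST:
                bad = sorted(c for c in value if not is_valid_tooth_code(c))
                for code in bad:
                    violations.append(Violation(i, col, f"invalid tooth code {code}"))
            elif not spec.is_valid_value(value):
                violations.append(Violation(i, col, f"value {value!r} outside domain of {spec.kind.value} variable"))
    return violations


def summarize_dataset(table: ClinicalTable, schema: DatasetSchema, histogram_bins: int = 10) -> dict[str, dict]:
    """Per-variable statistical summary, JSON-serializable.

    Discrete kinds get a frequency table (legend labels when present),
    continuous kinds mean/min/max plus histogram bins, tooth-lists a
    per-code frequency table and cardinality stats.
    """
    summary: dict[str, dict] = {}
    for col in table.columns:
        spec = schema[col]
        col_mask = table.missing_mask[col].to_numpy(dtype=bool)
        observed = [v for v, m in zip(table.values[col], col_mask) if not m]
        entry: dict[str, Any] = {
            "kind": spec.kind.value,
            "n": len(observed),
            "n_missing": int(col_mask.sum()),
        }
        if spec.kind is VariableKind.CONTINUOUS:
            arr = np.asarray(observed, dtype=float)
            if arr.size:
                counts, edges = np.histogram(arr, bins=histogram_bins)
                entry.update(
                    mean=float(arr.mean()),
                    min=float(arr.min()),
                    max=float(arr.max()),
                    std=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                    histogram={"counts": counts.tolist(), "edges": edges.tolist()},
                )
        elif spec.kind is VariableKind.TOOTHLIST:
            code_counts: dict[str, int] = {}
            for cell in observed:
                for code in cell:
                    code_counts[str(code)] = code_counts.get(str(code), 0) + 1
            cards = np.array([len(c) for c in observed], dtype=float)
            entry.update(
                code_frequencies=dict(sorted(code_counts.items())),
                cardinality_mean=float(cards.mean()) if cards.size else 0.0,
                cardinality_max=int(cards.max()) if cards.size else 0,
            )
        else:
            freq: dict[Any, int] = {}
            for v in observed:
                freq[int(v)] = freq.get(int(v), 0) + 1
            labelled = {spec.display_value(k): n for k, n in sorted(freq.items())}
            entry["frequencies"] = labelled
            if spec.kind in (VariableKind.INTEGER_BOUNDED, VariableKind.INTEGER_UNBOUNDED) and observed:
                arr = np.asarray(observed, dtype=float)
                entry.update(mean=float(arr.mean()), min=int(arr.min()), max=int(arr.max()))
        summary[col] = entry
    return summary


def schema_to_dict(schema: DatasetSchema) -> list[dict]:
    """JSON-serializable schema description (used inside model bundles)."""
    out = []
    for v in schema:
        out.append(
            {
                "name": v.name,
                "kind": v.kind.value,
                "valid_range": list(v.valid_range) if v.valid_range else None,
                "legend": {str(k): lbl for k, lbl in v.legend.items()} if v.legend else None,
                "missing_sentinel": v.missing_sentinel,
            }
        )
    return out


def schema_from_dict(data: Sequence[Mapping[str, Any]]) -> DatasetSchema:
    specs = []
    for d in data:
        specs.append(
            VariableSpec(
                name=d["name"],
                kind=VariableKind(d["kind"]),
                valid_range=tuple(d["valid_range"]) if d.get("valid_range") else None,
                legend={int(k): v for k, v in d["legend"].items()} if d.get("legend") else None,
                missing_sentinel=d.get("missing_sentinel", DEFAULT_MISSING_SENTINEL),
            )
        )
    return DatasetSchema(tuple(specs))
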