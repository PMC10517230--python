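"""Loading, error checking, and standardization of participant-level datasets.

The pipeline's contract with raw survey files: load them verbatim in any of
the five supported formats, report every detectable problem *before*
analysis starts, then rename and recode columns to the canonical layout
(``stratum``, ``cluster``, ``weight``, ``age_months``/``age_years``, ``sex``,
canonical biomarker names).  Zero biomarker values are recoded to 0.0001 so
later log transformation is defined; the recode happens in source units,
before SI conversion, and is flagged per row and biomarker for audit.

Missing-value convention: empty cells, pandas' default NA markers, declared
sentinel codes, and values that fail numeric coercion (after a reported
warning) become missing; analysis downstream is complete-case per biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .templates import DatasetDescriptor

__all__ = [
    "RawDataset",
    "StandardizedDataset",
    "ErrorReport",
    "ZERO_RECODE_VALUE",
    "load_raw",
    "check_errors",
    "standardize",
    "recode_zeros",
]

#: Value substituted for exact zeros so ln(x) is defined downstream.
ZERO_RECODE_VALUE = 0.0001

_EXT_FORMAT = {
    ".csv": "csv",
    ".xlsx": "excel",
    ".xls": "excel",
    ".sas7bdat": "sas",
    ".xpt": "sas",
    ".sav": "spss",
    ".dta": "stata",
}

_PLAUSIBLE_AGE = {"PSC": (0.0, 59.0), "WRA": (10.0, 60.0)}  # months / years


@dataclass
class RawDataset:
    """A dataset exactly as read from disk; no values transformed."""

    dataset_id: str
    table: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.table)


@dataclass
class StandardizedDataset:
    """Per-participant records under canonical names and per-biomarker units.

    ``data`` holds the analytic columns; ``units`` maps each biomarker column
    to its current unit (source units after :func:`standardize`, SI units
    after :func:`mnsurvey.units.convert_to_si`); ``flags`` carries per-row
    provenance booleans such as ``zero_recoded_<biomarker>``.
    """

    dataset_id: str
    data: pd.DataFrame
    units: dict[str, str]
    population_group: str
    age_column: str | None  # "age_months" or "age_years"
    has_design: bool
    flags: pd.DataFrame = dc_field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.flags.empty and len(self.flags.columns) == 0:
            self.flags = pd.DataFrame(index=self.data.index)

    @property
    def biomarkers(self) -> list[str]:
        return list(self.units)

    def copy(self) -> "StandardizedDataset":
        return StandardizedDataset(
            self.dataset_id,
            self.data.copy(),
            dict(self.units),
            self.population_group,
            self.age_column,
            self.has_design,
            self.flags.copy(),
        )

    def age_months(self) -> pd.Series | None:
        if self.age_column is None:
            return None
        age = self.data[self.age_column]
        return age if self.age_column == "age_months" else age * 12.0


@dataclass
class ErrorReport:
    """Problems found by :func:`check_errors`; fatal iff any error-severity item."""

    dataset_id: str
    items: list[tuple[str, str, str]] = dc_field(default_factory=list)
    # (severity, field, message)

    def add(self, severity: str, field: str, message: str) -> None:
        self.items.append((severity, field, message))

    @property
    def is_fatal(self) -> bool:
        return any(s == "error" for s, _, _ in self.items)

    @property
    def messages(self) -> list[str]:
        return [f"{s}: [{f}] {m}" for s, f, m in self.items]


def _detect_format(path: Path, declared: str) -> str:
    if declared != "auto":
        return declared
    fmt = _EXT_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise IOError(
            f"cannot auto-detect format of {path.name!r}; declare one of "
            "csv/excel/sas/spss/stata in the template"
        )
    return fmt


def load_raw(descriptor: DatasetDescriptor, base_dir=None) -> RawDataset:
    """Load a dataset file verbatim in its declared or auto-detected format."""
    path = Path(descriptor.file_path)
    if base_dir is not None and not path.is_absolute():
        path = Path(base_dir) / path
    if not path.exists():
        raise IOError(f"dataset {descriptor.dataset_id!r}: file not found: {path}")
    fmt = _detect_format(path, descriptor.file_format)
    try:
        if fmt == "csv":
            # exact decimal→binary parsing keeps CSV on par with binary formats
            table = pd.read_csv(path, float_precision="round_trip")
        elif fmt == "excel":
            table = pd.read_excel(path)
        elif fmt == "sas":
            table = pd.read_sas(path)
        elif fmt == "spss":
            from ._savio import read_sav

            table = read_sav(path)
        elif fmt == "stata":
            table = pd.read_stata(path)
        else:  # pragma: no cover - constrained by descriptor validation
            raise IOError(f"unsupported format {fmt!r}")
    except IOError:
        raise
    except Exception as exc:
        raise IOError(
            f"dataset {descriptor.dataset_id!r}: could not read {path.name!r} "
            f"as {fmt}: {exc}"
        ) from exc
    # SAS readers return bytes for character data
    for c in table.columns:
        if table[c].dtype == object:
            table[c] = table[c].map(
                lambda v: v.decode("ascii", "replace") if isinstance(v, bytes) else v
            )
    if fmt == "sas":
        # the IBM hex-float zero decodes to ~5.4e-79 under pandas; no
        # physical concentration is that small, so restore exact zeros
        for c in table.columns:
            if pd.api.types.is_float_dtype(table[c]):
                tiny = table[c].abs() < 1e-75
                if tiny.any():
                    table.loc[tiny, c] = 0.0
    if len(table) == 0:
        raise IOError(f"dataset {descriptor.dataset_id!r}: empty dataset in {path.name!r}")
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()].tolist()
        raise IOError(f"dataset {descriptor.dataset_id!r}: duplicated column(s) {dup}")
    return RawDataset(descriptor.dataset_id, table)


def _coercion_failures(s: pd.Series) -> pd.Index:
    coerced = pd.to_numeric(s, errors="coerce")
    return s.index[s.notna() & (s.astype(str).str.strip() != "") & coerced.isna()]


def check_errors(raw: RawDataset, descriptor: DatasetDescriptor) -> ErrorReport:
    """Validate the raw table against its descriptor; pure, report-returning."""
    rep = ErrorReport(raw.dataset_id)
    cols = set(raw.table.columns)

    mapped: list[tuple[str, str]] = []  # (field, source column)
    for f_name in ("stratum", "cluster", "weight", "age_column", "sex_column"):
        v = getattr(descriptor, f_name)
        if v:
            mapped.append((f_name, v))
    for b in descriptor.biomarkers:
        mapped.append((b.biomarker, b.source_column))

    for f_name, col in mapped:
        if col not in cols:
            rep.add("error", f_name, f"variable {col!r} not found in the dataset")

    # duplicate source-column mapping
    sources = [c for _, c in mapped]
    for col in sorted({c for c in sources if sources.count(c) > 1}):
        fields = [f for f, c in mapped if c == col]
        rep.add("error", ",".join(fields), f"column {col!r} mapped to multiple fields")

    def numeric_check(f_name: str, col: str) -> pd.Series | None:
        if col not in cols:
            return None
        bad = _coercion_failures(raw.table[col])
        if len(bad):
            shown = list(bad[:10])
            rep.add(
                "error",
                f_name,
                f"{len(bad)} non-numeric value(s) in {col!r}, e.g. rows {shown}",
            )
            return None
        return pd.to_numeric(raw.table[col], errors="coerce")

    for b in descriptor.biomarkers:
        vals = numeric_check(b.biomarker, b.source_column)
        if vals is not None and (vals < 0).any():
            n = int((vals < 0).sum())
            rep.add("error", b.biomarker, f"{n} negative value(s) in {b.source_column!r}")

    if descriptor.weight:
        w = numeric_check("weight", descriptor.weight)
        if w is not None and (w.dropna() <= 0).any():
            n = int((w.dropna() <= 0).sum())
            rep.add("error", "weight", f"{n} non-positive sampling weight(s)")

    if descriptor.age_column:
        age = numeric_check("age_column", descriptor.age_column)
        bounds = _PLAUSIBLE_AGE.get(descriptor.population_group)
        if age is not None and bounds is not None:
            lo, hi = bounds
            a = age.dropna()
            if descriptor.population_group == "PSC" and descriptor.age_unit == "years":
                a = a * 12.0
            if descriptor.population_group == "WRA" and descriptor.age_unit == "months":
                a = a / 12.0
            n_out = int(((a < lo) | (a > hi)).sum())
            if n_out:
                unit = "months" if descriptor.population_group == "PSC" else "years"
                rep.add(
                    "warning",
                    "age_column",
                    f"{n_out} age value(s) outside the plausible "
                    f"{descriptor.population_group} range [{lo}, {hi}] {unit}",
                )

    if descriptor.sex_column and descriptor.sex_column in cols:
        if not descriptor.sex_coding:
            rep.add("error", "sex_coding", "sex variable mapped without a coding")
        else:
            codes = {str(v).strip() for v in descriptor.sex_coding.values()}
            observed = {
                str(v).strip()
                for v in raw.table[descriptor.sex_column].dropna()
                if str(v).strip() != ""
            }
            # numeric storage may render "1" as "1.0"
            normalized = {o.removesuffix(".0") for o in observed}
            unexpected = sorted(normalized - codes)
            if unexpected:
                rep.add(
                    "warning",
                    "sex_column",
                    f"sex value(s) outside the declared coding: {unexpected[:10]} "
                    "(treated as missing)",
                )
    return rep


def standardize(raw: RawDataset, descriptor: DatasetDescriptor) -> StandardizedDataset:
    """Rename to canonical columns, coerce numerics, recode sex, convert age.

    Row order is preserved; unmapped columns are dropped from the analytic
    table.  Requires :func:`check_errors` to have passed without fatal items.
    """
    t = raw.table
    out = pd.DataFrame(index=t.index)

    for canon, source in (
        ("stratum", descriptor.stratum),
        ("cluster", descriptor.cluster),
    ):
        if source:
            out[canon] = t[source]
    if descriptor.weight:
        out["weight"] = pd.to_numeric(t[descriptor.weight], errors="coerce")

    age_column = None
    if descriptor.age_column:
        age = pd.to_numeric(t[descriptor.age_column], errors="coerce")
        if descriptor.population_group == "PSC":
            age_column = "age_months"
            out[age_column] = age * 12.0 if descriptor.age_unit == "years" else age
        else:
            age_column = "age_years"
            out[age_column] = age / 12.0 if descriptor.age_unit == "months" else age

    if descriptor.sex_column:
        code_to_level = {
            str(code).strip(): level for level, code in descriptor.sex_coding.items()
        }
        raw_sex = t[descriptor.sex_column].map(
            lambda v: "" if pd.isna(v) else str(v).strip().removesuffix(".0")
        )
        out["sex"] = raw_sex.map(code_to_level).astype(object)
        out.loc[out["sex"].isna(), "sex"] = None

    units: dict[str, str] = {}
    for b in descriptor.biomarkers:
        out[b.biomarker] = pd.to_numeric(t[b.source_column], errors="coerce")
        units[b.biomarker] = b.source_unit

    flags = pd.DataFrame(index=t.index)
    return StandardizedDataset(
        dataset_id=raw.dataset_id,
        data=out,
        units=units,
        population_group=descriptor.population_group,
        age_column=age_column,
        has_design=descriptor.has_design,
        flags=flags,
    )


def recode_zeros(ds: StandardizedDataset) -> StandardizedDataset:
    """Replace exact biomarker zeros by ``ZERO_RECODE_VALUE``, flagging rows.

    Applied in the column's current (source) unit, before SI conversion, so
    the substituted constant is exactly 0.0001.  Idempotent; negative values
    are never touched here (they are rejected by :func:`check_errors`).
    """
    out = ds.copy()
    for bm in ds.biomarkers:
        mask = out.data[bm] == 0.0
        flag_col = f"zero_recoded_{bm}"
        if flag_col not in out.flags.columns:
            out.flags[flag_col] = False
        if mask.any():
            out.data.loc[mask, bm] = ZERO_RECODE_VALUE
            out.flags.loc[mask, flag_col] = True
    return out
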