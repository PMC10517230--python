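"""The two user-facing configuration artifacts.

A run is driven by two small tables the analyst fills in:

* the **dataset template** — one column per survey dataset, rows naming the
  file, its format, the survey-design variables (strata, cluster, weight),
  the demographic variables (age with its unit, sex with its coding), the
  population group, and one variable/unit row pair per biomarker;
* the **cutoff template** — one row per deficiency rule: biomarker,
  condition label, population group, sex, age range (with its unit),
  direction, threshold in the biomarker's SI unit, and whether the rule is
  applied to the inflammation-adjusted value.

Both are accepted as CSV or Excel, recognized by extension.  Row labels and
enumerated values are matched case-insensitively with surrounding whitespace
stripped.  Age intervals are closed on both ends.  A packaged default cutoff
table ships with the library; users override it by supplying their own file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .units import CANONICAL_UNITS, default_registry

__all__ = [
    "BiomarkerMapping",
    "DatasetDescriptor",
    "CutoffRule",
    "CutoffTable",
    "ValidationReport",
    "TemplateError",
    "load_dataset_template",
    "write_dataset_template",
    "load_cutoff_template",
    "default_cutoffs",
    "validate_templates",
]

PopulationGroup = Literal["PSC", "WRA", "other"]
RuleGroup = Literal["PSC", "WRA", "male", "female", "any"]
AgeUnit = Literal["months", "years"]

#: Fixed field rows of the dataset template, in canonical order.
DATASET_TEMPLATE_FIELDS = (
    "file",
    "format",
    "strata",
    "cluster",
    "weight",
    "age",
    "age_unit",
    "sex",
    "sex_coding",
    "population_group",
)


class TemplateError(ValueError):
    """A template failed validation; the message names the offending entry."""


class BiomarkerMapping(BaseModel):
    """One biomarker: its canonical name, source column, and source unit."""

    biomarker: str
    source_column: str
    source_unit: str


class DatasetDescriptor(BaseModel):
    """Everything the pipeline needs to know about one input dataset."""

    dataset_id: str = Field(min_length=1)
    file_path: str
    file_format: Literal["csv", "excel", "sas", "spss", "stata", "auto"] = "auto"
    stratum: Optional[str] = None
    cluster: Optional[str] = None
    weight: Optional[str] = None
    age_column: Optional[str] = None
    age_unit: AgeUnit = "years"
    sex_column: Optional[str] = None
    sex_coding: dict[str, str] = Field(default_factory=dict)  # {"male": "1", ...}
    population_group: PopulationGroup = "other"
    biomarkers: list[BiomarkerMapping] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "DatasetDescriptor":
        names = [b.biomarker for b in self.biomarkers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TemplateError(
                f"dataset {self.dataset_id!r}: biomarker(s) mapped more than once: "
                f"{sorted(dupes)}"
            )
        if (self.stratum or self.cluster) and not self.weight:
            raise TemplateError(
                f"dataset {self.dataset_id!r}: survey design declared without a "
                "weight variable"
            )
        return self

    @property
    def has_design(self) -> bool:
        return self.weight is not None

    def biomarker_map(self) -> dict[str, BiomarkerMapping]:
        return {b.biomarker: b for b in self.biomarkers}


class CutoffRule(BaseModel):
    """One deficiency threshold with its applicability window."""

    biomarker: str
    condition_label: str
    group: RuleGroup = "any"
    sex: Literal["male", "female", "any"] = "any"
    age_min: float
    age_max: float
    age_unit: AgeUnit
    direction: Literal["below", "above"]
    threshold: float
    threshold_unit: Optional[str] = None
    use_adjusted: bool = True
    source: str = ""

    @field_validator("threshold")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise TemplateError(f"cutoff threshold must be > 0, got {v}")
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "CutoffRule":
        if not self.age_min < self.age_max:
            raise TemplateError(
                f"{self.biomarker}/{self.condition_label}: age_min ({self.age_min}) "
                f"must be < age_max ({self.age_max})"
            )
        return self

    def age_range_months(self) -> tuple[float, float]:
        f = 12.0 if self.age_unit == "years" else 1.0
        return self.age_min * f, self.age_max * f

    def _population_set(self) -> frozenset[str]:
        if self.group == "PSC":
            return frozenset({"PSC"})
        if self.group == "WRA":
            return frozenset({"WRA"})
        return frozenset({"PSC", "WRA", "other"})

    def _sex_set(self) -> frozenset[str]:
        implied = {
            "male": {"male"},
            "female": {"female"},
            "WRA": {"female"},
        }.get(self.group, {"male", "female"})
        explicit = {"male", "female"} if self.sex == "any" else {self.sex}
        return frozenset(implied & explicit)

    def overlaps(self, other: "CutoffRule") -> bool:
        """Could any participant be covered by both rules?"""
        if not self._population_set() & other._population_set():
            return False
        if not self._sex_set() & other._sex_set():
            return False
        a0, a1 = self.age_range_months()
        b0, b1 = other.age_range_months()
        return max(a0, b0) <= min(a1, b1)

    def matches(
        self,
        population_group: str,
        sex: Optional[str],
        age_months: Optional[float],
    ) -> bool:
        """Does this rule apply to one participant? Age interval is closed."""
        if self.group in ("PSC", "WRA"):
            if population_group != self.group:
                return False
        elif self.group in ("male", "female"):
            if sex != self.group:
                return False
        if self.sex != "any" and sex != self.sex:
            return False
        if age_months is None or pd.isna(age_months):
            return False
        lo, hi = self.age_range_months()
        return lo <= age_months <= hi


@dataclass
class CutoffTable:
    """An ordered, overlap-free collection of cutoff rules."""

    rules: list[CutoffRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_condition: dict[tuple[str, str], list[tuple[int, CutoffRule]]] = {}
        for i, r in enumerate(self.rules):
            by_condition.setdefault((r.biomarker, r.condition_label), []).append((i, r))
        collisions = []
        for (bm, cond), rs in by_condition.items():
            for i in range(len(rs)):
                for j in range(i + 1, len(rs)):
                    if rs[i][1].overlaps(rs[j][1]):
                        collisions.append((bm, cond, rs[i][0], rs[j][0]))
        if collisions:
            lines = ", ".join(
                f"{bm}/{cond} rows {i} and {j}" for bm, cond, i, j in collisions
            )
            raise TemplateError(f"overlapping cutoff rules: {lines}")

    def biomarkers(self) -> set[str]:
        return {r.biomarker for r in self.rules}

    def rules_for(self, biomarker: str) -> list[CutoffRule]:
        return [r for r in self.rules if r.biomarker == biomarker]

    def lookup(
        self,
        biomarker: str,
        population_group: str,
        age_months: float,
        sex: Optional[str] = None,
        condition_label: Optional[str] = None,
    ) -> list[CutoffRule]:
        """All rules applying to one participant (≤ 1 per condition label)."""
        out = [
            r
            for r in self.rules
            if r.biomarker == biomarker
            and (condition_label is None or r.condition_label == condition_label)
            and r.matches(population_group, sex, age_months)
        ]
        return out


@dataclass
class ValidationReport:
    """Cross-check result for a (descriptors, cutoff table) pair."""

    items: list[tuple[str, str]] = field(default_factory=list)  # (severity, message)

    @property
    def warnings(self) -> list[str]:
        return [m for s, m in self.items if s == "warning"]

    @property
    def errors(self) -> list[str]:
        return [m for s, m in self.items if s == "error"]

    @property
    def empty(self) -> bool:
        return not self.items


# ---------------------------------------------------------------------------
# physical template reading/writing


def _read_table(path, header) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"template file not found: {p}")
    suffix = p.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(p, header=header, dtype=str)
    return pd.read_csv(p, header=header, dtype=str, keep_default_na=False)


def _canon(s: str) -> str:
    return str(s).strip().lower()


def _parse_sex_coding(raw: str, dataset_id: str) -> dict[str, str]:
    # "male=1,female=2"
    coding: dict[str, str] = {}
    for part in raw.split(","):
        if "=" not in part:
            raise TemplateError(
                f"dataset {dataset_id!r}: sex_coding entry {part!r} is not "
                "'level=code'"
            )
        level, code = part.split("=", 1)
        level = _canon(level)
        if level not in ("male", "female"):
            raise TemplateError(
                f"dataset {dataset_id!r}: sex_coding level {level!r} must be "
                "male or female"
            )
        coding[level] = code.strip()
    return coding


def load_dataset_template(path) -> list[DatasetDescriptor]:
    """Parse the dataset template (rows = fields, one column per dataset)."""
    raw = _read_table(path, header=None)
    if raw.shape[1] < 2:
        raise TemplateError("dataset template needs a field column plus >= 1 dataset column")
    header = [str(v).strip() for v in raw.iloc[0]]
    ids = header[1:]
    seen: dict[str, int] = {}
    for i, ds_id in enumerate(ids, start=2):
        key = ds_id.lower()
        if key in seen and ds_id:
            raise TemplateError(
                f"duplicated dataset_id {ds_id!r} in template columns "
                f"{seen[key]} and {i}"
            )
        seen[key] = i

    body = raw.iloc[1:]
    fields = {}
    for _, row in body.iterrows():
        label = _canon(row.iloc[0])
        if label:
            fields[label] = [("" if pd.isna(v) else str(v).strip()) for v in row.iloc[1:]]

    registry = default_registry()
    descriptors: list[DatasetDescriptor] = []
    for col, ds_id in enumerate(ids):
        def get(field_name: str) -> str:
            vals = fields.get(field_name)
            return vals[col] if vals else ""

        if not ds_id or not get("file"):
            continue  # empty template column

        biomarkers = []
        for label, vals in fields.items():
            if not label.endswith("_var") or label in DATASET_TEMPLATE_FIELDS:
                continue
            bm = label[: -len("_var")]
            source = vals[col]
            if not source:
                continue
            unit = fields.get(f"{bm}_unit", [""] * len(ids))[col]
            if not unit:
                raise TemplateError(
                    f"dataset {ds_id!r}: biomarker {bm!r} mapped without a unit"
                )
            if bm in CANONICAL_UNITS and not registry.knows(bm, unit):
                raise TemplateError(
                    f"dataset {ds_id!r}: unknown unit {unit!r} for biomarker {bm!r}"
                )
            biomarkers.append(
                BiomarkerMapping(biomarker=bm, source_column=source, source_unit=unit)
            )
        biomarkers.sort(key=lambda b: b.biomarker)

        fmt = _canon(get("format")) or "auto"
        group = get("population_group").strip() or "other"
        group = {"psc": "PSC", "wra": "WRA", "other": "other"}.get(group.lower())
        if group is None:
            raise TemplateError(
                f"dataset {ds_id!r}: population_group must be PSC, WRA or other"
            )
        age_unit = _canon(get("age_unit")) or ("months" if group == "PSC" else "years")
        sex_raw = get("sex_coding")
        try:
            descriptor = DatasetDescriptor(
                dataset_id=ds_id,
                file_path=get("file"),
                file_format=fmt,  # type: ignore[arg-type]
                stratum=get("strata") or None,
                cluster=get("cluster") or None,
                weight=get("weight") or None,
                age_column=get("age") or None,
                age_unit=age_unit,  # type: ignore[arg-type]
                sex_column=get("sex") or None,
                sex_coding=_parse_sex_coding(sex_raw, ds_id) if sex_raw else {},
                population_group=group,  # type: ignore[arg-type]
                biomarkers=biomarkers,
            )
        except Exception as exc:  # pydantic wraps the underlying message
            raise TemplateError(f"dataset {ds_id!r}: {exc}") from exc
        descriptors.append(descriptor)
    if not descriptors:
        raise TemplateError("dataset template contains no non-empty dataset columns")
    return descriptors


def write_dataset_template(descriptors: list[DatasetDescriptor], path) -> None:
    """Serialize descriptors back to the template layout (CSV)."""
    bms = sorted({b.biomarker for d in descriptors for b in d.biomarkers})
    rows = list(DATASET_TEMPLATE_FIELDS)
    for bm in bms:
        rows += [f"{bm}_var", f"{bm}_unit"]
    table = {"field": rows}
    for d in descriptors:
        m = d.biomarker_map()
        coding = ",".join(f"{k}={v}" for k, v in sorted(d.sex_coding.items()))
        col = {
            "file": d.file_path,
            "format": "" if d.file_format == "auto" else d.file_format,
            "strata": d.stratum or "",
            "cluster": d.cluster or "",
            "weight": d.weight or "",
            "age": d.age_column or "",
            "age_unit": d.age_unit,
            "sex": d.sex_column or "",
            "sex_coding": coding,
            "population_group": d.population_group,
        }
        for bm in bms:
            col[f"{bm}_var"] = m[bm].source_column if bm in m else ""
            col[f"{bm}_unit"] = m[bm].source_unit if bm in m else ""
        table[d.dataset_id] = [col[r] for r in rows]
    pd.DataFrame(table).to_csv(path, index=False)


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def load_cutoff_template(path) -> CutoffTable:
    """Parse a cutoff template (one row per rule)."""
    df = _read_table(path, header=0)
    df.columns = [_canon(c) for c in df.columns]
    required = {
        "biomarker", "condition_label", "group", "age_min", "age_max",
        "age_unit", "direction", "threshold",
    }
    missing = required - set(df.columns)
    if missing:
        raise TemplateError(f"cutoff template missing column(s): {sorted(missing)}")
    rules = []
    for i, row in df.iterrows():
        def cell(name: str, default: str = "") -> str:
            v = row.get(name, default)
            return default if pd.isna(v) else str(v).strip()

        if not cell("biomarker"):
            continue
        adj_raw = _canon(cell("use_adjusted", "true")) or "true"
        if adj_raw not in _BOOL:
            raise TemplateError(f"cutoff row {i}: use_adjusted {adj_raw!r} not boolean")
        try:
            rules.append(
                CutoffRule(
                    biomarker=_canon(cell("biomarker")),
                    condition_label=_canon(cell("condition_label")),
                    group=cell("group") or "any",  # type: ignore[arg-type]
                    sex=_canon(cell("sex", "any")) or "any",  # type: ignore[arg-type]
                    age_min=float(cell("age_min")),
                    age_max=float(cell("age_max")),
                    age_unit=_canon(cell("age_unit")),  # type: ignore[arg-type]
                    direction=_canon(cell("direction")),  # type: ignore[arg-type]
                    threshold=float(cell("threshold")),
                    threshold_unit=cell("threshold_unit") or None,
                    use_adjusted=_BOOL[adj_raw],
                    source=cell("source"),
                )
            )
        except (ValueError, TypeError) as exc:
            raise TemplateError(f"cutoff template row {i}: {exc}") from exc
    return CutoffTable(rules)


def default_cutoffs() -> CutoffTable:
    """The cutoff table shipped with the package (see data/default_cutoffs.csv)."""
    with resources.as_file(
        resources.files("mnsurvey.data").joinpath("default_cutoffs.csv")
    ) as p:
        return load_cutoff_template(p)


def validate_templates(
    descriptors: list[DatasetDescriptor], cutoffs: CutoffTable
) -> ValidationReport:
    """Cross-check the two templates; report-returning, never mutates."""
    report = ValidationReport()
    mapped = {b.biomarker for d in descriptors for b in d.biomarkers}
    unused = cutoffs.biomarkers() - mapped
    for bm in sorted(unused):
        report.items.append(
            ("warning", f"cutoff rules for {bm!r} unused: not mapped in any dataset")
        )
    for d in descriptors:
        applicable = [
            r
            for r in cutoffs.rules
            if r.biomarker in {b.biomarker for b in d.biomarkers}
            and (r.group not in ("PSC", "WRA") or r.group == d.population_group)
        ]
        if d.biomarkers and cutoffs.rules and not applicable:
            report.items.append(
                (
                    "warning",
                    f"dataset {d.dataset_id!r} (group {d.population_group}): no "
                    "cutoff rule applies to any mapped biomarker",
                )
            )
    return report
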