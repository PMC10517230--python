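"""End-to-end orchestration: templates → ingest → units → adjustment → report.

One call runs the whole analysis for the first ``n_datasets`` columns of the
dataset template: each dataset is loaded, error-checked, standardized,
SI-converted, zero-recoded, inflammation-adjusted where applicable,
classified against the cutoff table and summarized with its own survey
design.  A dataset that fails validation is reported and skipped; the run
continues with the remaining datasets and exits nonzero if any failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import brinda, ingest, report, units
from .survey import SurveyDesign
from .templates import (
    CutoffTable,
    default_cutoffs,
    load_cutoff_template,
    load_dataset_template,
    validate_templates,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("mnsurvey")


@dataclass
class RunConfig:
    """The five run inputs plus optional module pass-through settings."""

    data_template: Path
    cutoff_template: Optional[Path] = None  # None → packaged defaults
    n_datasets: int | str = "all"
    output_dir: Path = Path(".")
    output_name: str = "mnsurvey"
    log_level: str = "INFO"
    units_file: Optional[Path] = None  # extra CSV of unit conversions
    lonely_psu: str = "error"
    adjustment: brinda.AdjustmentConfig = field(default_factory=brinda.AdjustmentConfig)


@dataclass
class DatasetStatus:
    dataset_id: str
    ok: bool
    messages: list[str] = field(default_factory=list)
    clean_path: Optional[Path] = None


@dataclass
class PipelineResult:
    exit_code: int
    datasets: list[DatasetStatus]
    summary_path: Optional[Path]
    summary: Optional[pd.DataFrame]


def _load_units(config: RunConfig) -> units.ConversionRegistry:
    reg = units.default_registry()
    if config.units_file is not None:
        extra = pd.read_csv(config.units_file)
        for _, r in extra.iterrows():
            reg.register(
                units.UnitConversion(
                    str(r["biomarker"]).strip(),
                    str(r["from_unit"]).strip(),
                    str(r["to_unit"]).strip(),
                    float(r["factor"]),
                )
            )
    return reg


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; see module docstring for semantics."""
    logging.basicConfig(level=config.log_level)
    descriptors = load_dataset_template(config.data_template)
    cutoffs: CutoffTable = (
        default_cutoffs()
        if config.cutoff_template is None
        else load_cutoff_template(config.cutoff_template)
    )
    cross = validate_templates(descriptors, cutoffs)
    for msg in cross.warnings:
        log.warning(msg)

    if config.n_datasets != "all":
        k = int(config.n_datasets)
        if k < 1 or k > len(descriptors):
            raise ValueError(
                f"n_datasets={k} outside 1..{len(descriptors)} template columns"
            )
        descriptors = descriptors[:k]

    registry = _load_units(config)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_dir = Path(config.data_template).resolve().parent

    statuses: list[DatasetStatus] = []
    summaries: list[pd.DataFrame] = []
    for d in descriptors:
        status = DatasetStatus(d.dataset_id, ok=False)
        statuses.append(status)
        try:
            raw = ingest.load_raw(d, base_dir=base_dir)
            errors = ingest.check_errors(raw, d)
            status.messages.extend(errors.messages)
            for m in errors.messages:
                log.warning("%s: %s", d.dataset_id, m)
            if errors.is_fatal:
                log.error("%s: fatal validation errors; dataset skipped", d.dataset_id)
                continue
            ds = ingest.standardize(raw, d)
            ds = ingest.recode_zeros(ds)
            ds = units.convert_to_si(ds, registry)
            adj = brinda.adjust_dataset(ds, config.adjustment)
            for w in adj.warnings:
                log.warning("%s: adjustment: %s", d.dataset_id, w)
            if adj.bypassed:
                log.info("%s: adjustment bypassed: %s", d.dataset_id, adj.reason)
            calls = report.classify_deficiency(ds, adj, cutoffs)
            design = (
                SurveyDesign.from_frame(
                    ds.data,
                    stratum="stratum" if "stratum" in ds.data.columns else None,
                    cluster="cluster" if "cluster" in ds.data.columns else None,
                    weight="weight",
                    lonely_psu=config.lonely_psu,  # type: ignore[arg-type]
                )
                if ds.has_design
                else SurveyDesign(lonely_psu=config.lonely_psu)  # type: ignore[arg-type]
            )
            summary_warnings: list[str] = []
            summary = report.summarize_dataset(ds, adj, calls, design, summary_warnings)
            for w in summary_warnings:
                log.warning("%s: summary: %s", d.dataset_id, w)
            clean_path = out_dir / f"{config.output_name}_{d.dataset_id}_clean.csv"
            report.write_clean_dataset(ds, adj, calls, clean_path)
            status.clean_path = clean_path
            summaries.append(summary)
            status.ok = True
        except (IOError, ValueError) as exc:
            status.messages.append(str(exc))
            log.error("%s: %s", d.dataset_id, exc)

    summary_path = None
    combined = None
    if summaries:
        combined = pd.concat(summaries, ignore_index=True)
        summary_path = out_dir / f"{config.output_name}_summary.csv"
        report.write_summary_report(combined, summary_path)

    exit_code = 0 if all(s.ok for s in statuses) and statuses else 1
    return PipelineResult(exit_code, statuses, summary_path, combined)
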