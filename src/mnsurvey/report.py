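"""Deficiency classification and the two output artifacts.

Classification compares each participant's analysis value — the
inflammation-adjusted concentration when the rule asks for it and adjustment
ran, otherwise the unadjusted one — against the cutoff rule matching the
participant's population group, sex and age.  Comparisons are strict: a
value exactly at the threshold is *not* deficient.  Participants with a
missing value or no matching rule get a missing call and drop out of the
prevalence denominator (the reported ``n`` keeps the denominator auditable).

Outputs are RFC-4180 CSV, UTF-8, ``.`` decimal separator, deterministic
(no timestamps; fixed column order), named
``<output_name>_<dataset_id>_clean.csv`` and ``<output_name>_summary.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .brinda import AdjustmentResult
from .ingest import StandardizedDataset
from .survey import (
    SurveyDesign,
    SummaryEstimate,
    geometric_mean,
    prevalence,
    weighted_mean,
    weighted_quantile,
)
from .templates import CutoffRule, CutoffTable

__all__ = [
    "DeficiencyCalls",
    "classify_deficiency",
    "summarize_dataset",
    "write_clean_dataset",
    "write_summary_report",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "dataset_id",
    "biomarker",
    "condition",
    "statistic",
    "adjusted",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "n",
    "n_weighted",
    "cutoff_used",
    "display",
]

_DISTRIBUTION_STATS = (
    ("mean", weighted_mean),
    ("geometric_mean", geometric_mean),
    ("q25", lambda v, d: weighted_quantile(v, d, 0.25)),
    ("median", lambda v, d: weighted_quantile(v, d, 0.50)),
    ("q75", lambda v, d: weighted_quantile(v, d, 0.75)),
)


@dataclass
class DeficiencyCalls:
    """Per-participant calls, one column per (biomarker, condition)."""

    calls: pd.DataFrame  # float columns: 1.0 deficient, 0.0 not, NaN no call
    meta: dict[str, dict] = field(default_factory=dict)
    # column -> {"biomarker", "condition", "adjusted", "thresholds": set}

    @property
    def conditions(self) -> list[str]:
        return list(self.calls.columns)


def _call_column(biomarker: str, condition: str) -> str:
    return condition if condition.startswith(biomarker) else f"{condition}"


def classify_deficiency(
    ds: StandardizedDataset,
    adjustment: Optional[AdjustmentResult],
    cutoffs: CutoffTable,
) -> DeficiencyCalls:
    """Apply every matching cutoff rule; strict inequalities at the threshold."""
    n = len(ds.data)
    age_m = ds.age_months()
    sex = ds.data["sex"] if "sex" in ds.data.columns else pd.Series([None] * n, index=ds.data.index)

    calls = pd.DataFrame(index=ds.data.index)
    meta: dict[str, dict] = {}
    for rule in cutoffs.rules:
        if rule.biomarker not in ds.data.columns:
            continue
        use_adj = bool(
            rule.use_adjusted
            and adjustment is not None
            and not adjustment.bypassed
            and rule.biomarker in adjustment.adjusted.columns
        )
        values = (
            adjustment.adjusted[rule.biomarker] if use_adj else ds.data[rule.biomarker]
        )
        applies = pd.Series(
            [
                rule.matches(
                    ds.population_group,
                    sex.iloc[i] if pd.notna(sex.iloc[i]) else None,
                    None if age_m is None else age_m.iloc[i],
                )
                for i in range(n)
            ],
            index=ds.data.index,
        )
        col = _call_column(rule.biomarker, rule.condition_label)
        if col not in calls.columns:
            calls[col] = np.nan
            meta[col] = {
                "biomarker": rule.biomarker,
                "condition": rule.condition_label,
                "adjusted": use_adj,
                "thresholds": set(),
            }
        mask = applies & values.notna()
        if rule.direction == "below":
            verdict = values < rule.threshold
        else:
            verdict = values > rule.threshold
        calls.loc[mask, col] = verdict[mask].astype(float)
        if mask.any():
            meta[col]["thresholds"].add(rule.threshold)
            meta[col]["adjusted"] = use_adj
    return DeficiencyCalls(calls, meta)


def _row(
    ds_id: str,
    biomarker: str,
    condition: str,
    statistic: str,
    adjusted: bool,
    est: SummaryEstimate,
    cutoff_used: Optional[float],
) -> dict:
    def r(v):
        return None if v is None else round(v, 2)

    if est.ci_low is not None:
        display = f"{r(est.estimate)} ({r(est.ci_low)}, {r(est.ci_high)})"
    else:
        display = f"{r(est.estimate)}"
    return {
        "dataset_id": ds_id,
        "biomarker": biomarker,
        "condition": condition,
        "statistic": statistic,
        "adjusted": adjusted,
        "estimate": est.estimate,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n": est.n,
        "n_weighted": est.n_weighted,
        "cutoff_used": cutoff_used,
        "display": display,
    }


def summarize_dataset(
    ds: StandardizedDataset,
    adjustment: Optional[AdjustmentResult],
    calls: DeficiencyCalls,
    design: Optional[SurveyDesign] = None,
    warnings: Optional[list[str]] = None,
) -> pd.DataFrame:
    """One summary row per (biomarker, statistic[, condition], adjusted flag).

    Distribution statistics are reported for the unadjusted values of every
    biomarker and, when adjustment ran, additionally for the adjusted values.
    Prevalences come from the survey engine applied to the classification
    indicator on the identical analysis subset.
    """
    if design is None:
        if ds.has_design:
            design = SurveyDesign.from_frame(
                ds.data,
                stratum="stratum" if "stratum" in ds.data.columns else None,
                cluster="cluster" if "cluster" in ds.data.columns else None,
                weight="weight",
            )
        else:
            design = SurveyDesign()
    warnings = warnings if warnings is not None else []

    rows: list[dict] = []
    adj_cols = (
        [] if adjustment is None or adjustment.bypassed
        else list(adjustment.adjusted.columns)
    )
    for bm in ds.biomarkers:
        versions: list[tuple[bool, pd.Series]] = [(False, ds.data[bm])]
        if bm in adj_cols:
            versions.append((True, adjustment.adjusted[bm]))
        for adjusted, values in versions:
            if values.notna().sum() == 0:
                warnings.append(f"{bm}: no non-missing values; omitted from summary")
                continue
            for stat_name, fn in _DISTRIBUTION_STATS:
                est = fn(values.to_numpy(dtype=float), design)
                rows.append(
                    _row(ds.dataset_id, bm, "distribution", stat_name, adjusted, est, None)
                )
    for col in calls.conditions:
        info = calls.meta[col]
        indicator = calls.calls[col]
        if indicator.notna().sum() == 0:
            warnings.append(f"{col}: no classifiable participants; omitted")
            continue
        est = prevalence(indicator.to_numpy(dtype=float), design)
        thresholds = info["thresholds"]
        cutoff = thresholds.pop() if len(thresholds) == 1 else None
        if cutoff is not None:
            info["thresholds"].add(cutoff)
        rows.append(
            _row(
                ds.dataset_id,
                info["biomarker"],
                info["condition"],
                "prevalence",
                info["adjusted"],
                est,
                cutoff,
            )
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_clean_dataset(
    ds: StandardizedDataset,
    adjustment: Optional[AdjustmentResult],
    calls: Optional[DeficiencyCalls],
    path,
) -> Path:
    """Write the per-participant cleaned CSV (canonical names, SI units,
    ``_adj`` columns when adjustment ran, provenance flags, deficiency calls)."""
    path = Path(path)
    frames = [ds.data]
    if adjustment is not None and not adjustment.bypassed:
        frames.append(adjustment.adjusted.add_suffix("_adj"))
        frames.append(adjustment.skipped.add_suffix("_adj_skipped"))
    if not ds.flags.empty:
        frames.append(ds.flags)
    if calls is not None and not calls.calls.empty:
        frames.append(calls.calls.add_prefix("def_"))
    out = pd.concat(frames, axis=1)
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if adjustment is not None and adjustment.bypassed:
                fh.write(f"# inflammation adjustment bypassed: {adjustment.reason}\n")
            out.to_csv(fh, index=False)
    except OSError as exc:
        raise IOError(f"cannot write clean dataset to {path}: {exc}") from exc
    return path


def write_summary_report(rows: pd.DataFrame, path) -> Path:
    """Write the cross-dataset summary CSV (full precision + display column)."""
    if rows.empty:
        raise ValueError("no summary rows to write")
    path = Path(path)
    out = rows[SUMMARY_COLUMNS]
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            out.to_csv(fh, index=False)
    except OSError as exc:
        raise IOError(f"cannot write summary report to {path}: {exc}") from exc
    return path
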