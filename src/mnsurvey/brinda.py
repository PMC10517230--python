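"""BRINDA regression-correction inflammation adjustment.

Acute-phase inflammation shifts several micronutrient biomarkers away from
the values that reflect true nutrient status: ferritin and sTfR rise with
inflammation while retinol, RBP and zinc fall, so unadjusted estimates under-
or over-state deficiency prevalence.  The regression-correction approach
models the ln biomarker as linear in ln AGP and ln CRP, and subtracts the
fitted inflammation contribution *above a reference level*:

    ln x~_i = ln x_i - b_agp * max(ln AGP_i - ref_agp, 0)
                     - b_crp * max(ln CRP_i - ref_crp, 0)

with slopes from an unweighted OLS fit of ln x on the available ln markers
over complete cases, and reference values defaulting to the lowest decile of
the dataset's own ln-marker distribution (external references may be
supplied).  Participants at or below both references are unchanged; the
correction never produces non-positive concentrations.

By default the adjustable set is {ferritin, sTfR, RBP, retinol, zinc}; sTfR
is regressed on ln AGP only.  Both choices are configurable.  Datasets whose
population group is not PSC or WRA, or that carry neither AGP nor CRP, are
bypassed in full: the pipeline proceeds with unadjusted values and records
the reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ingest import StandardizedDataset

__all__ = [
    "ReferenceValues",
    "InflammationModel",
    "AdjustmentConfig",
    "AdjustmentResult",
    "DEFAULT_ADJUSTABLE",
    "compute_reference_deciles",
    "fit_inflammation_regression",
    "apply_regression_correction",
    "adjust_dataset",
]

#: Biomarkers adjusted by default.
DEFAULT_ADJUSTABLE = ("ferritin", "stfr", "rbp", "retinol", "zinc")

_MARKERS = ("agp", "crp")


@dataclass(frozen=True)
class ReferenceValues:
    """Reference levels on the ln scale (AGP in g/L, CRP in mg/L)."""

    ln_agp_ref: Optional[float]
    ln_crp_ref: Optional[float]
    source: Literal["internal_decile", "user_supplied"]

    def available(self) -> tuple[str, ...]:
        out = []
        if self.ln_agp_ref is not None:
            out.append("agp")
        if self.ln_crp_ref is not None:
            out.append("crp")
        return tuple(out)

    def ref(self, marker: str) -> float:
        return {"agp": self.ln_agp_ref, "crp": self.ln_crp_ref}[marker]


@dataclass(frozen=True)
class InflammationModel:
    """Fitted ln-ln regression for one biomarker."""

    biomarker: str
    beta0: float
    beta_agp: Optional[float]
    beta_crp: Optional[float]
    refs: ReferenceValues
    n_fit: int

    def slope(self, marker: str) -> Optional[float]:
        return {"agp": self.beta_agp, "crp": self.beta_crp}[marker]

    def regressors(self) -> tuple[str, ...]:
        return tuple(m for m in _MARKERS if self.slope(m) is not None)


@dataclass
class AdjustmentConfig:
    """Tunable behavior of the adjustment step."""

    adjustable: tuple[str, ...] = DEFAULT_ADJUSTABLE
    #: per-biomarker regressor sets; anything absent uses both markers
    regressors: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"stfr": ("agp",)}
    )
    #: external references on the ln scale; None → internal lowest decile
    external_refs: Optional[ReferenceValues] = None
    min_n_fit: int = 10
    #: if True, slopes whose p-value exceeds 0.05 are set to zero
    significance_gate: bool = False

    def regressors_for(self, biomarker: str) -> tuple[str, ...]:
        return self.regressors.get(biomarker, _MARKERS)


@dataclass
class AdjustmentResult:
    """Outcome of Step-6 style adjustment for one dataset.

    ``adjusted`` has one column per adjusted biomarker (same index as the
    dataset); ``skipped`` flags rows whose inflammation markers were missing
    (their adjusted value equals the unadjusted one).
    """

    adjusted: pd.DataFrame
    models: dict[str, InflammationModel]
    skipped: pd.DataFrame
    bypassed: bool = False
    reason: Optional[str] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def adjusted_biomarkers(self) -> list[str]:
        return list(self.adjusted.columns)


class BypassSignal(Exception):
    """Internal: adjustment cannot run; carry the reason."""


def compute_reference_deciles(
    ds: StandardizedDataset, min_n: int = 10
) -> tuple[ReferenceValues, list[str]]:
    """Lowest decile of ln AGP / ln CRP over non-missing positive values.

    A marker with fewer than ``min_n`` usable values is dropped with a
    warning.  If neither marker is present the caller must bypass.
    """
    refs: dict[str, Optional[float]] = {"agp": None, "crp": None}
    warnings: list[str] = []
    for m in _MARKERS:
        if m not in ds.data.columns:
            continue
        v = ds.data[m].dropna()
        v = v[v > 0]
        if len(v) < min_n:
            warnings.append(
                f"{m}: only {len(v)} usable value(s) (< {min_n}); reference omitted"
            )
            continue
        refs[m] = float(np.quantile(np.log(v.to_numpy()), 0.10))
    return (
        ReferenceValues(refs["agp"], refs["crp"], "internal_decile"),
        warnings,
    )


def fit_inflammation_regression(
    ds: StandardizedDataset,
    biomarker: str,
    refs: Optional[ReferenceValues] = None,
    regressors: tuple[str, ...] = _MARKERS,
    min_n: int = 10,
    significance_gate: bool = False,
) -> InflammationModel:
    """OLS of ln(biomarker) on the available ln inflammation markers.

    Raises :class:`BypassSignal` when the fit is impossible (marker columns
    absent, too few complete cases, singular design).
    """
    if refs is None:
        refs, _ = compute_reference_deciles(ds, min_n)
    use = tuple(m for m in regressors if m in refs.available() and m in ds.data.columns)
    if not use:
        raise BypassSignal(f"{biomarker}: no usable inflammation marker among {regressors}")
    if biomarker not in ds.data.columns:
        raise BypassSignal(f"{biomarker}: column not present")

    cols = ds.data[[biomarker, *use]]
    cc = cols.dropna()
    cc = cc[(cc > 0).all(axis=1)]
    n = len(cc)
    if n < min_n:
        raise BypassSignal(f"{biomarker}: only {n} complete case(s) (< {min_n})")

    X = np.log(cc[list(use)].to_numpy())
    if np.any(np.ptp(X, axis=0) == 0.0):
        raise BypassSignal(f"{biomarker}: singular design (constant regressor)")
    y = np.log(cc[biomarker].to_numpy())
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    if int(np.linalg.matrix_rank(sm.add_constant(X))) < X.shape[1] + 1:
        raise BypassSignal(f"{biomarker}: singular design")

    betas = dict(zip(use, fit.params[1:]))
    if significance_gate:
        pvals = dict(zip(use, fit.pvalues[1:]))
        betas = {m: (b if pvals[m] <= 0.05 else 0.0) for m, b in betas.items()}
    return InflammationModel(
        biomarker=biomarker,
        beta0=float(fit.params[0]),
        beta_agp=float(betas["agp"]) if "agp" in betas else None,
        beta_crp=float(betas["crp"]) if "crp" in betas else None,
        refs=refs,
        n_fit=n,
    )


def apply_regression_correction(
    ds: StandardizedDataset, model: InflammationModel
) -> tuple[pd.Series, pd.Series]:
    """Adjusted concentrations for one biomarker.

    Returns ``(adjusted, skipped)``: rows with a missing biomarker stay
    missing; rows missing any regressor marker keep the unadjusted value and
    are flagged in ``skipped``.
    """
    x = ds.data[model.biomarker]
    ln_adj = pd.Series(np.log(x.where(x > 0)), index=x.index)
    needed = model.regressors()
    marker_ok = pd.Series(True, index=x.index)
    correction = pd.Series(0.0, index=x.index)
    for m in needed:
        mv = ds.data[m]
        ok = mv.notna() & (mv > 0)
        marker_ok &= ok
        excess = (np.log(mv.where(ok)) - model.refs.ref(m)).clip(lower=0.0)
        correction = correction + model.slope(m) * excess
    adjusted = np.exp(ln_adj - correction.where(marker_ok))
    skipped = x.notna() & ~marker_ok
    adjusted[skipped] = x[skipped]
    return adjusted, skipped


def adjust_dataset(
    ds: StandardizedDataset, config: AdjustmentConfig | None = None
) -> AdjustmentResult:
    """Run the full adjustment step on an SI-converted dataset.

    All failure modes degrade to flagged bypasses — the pipeline always
    proceeds, with unadjusted values, exactly as when no inflammation data
    are available.
    """
    config = config or AdjustmentConfig()
    empty = pd.DataFrame(index=ds.data.index)

    def bypass(reason: str) -> AdjustmentResult:
        return AdjustmentResult(
            adjusted=empty.copy(),
            models={},
            skipped=empty.copy(),
            bypassed=True,
            reason=reason,
        )

    if ds.population_group not in ("PSC", "WRA"):
        return bypass(f"population group {ds.population_group!r} is not PSC or WRA")
    present = [m for m in _MARKERS if m in ds.data.columns]
    if not present:
        return bypass("neither AGP nor CRP present")

    warnings: list[str] = []
    if config.external_refs is not None:
        refs = config.external_refs
    else:
        refs, ref_warnings = compute_reference_deciles(ds, config.min_n_fit)
        warnings.extend(ref_warnings)
    if not refs.available():
        return bypass("no inflammation marker has enough values for a reference")

    targets = [b for b in config.adjustable if b in ds.data.columns]
    adjusted = pd.DataFrame(index=ds.data.index)
    skipped = pd.DataFrame(index=ds.data.index)
    models: dict[str, InflammationModel] = {}
    for bm in targets:
        try:
            model = fit_inflammation_regression(
                ds,
                bm,
                refs=refs,
                regressors=config.regressors_for(bm),
                min_n=config.min_n_fit,
                significance_gate=config.significance_gate,
            )
        except BypassSignal as sig:
            warnings.append(str(sig))
            continue
        adj, skip = apply_regression_correction(ds, model)
        adjusted[bm] = adj
        skipped[bm] = skip
        models[bm] = model

    if not models:
        res = bypass("no biomarker could be adjusted")
        res.warnings = warnings
        return res
    return AdjustmentResult(
        adjusted=adjusted, models=models, skipped=skipped, warnings=warnings
    )
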