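"""Synthetic stratified-cluster survey fixtures with known truth.

Emulates the data structure the pipeline assumes: a stratified one-stage
cluster sample of PSC or WRA with lognormal biomarker concentrations whose
ln values are linearly associated with ln AGP and ln CRP,

    ln X_i = mu + b_agp * ln AGP_i + b_crp * ln CRP_i + u_c(i) + eps_i,

where ``u_c`` is a cluster-level Normal(0, cluster_sd^2) effect and
``eps_i`` is Normal(0, sigma^2).  Inflammation markers are lognormal,
weights depend on the stratum only (so design-based estimators stay
unbiased and hand-checkable), and the biomarker distribution does not vary
by stratum.

Every generated dataset comes with a truth sidecar holding, per row and
biomarker, the concentration with the inflammation terms removed
(``*_free``), the concentration standardized to the analytic population
10th percentile of the ln markers (``*_ref`` — the estimand of the
regression-correction adjustment), and the true deficiency status
(``*_deficient``, defined on ``*_ref``).  The analytic deficiency
probability is available in closed form from the lognormal CDF.

All randomness flows from one ``numpy.random.default_rng(seed)`` (PCG64),
so identical specs and seeds give identical files on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiomarkerSim",
    "SimulationSpec",
    "generate_survey_frame",
    "generate_survey_dataset",
    "generate_templates",
    "analytic_deficiency_probability",
    "DATASET_FORMATS",
]

DATASET_FORMATS = ("csv", "excel", "sas", "spss", "stata")

_EXT = {"csv": ".csv", "excel": ".xlsx", "sas": ".xpt", "spss": ".sav", "stata": ".dta"}

#: Quantile of the standard normal at p = 0.10 (reference-level definition).
_Z10 = float(stats.norm.ppf(0.10))


@dataclass(frozen=True)
class BiomarkerSim:
    """ln-scale generating parameters for one biomarker."""

    name: str  # canonical name
    source_column: str  # short upper-case name used in the files
    unit: str  # unit the files are written in
    si_factor: float  # value_si = value_written * si_factor
    mu: float  # ln-scale mean of the inflammation-free concentration (SI)
    sigma: float  # ln-scale residual SD
    b_agp: float = 0.0
    b_crp: float = 0.0
    cutoff: float | None = None  # deficiency threshold, SI unit, direction below


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic survey."""

    n_strata: int = 4
    psus_per_stratum: int = 8
    rows_per_psu: int = 15
    group: str = "PSC"  # "PSC" or "WRA"
    biomarkers: tuple[BiomarkerSim, ...] = (
        BiomarkerSim(
            "ferritin", "FER", "ug/L", 1.0,
            mu=math.log(30.0), sigma=0.7, b_agp=0.8, b_crp=0.2, cutoff=12.0,
        ),
        BiomarkerSim(
            "retinol", "RET", "ug/dL", 10.0 / 286.45,
            mu=math.log(1.0), sigma=0.35,
            b_agp=-0.25, b_crp=-0.10, cutoff=0.7,
        ),
    )
    ln_agp: tuple[float, float] = (-0.1, 0.35)  # AGP in g/L: geomean ~0.9
    ln_crp: tuple[float, float] = (0.0, 1.2)  # CRP in mg/L: geomean 1
    cluster_sd: float = 0.15
    weight_range: tuple[float, float] = (0.8, 1.8)  # per-stratum multipliers
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_strata, self.psus_per_stratum, self.rows_per_psu) < 1:
            raise ValueError("all design counts must be >= 1")
        for bm in self.biomarkers:
            if bm.sigma <= 0:
                raise ValueError(f"{bm.name}: sigma must be > 0")
        if self.ln_agp[1] <= 0 or self.ln_crp[1] <= 0:
            raise ValueError("inflammation ln-scale SDs must be > 0")

    @property
    def n_rows(self) -> int:
        return self.n_strata * self.psus_per_stratum * self.rows_per_psu

    def ln_ref(self, marker: str) -> float:
        """Analytic population 10th percentile of the ln marker."""
        m, s = self.ln_agp if marker == "agp" else self.ln_crp
        return m + _Z10 * s


def analytic_deficiency_probability(spec: SimulationSpec, biomarker: str) -> float:
    """P(X_ref < cutoff) under the generating model (lognormal CDF)."""
    bm = next(b for b in spec.biomarkers if b.name == biomarker)
    if bm.cutoff is None:
        raise ValueError(f"{biomarker}: no cutoff in the simulation spec")
    mu_ref = bm.mu + bm.b_agp * spec.ln_ref("agp") + bm.b_crp * spec.ln_ref("crp")
    sd = math.sqrt(bm.sigma**2 + spec.cluster_sd**2)
    return float(stats.norm.cdf((math.log(bm.cutoff) - mu_ref) / sd))


def generate_survey_frame(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(data, truth)`` in memory.

    ``data`` uses the short source column names and source units the files
    are written with; ``truth`` is row-aligned with the sidecar columns.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    stratum = np.repeat(np.arange(1, spec.n_strata + 1), spec.psus_per_stratum * spec.rows_per_psu)
    psu_within = np.repeat(
        np.arange(1, spec.psus_per_stratum + 1), spec.rows_per_psu
    )
    cluster = np.tile(psu_within, spec.n_strata) + 100 * stratum

    w_lo, w_hi = spec.weight_range
    stratum_w = np.linspace(w_lo, w_hi, spec.n_strata)
    weight = stratum_w[stratum - 1]

    if spec.group == "PSC":
        age = rng.uniform(6.0, 59.0, n)  # months
        sex = rng.integers(1, 3, n)  # 1 male, 2 female
    else:
        age = rng.uniform(15.0, 49.0, n)  # years
        sex = np.full(n, 2)

    ln_agp = rng.normal(*spec.ln_agp, n)
    ln_crp = rng.normal(*spec.ln_crp, n)

    n_psu_total = spec.n_strata * spec.psus_per_stratum
    u = rng.normal(0.0, spec.cluster_sd, n_psu_total)
    psu_index = np.repeat(np.arange(n_psu_total), spec.rows_per_psu)

    data = {
        "STRAT": stratum.astype(float),
        "CLUST": cluster.astype(float),
        "WT": weight,
        "AGEM" if spec.group == "PSC" else "AGEY": age,
        "SEX": sex.astype(float),
        "AGP": np.exp(ln_agp),
        "CRP": np.exp(ln_crp),
    }
    truth = {}
    for bm in spec.biomarkers:
        eps = rng.normal(0.0, bm.sigma, n)
        ln_base = bm.mu + u[psu_index] + eps  # SI scale, b-terms removed
        ln_obs = ln_base + bm.b_agp * ln_agp + bm.b_crp * ln_crp
        ln_ref = (
            ln_base
            + bm.b_agp * spec.ln_ref("agp")
            + bm.b_crp * spec.ln_ref("crp")
        )
        data[bm.source_column] = np.exp(ln_obs) / bm.si_factor  # to source units
        truth[f"{bm.name}_free"] = np.exp(ln_base)
        # (observed columns are quantized below; truth keeps full precision)
        truth[f"{bm.name}_ref"] = np.exp(ln_ref)
        if bm.cutoff is not None:
            truth[f"{bm.name}_deficient"] = (np.exp(ln_ref) < bm.cutoff).astype(int)

    # Quantize observed values to 15 significant decimal digits: every
    # supported file format (xlsx included, which stores at most 15 digits)
    # then represents the fixture bit-exactly, so one dataset serialized to
    # all five formats loads back identical to the last bit.
    frame = pd.DataFrame(data)
    for c in frame.columns:
        frame[c] = np.array([float(f"{v:.15g}") for v in frame[c]])
    return frame, pd.DataFrame(truth)


def _write(df: pd.DataFrame, path: Path, fmt: str) -> None:
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "excel":
        df.to_excel(path, index=False)
    elif fmt == "sas":
        from ._xportio import write_xport

        write_xport(df, path)
    elif fmt == "spss":
        from ._savio import write_sav

        write_sav(df, path)
    elif fmt == "stata":
        df.to_stata(path, write_index=False)
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")


def generate_survey_dataset(
    spec: SimulationSpec, out_dir, fmt: str = "csv", stem: str = "survey"
) -> tuple[Path, Path]:
    """Write the dataset file (in ``fmt``) and its truth sidecar CSV.

    Returns ``(data_path, truth_path)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data, truth = generate_survey_frame(spec)
    data_path = out_dir / f"{stem}{_EXT[fmt]}"
    truth_path = out_dir / f"{stem}_truth.csv"
    _write(data, data_path, fmt)
    truth.to_csv(truth_path, index=False)
    return data_path, truth_path


def generate_templates(
    spec: SimulationSpec,
    data_path,
    out_dir,
    dataset_id: str = "sim1",
    stem: str = "survey",
) -> tuple[Path, Path]:
    """Write a dataset template column and a cutoff table matching the fixture.

    Both load unchanged through the templates module.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    age_row = "AGEM" if spec.group == "PSC" else "AGEY"
    age_unit = "months" if spec.group == "PSC" else "years"
    rows = [
        ("file", str(data_path)),
        ("format", ""),
        ("strata", "STRAT"),
        ("cluster", "CLUST"),
        ("weight", "WT"),
        ("age", age_row),
        ("age_unit", age_unit),
        ("sex", "SEX"),
        ("sex_coding", "male=1,female=2"),
        ("population_group", spec.group),
        ("agp_var", "AGP"),
        ("agp_unit", "g/L"),
        ("crp_var", "CRP"),
        ("crp_unit", "mg/L"),
    ]
    from .units import CANONICAL_UNITS

    for bm in spec.biomarkers:
        rows.append((f"{bm.name}_var", bm.source_column))
        rows.append((f"{bm.name}_unit", bm.unit))
    template_path = out_dir / f"{stem}_dataset_template.csv"
    pd.DataFrame(rows, columns=["field", dataset_id]).to_csv(template_path, index=False)

    age_lo, age_hi = (6, 59) if spec.group == "PSC" else (15, 49)
    cut_rows = []
    for bm in spec.biomarkers:
        if bm.cutoff is None:
            continue
        cut_rows.append(
            {
                "biomarker": bm.name,
                "condition_label": f"{bm.name}_deficiency",
                "group": spec.group,
                "sex": "any",
                "age_min": age_lo,
                "age_max": age_hi,
                "age_unit": age_unit,
                "direction": "below",
                "threshold": bm.cutoff,
                "threshold_unit": CANONICAL_UNITS.get(bm.name, bm.unit),
                "use_adjusted": "true",
                "source": "synthetic fixture",
            }
        )
    cutoff_path = out_dir / f"{stem}_cutoff_template.csv"
    pd.DataFrame(cut_rows).to_csv(cutoff_path, index=False)
    return template_path, cutoff_path
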