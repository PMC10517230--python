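"""Design-based summary statistics under stratified one-stage cluster sampling.

Point estimators are Hájek (ratio) means of survey-weighted totals; variances
come from first-order Taylor linearization with the with-replacement
approximation, taking variance between primary-sampling-unit (PSU) totals of
the linearized residuals within strata:

    ybar   = sum(w_i y_i) / sum(w_i)
    z_i    = w_i (y_i - ybar)
    z_ha   = sum of z_i over rows of PSU a in stratum h
    v      = sum_h  n_h/(n_h - 1) * sum_a (z_ha - zbar_h)^2
    SE     = sqrt(v) / sum(w_i)

Confidence intervals use Student's t with the design degrees of freedom
(#PSUs − #strata).  With the default design — every row its own PSU, one
stratum, unit weights — all estimators collapse to their textbook SRS
counterparts (mean with SE = sd/√n, df = n − 1).

The weighted quantile is the inverse of the weighted empirical CDF: the value
whose cumulative weight share strictly brackets p; when p falls exactly on a
CDF step boundary, the midpoint of the two adjacent distinct values is
returned (the average of the left- and right-continuous inverses).  Under
equal weights this is the Hyndman–Fan type 2 sample quantile.  Quantile SEs
are not reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "SummaryEstimate",
    "weighted_mean",
    "geometric_mean",
    "weighted_quantile",
    "prevalence",
]

Statistic = Literal["mean", "geometric_mean", "median", "q25", "q75", "prevalence"]


class LonelyPSUError(ValueError):
    """A stratum contains a single PSU, so its variance contribution is undefined.

    Either merge strata upstream, or construct the design with
    ``lonely_psu="center"`` to score lonely strata against the grand mean of
    PSU totals.
    """


@dataclass
class SurveyDesign:
    """Per-row survey design: stratum labels, PSU labels, sampling weights.

    All three default to the self-representing SRS design (one stratum, each
    row its own PSU, unit weights).  ``lonely_psu`` controls strata with a
    single PSU: ``"error"`` (default) raises, ``"center"`` scores the lonely
    PSU total against the grand mean.
    """

    stratum: np.ndarray | None = None
    cluster: np.ndarray | None = None
    weight: np.ndarray | None = None
    lonely_psu: Literal["error", "center"] = "error"

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        stratum: str | None = None,
        cluster: str | None = None,
        weight: str | None = None,
        lonely_psu: Literal["error", "center"] = "error",
    ) -> "SurveyDesign":
        return cls(
            stratum=None if stratum is None else np.asarray(df[stratum]),
            cluster=None if cluster is None else np.asarray(df[cluster]),
            weight=None if weight is None else np.asarray(df[weight], dtype=float),
            lonely_psu=lonely_psu,
        )

    def resolve(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Materialize (stratum codes, psu codes, weights) for n rows."""
        w = np.ones(n) if self.weight is None else np.asarray(self.weight, float)
        if w.shape != (n,):
            raise ValueError(f"weight length {w.shape} != data length {n}")
        if not np.all(w[~np.isnan(w)] > 0):
            raise ValueError("sampling weights must be strictly positive")
        strat = (
            np.zeros(n, dtype=np.int64)
            if self.stratum is None
            else pd.factorize(np.asarray(self.stratum))[0]
        )
        psu = (
            np.arange(n, dtype=np.int64)
            if self.cluster is None
            else pd.factorize(np.asarray(self.cluster))[0]
        )
        if strat.shape != (n,) or psu.shape != (n,):
            raise ValueError("design variable length does not match data length")
        # a PSU label reused across strata denotes distinct PSUs
        psu = pd.factorize(strat.astype(np.int64) * (psu.max() + 1) + psu)[0]
        return strat, psu, w

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        def take(a):
            return None if a is None else np.asarray(a)[mask]

        return SurveyDesign(
            take(self.stratum), take(self.cluster), take(self.weight), self.lonely_psu
        )


@dataclass
class SummaryEstimate:
    """A point estimate with its design-based uncertainty."""

    statistic: Statistic
    estimate: float
    se: float | None
    ci_low: float | None
    ci_high: float | None
    n: int
    n_weighted: float

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.estimate <= self.ci_high):
                # permissible only through float round-off at zero-variance
                if not np.allclose(
                    [self.ci_low, self.ci_high], self.estimate, atol=1e-10
                ):
                    raise ValueError("CI does not bracket the estimate")


def _complete_cases(values, design: SurveyDesign):
    y = np.asarray(values, dtype=float)
    keep = ~np.isnan(y)
    if design.weight is not None:
        keep &= ~np.isnan(np.asarray(design.weight, dtype=float))
    if not keep.any():
        raise ValueError("no non-missing values to estimate from")
    return y[keep], design.subset(keep)


def _linearized_variance(
    y: np.ndarray, strat: np.ndarray, psu: np.ndarray, w: np.ndarray, ybar: float
) -> tuple[float | None, int, str | None]:
    """Between-PSU within-stratum variance of the Hájek mean.

    Returns (variance or None, design df, warning or None).
    """
    z = w * (y - ybar)
    tot = pd.DataFrame({"s": strat, "p": psu, "z": z}).groupby(["s", "p"])["z"].sum()
    n_psu = len(tot)
    n_strata = tot.index.get_level_values("s").nunique()
    df = n_psu - n_strata
    if df <= 0:
        # only possible when every stratum holds a single PSU
        return None, df, "non-positive design degrees of freedom; SE omitted"
    grand = float(tot.mean())
    v = 0.0
    lonely = False
    for _, zh in tot.groupby(level="s"):
        nh = len(zh)
        if nh == 1:
            lonely = True
            v += float((zh.iloc[0] - grand) ** 2)
        else:
            v += nh / (nh - 1) * float(((zh - zh.mean()) ** 2).sum())
    var = v / float(w.sum()) ** 2
    return var, df, ("lonely PSU centered at grand mean" if lonely else None)


def _has_lonely(strat: np.ndarray, psu: np.ndarray) -> tuple[int, int]:
    """(number of lonely strata, number of strata)."""
    tab = pd.DataFrame({"s": strat, "p": psu}).drop_duplicates()
    per = tab.groupby("s")["p"].nunique()
    return int((per == 1).sum()), len(per)


def weighted_mean(values, design: SurveyDesign | None = None) -> SummaryEstimate:
    """Survey-weighted arithmetic mean with Taylor-linearized SE and t CI."""
    design = design or SurveyDesign()
    y, d = _complete_cases(values, design)
    strat, psu, w = d.resolve(len(y))
    ybar = float(np.sum(w * y) / np.sum(w))
    n_lonely, n_strata = _has_lonely(strat, psu)
    if 0 < n_lonely < n_strata and d.lonely_psu == "error":
        # all-lonely designs fall through to the df <= 0 path (SE omitted)
        raise LonelyPSUError(
            "a stratum contains a single PSU; merge strata or use lonely_psu='center'"
        )
    var, df, _warn = _linearized_variance(y, strat, psu, w, ybar)
    se = None if var is None else float(np.sqrt(var))
    lo = hi = None
    if se is not None:
        t = float(stats.t.ppf(0.975, df))
        lo, hi = ybar - t * se, ybar + t * se
    return SummaryEstimate("mean", ybar, se, lo, hi, len(y), float(np.sum(w)))


def geometric_mean(values, design: SurveyDesign | None = None) -> SummaryEstimate:
    """exp of the weighted mean of ln values; CI transformed from the ln scale.

    The natural-scale SE is the delta-method transform ``estimate * se_ln``.
    """
    design = design or SurveyDesign()
    y, d = _complete_cases(values, design)
    if np.any(y <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    ln = weighted_mean(np.log(y), d)
    est = float(np.exp(ln.estimate))
    se = None if ln.se is None else est * ln.se
    lo = None if ln.ci_low is None else float(np.exp(ln.ci_low))
    hi = None if ln.ci_high is None else float(np.exp(ln.ci_high))
    return SummaryEstimate("geometric_mean", est, se, lo, hi, ln.n, ln.n_weighted)


def _quantile_from_cdf(y: np.ndarray, w: np.ndarray, p: float) -> float:
    order = np.argsort(y, kind="stable")
    ys, ws = y[order], w[order]
    # collapse ties to distinct values
    uniq, idx = np.unique(ys, return_index=True)
    wsum = np.add.reduceat(ws, idx)
    cdf = np.cumsum(wsum) / wsum.sum()
    j = int(np.searchsorted(cdf, p, side="left"))
    if j >= len(uniq):
        return float(uniq[-1])
    # exact hit on a step boundary → midpoint of adjacent distinct values
    if np.isclose(cdf[j], p, rtol=0.0, atol=1e-12) and j + 1 < len(uniq):
        return float(0.5 * (uniq[j] + uniq[j + 1]))
    return float(uniq[j])


def weighted_quantile(
    values, design: SurveyDesign | None = None, p: float = 0.5
) -> SummaryEstimate:
    """Weighted quantile (inverse weighted ECDF, boundary-midpoint rule)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    design = design or SurveyDesign()
    y, d = _complete_cases(values, design)
    _, _, w = d.resolve(len(y))
    est = _quantile_from_cdf(y, w, p)
    name = {0.25: "q25", 0.5: "median", 0.75: "q75"}.get(p, f"q{round(100 * p)}")
    return SummaryEstimate(name, est, None, None, None, len(y), float(np.sum(w)))


def prevalence(indicator, design: SurveyDesign | None = None) -> SummaryEstimate:
    """Survey-weighted prevalence in percent, Wald CI truncated to [0, 100]."""
    design = design or SurveyDesign()
    y, d = _complete_cases(indicator, design)
    bad = ~np.isin(y, (0.0, 1.0))
    if bad.any():
        raise ValueError("prevalence indicator must be 0, 1 or missing")
    m = weighted_mean(y, d)
    est = 100.0 * m.estimate
    se = None if m.se is None else 100.0 * m.se
    lo = None if m.ci_low is None else max(0.0, 100.0 * m.ci_low)
    hi = None if m.ci_high is None else min(100.0, 100.0 * m.ci_high)
    return SummaryEstimate("prevalence", est, se, lo, hi, m.n, m.n_weighted)
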