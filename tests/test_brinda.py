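"""Regression-correction inflammation adjustment: references, fits, correction."""

import numpy as np
import pandas as pd
import pytest

from mnsurvey.brinda import (
    AdjustmentConfig,
    BypassSignal,
    InflammationModel,
    ReferenceValues,
    adjust_dataset,
    apply_regression_correction,
    compute_reference_deciles,
    fit_inflammation_regression,
)

from conftest import make_standardized


def synthetic_ds(
    n=1000,
    seed=0,
    beta_agp=0.8,
    beta_crp=0.0,
    mu=3.0,
    resid_sd=0.1,
    include_crp=True,
    group="PSC",
):
    rng = np.random.default_rng(seed)
    ln_agp = rng.normal(-0.1, 0.35, n)
    ln_crp = rng.normal(0.0, 1.2, n)
    ln_fer = mu + beta_agp * ln_agp + beta_crp * ln_crp + rng.normal(0, resid_sd, n)
    cols = {"ferritin": np.exp(ln_fer), "agp": np.exp(ln_agp)}
    units = {"ferritin": "ug/L", "agp": "g/L"}
    if include_crp:
        cols["crp"] = np.exp(ln_crp)
        units["crp"] = "mg/L"
    return make_standardized(cols, units, group=group)


class TestReferenceDeciles:
    def test_grid_oracle(self):
        # ln CRP on an equally spaced grid over [-4, 1]
        ln_grid = np.linspace(-4.0, 1.0, 100)
        ds = make_standardized(
            {"crp": np.exp(ln_grid)}, {"crp": "mg/L"}, group="PSC"
        )
        refs, _ = compute_reference_deciles(ds)
        assert refs.ln_crp_ref == pytest.approx(np.quantile(ln_grid, 0.10), rel=1e-12)
        assert refs.ln_agp_ref is None

    def test_constant_marker(self):
        ds = make_standardized({"agp": [0.8] * 20}, {"agp": "g/L"})
        refs, _ = compute_reference_deciles(ds)
        assert refs.ln_agp_ref == pytest.approx(np.log(0.8), rel=1e-12)

    def test_too_few_values_omitted_with_warning(self):
        ds = make_standardized(
            {"agp": [0.8] * 20, "crp": [1.0] * 5 + [np.nan] * 15},
            {"agp": "g/L", "crp": "mg/L"},
        )
        refs, warnings = compute_reference_deciles(ds)
        assert refs.ln_crp_ref is None and refs.ln_agp_ref is not None
        assert any("crp" in w for w in warnings)

    def test_source_flag(self):
        ds = synthetic_ds(50)
        refs, _ = compute_reference_deciles(ds)
        assert refs.source == "internal_decile"


class TestFit:
    def test_recovers_known_slope(self):
        # analytic SE of the slope ≈ resid_sd / (sd(lnAGP)·sqrt(n)) ≈ 0.009
        ds = synthetic_ds(n=1000, seed=1, beta_agp=0.8, include_crp=False)
        model = fit_inflammation_regression(ds, "ferritin", regressors=("agp",))
        assert model.beta_agp == pytest.approx(0.8, abs=0.03)
        assert model.beta_crp is None
        assert model.n_fit == 1000

    def test_null_slope_near_zero(self):
        ds = synthetic_ds(n=5000, seed=2, beta_agp=0.0, include_crp=False)
        model = fit_inflammation_regression(ds, "ferritin", regressors=("agp",))
        assert abs(model.beta_agp) < 0.05

    def test_both_regressors(self):
        ds = synthetic_ds(n=4000, seed=3, beta_agp=0.6, beta_crp=0.2)
        model = fit_inflammation_regression(ds, "ferritin")
        assert model.beta_agp == pytest.approx(0.6, abs=0.03)
        assert model.beta_crp == pytest.approx(0.2, abs=0.01)

    def test_constant_regressor_bypasses(self):
        ds = make_standardized(
            {"ferritin": np.linspace(10, 40, 20), "agp": [0.9] * 20},
            {"ferritin": "ug/L", "agp": "g/L"},
        )
        with pytest.raises(BypassSignal, match="singular"):
            fit_inflammation_regression(ds, "ferritin", regressors=("agp",))

    def test_too_few_cases_bypasses(self):
        ds = synthetic_ds(n=8)
        refs = ReferenceValues(-0.5, -1.5, "user_supplied")
        with pytest.raises(BypassSignal, match="complete case"):
            fit_inflammation_regression(ds, "ferritin", refs=refs)


class TestApplyCorrection:
    def _model(self, beta_agp=None, beta_crp=None, ref_agp=None, ref_crp=None):
        return InflammationModel(
            biomarker="ferritin",
            beta0=3.0,
            beta_agp=beta_agp,
            beta_crp=beta_crp,
            refs=ReferenceValues(ref_agp, ref_crp, "user_supplied"),
            n_fit=100,
        )

    def test_zero_slopes_identity(self):
        ds = synthetic_ds(50, seed=4)
        model = self._model(beta_agp=0.0, beta_crp=0.0, ref_agp=-0.5, ref_crp=-1.5)
        adjusted, _ = apply_regression_correction(ds, model)
        assert np.allclose(adjusted, ds.data["ferritin"], rtol=1e-12)

    def test_row_at_reference_unchanged(self):
        ds = make_standardized(
            {"ferritin": [30.0], "agp": [np.exp(-0.5)]},
            {"ferritin": "ug/L", "agp": "g/L"},
        )
        model = self._model(beta_agp=0.9, ref_agp=-0.5)
        adjusted, _ = apply_regression_correction(ds, model)
        assert adjusted.iloc[0] == pytest.approx(30.0, rel=1e-12)

    def test_hand_computed_case(self):
        # x=30, beta=0.9, ln AGP − ref = 0.5 → 30·exp(−0.45) = 19.1288…
        ds = make_standardized(
            {"ferritin": [30.0], "agp": [np.exp(-0.5 + 0.5)]},
            {"ferritin": "ug/L", "agp": "g/L"},
        )
        model = self._model(beta_agp=0.9, ref_agp=-0.5)
        adjusted, _ = apply_regression_correction(ds, model)
        assert adjusted.iloc[0] == pytest.approx(30.0 * np.exp(-0.45), rel=1e-12)

    def test_below_reference_truncated(self):
        ds = make_standardized(
            {"ferritin": [30.0], "agp": [np.exp(-1.0)]},  # below ref −0.5
            {"ferritin": "ug/L", "agp": "g/L"},
        )
        model = self._model(beta_agp=0.9, ref_agp=-0.5)
        adjusted, _ = apply_regression_correction(ds, model)
        assert adjusted.iloc[0] == pytest.approx(30.0, rel=1e-12)

    def test_missing_marker_row_flagged_not_adjusted(self):
        ds = make_standardized(
            {"ferritin": [30.0, 20.0], "agp": [np.exp(0.5), np.nan]},
            {"ferritin": "ug/L", "agp": "g/L"},
        )
        model = self._model(beta_agp=0.9, ref_agp=-0.5)
        adjusted, skipped = apply_regression_correction(ds, model)
        assert adjusted.iloc[1] == 20.0 and skipped.tolist() == [False, True]

    def test_missing_biomarker_stays_missing(self):
        ds = make_standardized(
            {"ferritin": [np.nan], "agp": [1.0]}, {"ferritin": "ug/L", "agp": "g/L"}
        )
        model = self._model(beta_agp=0.9, ref_agp=-0.5)
        adjusted, _ = apply_regression_correction(ds, model)
        assert np.isnan(adjusted.iloc[0])


class TestAdjustDataset:
    def test_agp_only_dataset(self):
        ds = synthetic_ds(500, seed=5, include_crp=False)
        res = adjust_dataset(ds)
        assert not res.bypassed
        assert res.models["ferritin"].beta_crp is None

    def test_no_markers_bypass(self):
        ds = make_standardized(
            {"ferritin": np.linspace(5, 50, 30)}, {"ferritin": "ug/L"}, group="PSC"
        )
        res = adjust_dataset(ds)
        assert res.bypassed and "neither AGP nor CRP" in res.reason

    def test_group_other_bypass(self):
        ds = synthetic_ds(100, group="other")
        res = adjust_dataset(ds)
        assert res.bypassed and "not PSC or WRA" in res.reason

    def test_stfr_uses_agp_only_by_default(self):
        rng = np.random.default_rng(6)
        n = 500
        ln_agp = rng.normal(-0.1, 0.35, n)
        ln_crp = rng.normal(0.0, 1.2, n)
        ds = make_standardized(
            {
                "stfr": np.exp(1.5 + 0.3 * ln_agp + 0.2 * ln_crp + rng.normal(0, 0.1, n)),
                "agp": np.exp(ln_agp),
                "crp": np.exp(ln_crp),
            },
            {"stfr": "mg/L", "agp": "g/L", "crp": "mg/L"},
        )
        res = adjust_dataset(ds)
        assert res.models["stfr"].beta_crp is None
        assert res.models["stfr"].beta_agp is not None

    def test_folate_not_adjusted_by_default_but_configurable(self):
        rng = np.random.default_rng(7)
        n = 300
        ln_agp = rng.normal(-0.1, 0.35, n)
        cols = {
            "serum_folate": np.exp(2.5 + rng.normal(0, 0.2, n)),
            "ferritin": np.exp(3.4 + 0.8 * ln_agp + rng.normal(0, 0.2, n)),
            "agp": np.exp(ln_agp),
        }
        units = {"serum_folate": "nmol/L", "ferritin": "ug/L", "agp": "g/L"}
        ds = make_standardized(cols, units)
        res = adjust_dataset(ds)
        assert "serum_folate" not in res.adjusted.columns
        cfg = AdjustmentConfig(adjustable=("ferritin", "serum_folate"))
        res2 = adjust_dataset(ds, cfg)
        assert "serum_folate" in res2.adjusted.columns

    def test_external_references_used(self):
        ds = synthetic_ds(500, seed=8, include_crp=False)
        refs = ReferenceValues(-0.5, None, "user_supplied")
        res = adjust_dataset(ds, AdjustmentConfig(external_refs=refs))
        assert res.models["ferritin"].refs.ln_agp_ref == -0.5


class TestAdjustmentProperties:
    def test_slope_removed_after_adjustment(self):
        """Refitting adjusted values on ln AGP above reference gives ~0 slope."""
        import statsmodels.api as sm

        ds = synthetic_ds(n=5000, seed=9, beta_agp=0.8, include_crp=False)
        res = adjust_dataset(ds)
        ref = res.models["ferritin"].refs.ln_agp_ref
        ln_agp = np.log(ds.data["agp"].to_numpy())
        above = ln_agp > ref
        y = np.log(res.adjusted["ferritin"].to_numpy()[above])
        X = sm.add_constant(ln_agp[above])
        fit = sm.OLS(y, X).fit()
        assert abs(fit.params[1]) < 3 * fit.bse[1]

    def test_direction_sanity(self):
        """Positive slope → adjusted ≤ unadjusted row-wise; negative → ≥."""
        for beta, cmp in ((0.8, np.less_equal), (-0.4, np.greater_equal)):
            ds = synthetic_ds(n=2000, seed=10, beta_agp=beta, include_crp=False)
            res = adjust_dataset(ds)
            adj = res.adjusted["ferritin"].to_numpy()
            raw = ds.data["ferritin"].to_numpy()
            assert cmp(adj, raw * (1 + 1e-12)).all() or cmp(adj, raw).all()
            ref = res.models["ferritin"].refs.ln_agp_ref
            at_or_below = np.log(ds.data["agp"].to_numpy()) <= ref
            assert np.allclose(adj[at_or_below], raw[at_or_below], rtol=1e-12)

    def test_order_invariance(self):
        ds = synthetic_ds(n=800, seed=11)
        ds.data["retinol"] = np.exp(
            0.0 - 0.25 * np.log(ds.data["agp"]) + np.random.default_rng(12).normal(0, 0.2, 800)
        )
        ds.units["retinol"] = "umol/L"
        a = adjust_dataset(ds, AdjustmentConfig(adjustable=("ferritin", "retinol")))
        b = adjust_dataset(ds, AdjustmentConfig(adjustable=("retinol", "ferritin")))
        pd.testing.assert_frame_equal(
            a.adjusted.sort_index(axis=1), b.adjusted.sort_index(axis=1)
        )
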