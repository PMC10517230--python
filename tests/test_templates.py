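"""Template parsing, validation, cutoff lookup semantics."""

import numpy as np
import pandas as pd
import pytest

import mnsurvey as m
from mnsurvey.templates import (
    CutoffRule,
    CutoffTable,
    TemplateError,
    default_cutoffs,
    load_cutoff_template,
    load_dataset_template,
    validate_templates,
    write_dataset_template,
)


def template_frame(columns: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Build a rows=fields template table from {dataset_id: {field: value}}."""
    fields = []
    for spec in columns.values():
        for f in spec:
            if f not in fields:
                fields.append(f)
    data = {"field": fields}
    for ds_id, spec in columns.items():
        data[ds_id] = [spec.get(f, "") for f in fields]
    return pd.DataFrame(data)


BASE = {
    "file": "a.csv",
    "strata": "STRAT",
    "cluster": "CLUST",
    "weight": "WT",
    "age": "AGEM",
    "age_unit": "months",
    "sex": "SEX",
    "sex_coding": "male=1,female=2",
    "population_group": "PSC",
    "ferritin_var": "FER",
    "ferritin_unit": "ug/L",
}


class TestDatasetTemplate:
    def test_two_columns_two_descriptors_in_order(self, tmp_path):
        second = dict(BASE, file="b.csv")
        p = tmp_path / "t.csv"
        template_frame({"kenya": BASE, "malawi": second}).to_csv(p, index=False)
        descs = load_dataset_template(p)
        assert [d.dataset_id for d in descs] == ["kenya", "malawi"]
        assert descs[1].file_path == "b.csv"

    def test_optional_fields_absent_not_defaulted(self, tmp_path):
        minimal = {
            "file": "a.csv",
            "population_group": "WRA",
            "ferritin_var": "FER",
            "ferritin_unit": "ug/L",
        }
        p = tmp_path / "t.csv"
        template_frame({"d1": minimal}).to_csv(p, index=False)
        (d,) = load_dataset_template(p)
        assert d.stratum is None and d.cluster is None and d.weight is None
        assert not d.has_design

    def test_unknown_unit_names_biomarker_and_unit(self, tmp_path):
        bad = dict(BASE, ferritin_unit="mg/dL")
        p = tmp_path / "t.csv"
        template_frame({"d1": bad}).to_csv(p, index=False)
        with pytest.raises(TemplateError, match="mg/dL.*ferritin|ferritin.*mg/dL"):
            load_dataset_template(p)

    def test_duplicate_dataset_id_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        df = template_frame({"d1": BASE})
        df["d1.dup"] = df["d1"]
        df.columns = ["field", "d1", "d1"]
        df.to_csv(p, index=False)
        with pytest.raises(TemplateError, match="duplicated dataset_id"):
            load_dataset_template(p)

    def test_design_without_weight_rejected(self, tmp_path):
        bad = dict(BASE)
        bad.pop("weight")
        p = tmp_path / "t.csv"
        template_frame({"d1": bad}).to_csv(p, index=False)
        with pytest.raises(TemplateError, match="weight"):
            load_dataset_template(p)

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset_template(tmp_path / "nope.csv")

    def test_round_trip(self, tmp_path):
        p = tmp_path / "t.csv"
        template_frame({"kenya": BASE, "malawi": dict(BASE, file="b.csv")}).to_csv(
            p, index=False
        )
        descs = load_dataset_template(p)
        p2 = tmp_path / "t2.csv"
        write_dataset_template(descs, p2)
        assert load_dataset_template(p2) == descs

    def test_excel_equivalent_to_csv(self, tmp_path):
        frame = template_frame({"d1": BASE})
        frame.to_csv(tmp_path / "t.csv", index=False)
        frame.to_excel(tmp_path / "t.xlsx", index=False)
        assert load_dataset_template(tmp_path / "t.csv") == load_dataset_template(
            tmp_path / "t.xlsx"
        )

    def test_row_labels_case_insensitive(self, tmp_path):
        shouty = {k.upper(): v for k, v in BASE.items()}
        p = tmp_path / "t.csv"
        template_frame({"d1": shouty}).to_csv(p, index=False)
        (d,) = load_dataset_template(p)
        assert d.biomarkers[0].biomarker == "ferritin"


class TestCutoffTable:
    def test_default_ferritin_psc(self):
        table = default_cutoffs()
        (rule,) = table.lookup("ferritin", "PSC", 24, condition_label="iron_deficiency")
        assert rule.direction == "below" and rule.threshold == 12.0

    def test_default_ferritin_wra_and_retinol(self):
        table = default_cutoffs()
        (wra,) = table.lookup(
            "ferritin", "WRA", 30 * 12, sex="female", condition_label="iron_deficiency"
        )
        assert wra.threshold == 15.0
        (ret,) = table.lookup("retinol", "PSC", 24, condition_label="vitamin_a_deficiency")
        assert ret.threshold == 0.7 and ret.use_adjusted

    def test_wra_retinol_rule_is_unadjusted(self):
        table = default_cutoffs()
        (ret,) = table.lookup(
            "retinol", "WRA", 25 * 12, sex="female", condition_label="vitamin_a_deficiency"
        )
        assert not ret.use_adjusted

    def test_empty_rules_file(self, tmp_path):
        p = tmp_path / "c.csv"
        pd.DataFrame(
            columns=[
                "biomarker", "condition_label", "group", "age_min", "age_max",
                "age_unit", "direction", "threshold",
            ]
        ).to_csv(p, index=False)
        table = load_cutoff_template(p)
        assert table.rules == []

    def test_overlapping_rules_rejected(self):
        mk = lambda lo, hi: CutoffRule(
            biomarker="zinc", condition_label="zinc_deficiency", group="WRA",
            age_min=lo, age_max=hi, age_unit="years", direction="below", threshold=10.1,
        )
        with pytest.raises(TemplateError, match="overlapping"):
            CutoffTable([mk(15, 30), mk(25, 49)])

    def test_disjoint_age_ranges_allowed(self):
        mk = lambda lo, hi, thr: CutoffRule(
            biomarker="zinc", condition_label="zinc_deficiency", group="WRA",
            age_min=lo, age_max=hi, age_unit="years", direction="below", threshold=thr,
        )
        table = CutoffTable([mk(15, 29.99, 10.1), mk(30, 49, 10.7)])
        assert len(table.lookup("zinc", "WRA", 25 * 12, sex="female")) == 1

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises((TemplateError, ValueError), match="> 0"):
            CutoffRule(
                biomarker="zinc", condition_label="z", group="any",
                age_min=1, age_max=2, age_unit="years", direction="below", threshold=0,
            )

    def test_age_interval_closed_both_ends(self):
        table = default_cutoffs()
        assert table.lookup("ferritin", "PSC", 6.0)  # lower bound included
        assert table.lookup("ferritin", "PSC", 59.0)  # upper bound included
        assert not table.lookup("ferritin", "PSC", 59.01)

    def test_lookup_is_a_function_on_age_grid(self):
        """≤1 matching rule per condition over an exhaustive age grid."""
        table = default_cutoffs()
        ages_months = np.arange(0.0, 70 * 12.0, 1.0)
        for group in ("PSC", "WRA"):
            for sex in ("male", "female"):
                for bm in table.biomarkers():
                    conditions = {r.condition_label for r in table.rules_for(bm)}
                    for cond in conditions:
                        matches = [
                            len(table.lookup(bm, group, a, sex, cond))
                            for a in ages_months
                        ]
                        assert max(matches, default=0) <= 1


class TestCrossValidation:
    def _descriptor(self, **kw):
        defaults = dict(
            dataset_id="d1", file_path="a.csv", population_group="PSC",
            biomarkers=[
                m.templates.BiomarkerMapping(
                    biomarker="ferritin", source_column="FER", source_unit="ug/L"
                )
            ],
        )
        defaults.update(kw)
        return m.DatasetDescriptor(**defaults)

    def test_unused_cutoffs_warned(self):
        report = validate_templates([self._descriptor()], default_cutoffs())
        assert any("zinc" in w for w in report.warnings)

    def test_matching_templates_clean(self):
        table = CutoffTable(
            [
                CutoffRule(
                    biomarker="ferritin", condition_label="iron_deficiency",
                    group="PSC", age_min=6, age_max=59, age_unit="months",
                    direction="below", threshold=12,
                )
            ]
        )
        assert validate_templates([self._descriptor()], table).empty

    def test_group_mismatch_warned(self):
        psc_only = CutoffTable(
            [
                CutoffRule(
                    biomarker="ferritin", condition_label="iron_deficiency",
                    group="PSC", age_min=6, age_max=59, age_unit="months",
                    direction="below", threshold=12,
                )
            ]
        )
        report = validate_templates(
            [self._descriptor(population_group="other")], psc_only
        )
        assert any("no cutoff rule applies" in w for w in report.warnings)

    def test_report_never_mutates(self):
        descs = [self._descriptor()]
        table = default_cutoffs()
        before = len(table.rules)
        validate_templates(descs, table)
        assert len(table.rules) == before and descs[0].dataset_id == "d1"
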