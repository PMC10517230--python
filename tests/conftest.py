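import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mnsurvey as m
from mnsurvey.ingest import StandardizedDataset

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def psc_spec():
    """Default PSC study conditions, fixed seed."""
    return m.SimulationSpec(seed=20230601)


@pytest.fixture(scope="session")
def psc_fixture(psc_spec, tmp_path_factory):
    """Generated CSV dataset + truth sidecar + matching templates."""
    root = tmp_path_factory.mktemp("psc_fixture")
    data_path, truth_path = m.generate_survey_dataset(psc_spec, root, "csv")
    template_path, cutoff_path = m.generate_templates(psc_spec, data_path, root)
    return {
        "root": root,
        "data": data_path,
        "truth": truth_path,
        "template": template_path,
        "cutoffs": cutoff_path,
    }


def make_standardized(
    columns: dict,
    units: dict,
    group: str = "PSC",
    age_column: str | None = None,
    has_design: bool = False,
    dataset_id: str = "t",
) -> StandardizedDataset:
    """Assemble a StandardizedDataset directly for unit tests."""
    return StandardizedDataset(
        dataset_id=dataset_id,
        data=pd.DataFrame(columns),
        units=units,
        population_group=group,
        age_column=age_column,
        has_design=has_design,
    )


def oracle_stratified_mean(y, w, stratum, psu):
    """Independent brute-force Hájek mean + stratified between-PSU SE.

    Direct transcription of the textbook formula, kept free of any code
    from the package under test.
    """
    y, w = np.asarray(y, float), np.asarray(w, float)
    W = w.sum()
    ybar = float((w * y).sum() / W)
    z = w * (y - ybar)
    df = pd.DataFrame({"s": stratum, "p": psu, "z": z})
    totals = df.groupby(["s", "p"])["z"].sum()
    v = 0.0
    for _, zh in totals.groupby(level="s"):
        nh = len(zh)
        v += nh / (nh - 1) * float(((zh - zh.mean()) ** 2).sum())
    return ybar, float(np.sqrt(v) / W)
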