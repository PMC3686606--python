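import numpy as np
import pandas as pd
import pytest

from bicarotid import CohortConfig, MedianTable, classify_cohort, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_subjects=2500, seed=20130615)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def classified_small(small_cohort) -> pd.DataFrame:
    medians = MedianTable.from_cohort(small_cohort)
    return classify_cohort(small_cohort, medians)


def make_manual_cohort(rows: list[dict]) -> pd.DataFrame:
    """Hand-built cohort rows with schema defaults filled in."""
    defaults = dict(
        sex="F", age=55.0, race="white", height_cm=162.0,
        r_imt_mm=0.6, l_imt_mm=0.6, r_dia_mm=7.0, l_dia_mm=7.0,
        event=0, time_years=11.0, prevalent_stroke=0,
    )
    out = []
    for i, r in enumerate(rows):
        d = dict(defaults, subject_id=f"H{i:03d}")
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)
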