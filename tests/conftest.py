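import numpy as np
import pandas as pd
import pytest

import cytosurge as cs


@pytest.fixture(scope="session")
def default_cohort():
    """One default simulated cohort (surge injected), shared across tests."""
    return cs.simulate_cohort(cs.CohortSimParams(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no injected surge."""
    return cs.simulate_cohort(cs.CohortSimParams(seed=11, surge_peak_log_effect=0.0))


@pytest.fixture(scope="session")
def default_tissue():
    return cs.simulate_tissue(seed=7)


@pytest.fixture()
def small_panel():
    """Hand-built 6-sample, 3-cytokine panel with two subjects."""
    rows = []
    for i in range(6):
        rows.append(
            dict(
                sample_id=f"P{i}",
                subject_id="A" if i < 3 else "B",
                visit_date=pd.Timestamp("2010-01-01") + pd.Timedelta(days=365 * i),
                age_at_sampling=70.0 + i,
                sex="F" if i < 3 else "M",
                IL6=10.0 * (i + 1),
                TNF=5.0,
                CXCL10=100.0,
            )
        )
    return cs.PanelTable(pd.DataFrame(rows), ["IL6", "TNF", "CXCL10"])


def make_events(rows):
    """rows: list of (subject_id, category, iso_date[, age])."""
    recs = []
    for r in rows:
        recs.append(
            dict(
                subject_id=r[0],
                category=r[1],
                diagnosis_date=r[2],
                age_at_diagnosis=r[3] if len(r) > 3 else np.nan,
            )
        )
    return cs.io.validate_events(pd.DataFrame(recs))
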