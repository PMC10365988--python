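import numpy as np
import pandas as pd
import pytest

import dietfootprint as dfp
from dietfootprint.cohort import item_column


@pytest.fixture(scope="session")
def default_db():
    return dfp.gen_lca_database(dfp.default_lca_spec(), seed=11)


@pytest.fixture(scope="session")
def default_links():
    return dfp.default_link_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Screened desk-scale cohort: 60 participants per diet group."""
    cohort = dfp.gen_cohort(dfp.default_cohort_spec(60), seed=12)
    retained, _ = dfp.apply_exclusions(cohort)
    return retained


@pytest.fixture
def point_mass_db():
    """Degenerate database: every category a single point mass at its median."""
    return dfp.gen_lca_database(dfp.default_lca_spec(sigma_scale=0.0, n_records=1), seed=5)


def make_cohort_row(pid="P0", age=45.0, gender="F", answers=("Yes",) * 4,
                    energy=2000.0, completion=1.0, intakes=None, item_ids=("meat",)):
    """One hand-built cohort row with item_<id>_g columns."""
    row = {
        "id": pid, "age": age, "gender": gender,
        "q_meat": answers[0], "q_fish": answers[1], "q_eggs": answers[2], "q_dairy": answers[3],
        "energy_kcal": energy, "ffq_completion": completion,
    }
    intakes = intakes or {}
    for item in item_ids:
        row[item_column(item)] = intakes.get(item, 0.0)
    return row


def cohort_frame(rows):
    return pd.DataFrame(rows)
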