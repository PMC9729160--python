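import logging

import pandas as pd
import pytest

import iabrisk as ir

logging.getLogger("iabrisk").setLevel(logging.ERROR)
for name in ("iabrisk.ipcw", "iabrisk.glm", "iabrisk.evaluate"):
    logging.getLogger(name).setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort() -> ir.GeneratedCohort:
    """A 400-child longitudinal cohort shared across tests."""
    return ir.generate_cohort(ir.CohortConfig(n_children=400, seed=42))


@pytest.fixture(scope="session")
def small_sero(small_cohort) -> pd.DataFrame:
    return ir.seroconversion_table(small_cohort.children, small_cohort.visits)


def make_child(child_id="c1", diagnosis=None, last_fu=20.0, **overrides):
    base = dict(
        child_id=child_id,
        source="DIPP",
        sex="M",
        family_history=0,
        hla_group="B",
        diagnosis_age_years=diagnosis,
        last_followup_age_years=last_fu,
    )
    base.update(overrides)
    return pd.Series(base)


def make_visits(child_id, ages, iaa=None, gada=None, ia2a=None):
    """Visit frame for one child; unspecified antibodies sit at mULN = 0.1."""
    n = len(ages)
    return pd.DataFrame(
        {
            "child_id": [child_id] * n,
            "age_years": list(ages),
            "iaa_mULN": iaa if iaa is not None else [0.1] * n,
            "gada_mULN": gada if gada is not None else [0.1] * n,
            "ia2a_mULN": ia2a if ia2a is not None else [0.1] * n,
        }
    )
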