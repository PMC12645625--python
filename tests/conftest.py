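import numpy as np
import pandas as pd
import pytest

from sibmort.cmc import to_cmc
from sibmort.synthetic import calibrate_regime, simulate_sibships

INTERVIEW = to_cmc(2022, 12)   # 1476
CUTOFF = to_cmc(2019, 1)       # 1429


@pytest.fixture(scope="session")
def regime15():
    return calibrate_regime(0.15)


@pytest.fixture(scope="session")
def survey(regime15):
    """A moderate simulated survey shared by read-only tests."""
    resp, sib = simulate_sibships(regime15, 5000, INTERVIEW, seed=42)
    return resp, sib


def make_respondents(ages, interview_cmc=INTERVIEW, **overrides):
    n = len(ages)
    base = {
        "respondent_id": [f"p{i:04d}" for i in range(n)],
        "sex": ["f"] * n,
        "age_years": list(ages),
        "interview_cmc": interview_cmc,
        "residence": ["urban"] * n,
        "education": ["secondary"] * n,
        "hh_size_class": ["1-5"] * n,
        "design_weight": [1.0] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


def make_siblings(rows):
    """rows: list of dicts with sibling fields (defaults filled in)."""
    out = []
    for i, r in enumerate(rows):
        d = {"respondent_id": "p0000", "line_no": i + 1, "sex": "f",
             "alive": True, "age_now": np.nan, "age_at_death": np.nan,
             "death_cmc": np.nan, "birth_cmc": np.nan, "imputed_fields": ""}
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)
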