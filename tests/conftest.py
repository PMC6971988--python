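import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_strata_cohort() -> pd.DataFrame:
    """Two equal strata of 100 children (rural/urban), measured 80 and 60.

    Obesity is 10% in the rural stratum and 50% in the urban one, so the
    true equal-strata prevalence is 30% while the complete-case sample
    holds 8 + 30 = 38 obese of 140 measured (27.143%).  Missingness is
    a deterministic function of the stratum — the saturated missingness
    model recovers it exactly.
    """
    rows = []
    i = 0

    def add(n, residence, measured, obese):
        nonlocal i
        for _ in range(n):
            rows.append(
                {
                    "child_id": f"t{i:04d}",
                    "sex": "boy",
                    "residence": residence,
                    "income": 2,
                    "z_base": 0.0,
                    "status_base": "normal",
                    "age_years": 7,
                    "measured": measured,
                    "z_follow": 2.5 if obese else 0.0,
                    "status_follow": ("obese" if obese else "normal") if measured else pd.NA,
                }
            )
            i += 1

    add(8, "rural", True, True)
    add(72, "rural", True, False)
    add(20, "rural", False, False)
    add(30, "urban", True, True)
    add(30, "urban", True, False)
    add(40, "urban", False, False)
    return pd.DataFrame(rows)
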