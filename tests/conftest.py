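import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from jnksig.preprocess import ExpressionMatrix
from jnksig.synthio import ClinicalCohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_counts() -> ExpressionMatrix:
    """3 genes x 4 samples of raw counts with unequal library sizes."""
    df = pd.DataFrame(
        [[10, 20, 0, 5], [100, 200, 50, 55], [1, 2, 3, 4]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(df, units="raw_counts")


def make_clinical(
    n: int,
    n_cases: int,
    seed: int = 0,
    single_stratum: bool = False,
) -> ClinicalCohort:
    """Hand-built clinical table with an exact BCFI case count."""
    rng = np.random.default_rng(seed)
    tab = pd.DataFrame(index=[f"P{i:04d}" for i in range(n)])
    for ep in ("dfs", "os", "drfi", "bcfi"):
        tab[f"{ep}_time"] = rng.uniform(1.0, 120.0, n)
        tab[f"{ep}_event"] = 0
    tab.iloc[: n_cases, tab.columns.get_loc("bcfi_event")] = 1
    tab.loc[tab["bcfi_event"] == 1, "dfs_event"] = 1
    if single_stratum:
        tab["tumor_size_category"] = "T1"
        tab["nodal_category"] = "N0"
        tab["age_category"] = "60+"
        tab["treatment"] = "CM"
    else:
        tab["tumor_size_category"] = rng.choice(["T1", "T2", "T3"], n)
        tab["nodal_category"] = rng.choice(["N0", "N1-3", "N4plus"], n)
        tab["age_category"] = rng.choice(["<40", "40-<50", "50-<60", "60+"], n)
        tab["treatment"] = rng.choice(["CM", "no-CM"], n)
    tab["tils_percent"] = rng.uniform(0.0, 60.0, n)
    return ClinicalCohort(tab)
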