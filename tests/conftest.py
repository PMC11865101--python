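import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from actisleep.features import FEATURE_NAMES, CaseTable

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_case_table(
    n: int,
    seed: int = 0,
    participant: str = "P01",
    n_features: int | None = None,
    target_from=None,
) -> CaseTable:
    """Random case table with independent features and targets.

    Features are drawn on activity-like scales; targets are sleep-like
    seconds.  ``target_from(rng, X) -> y`` may inject a dependence.
    """
    rng = np.random.default_rng(seed)
    names = FEATURE_NAMES if n_features is None else FEATURE_NAMES[:n_features]
    X = rng.normal(5000, 1500, size=(n, len(names)))
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "participant_id", participant)
    df.insert(1, "date", pd.date_range("2021-01-04", periods=n, freq="D"))
    if target_from is None:
        df["light_sleep_s"] = rng.normal(13500, 2700, n)
        df["deep_sleep_s"] = rng.normal(13400, 2400, n)
    else:
        df["light_sleep_s"] = target_from(rng, X)
        df["deep_sleep_s"] = rng.normal(13400, 2400, n)
    return CaseTable(df, {"synthetic": True, "seed": seed})


@pytest.fixture
def case_table_factory():
    return make_case_table
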