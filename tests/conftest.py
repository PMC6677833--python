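import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import heterosub as hs

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# Synthetic centroids sit on the raw log2 scale, so per-gene median
# centering (meant for centroids built from centered data) is disabled
# when classifying generated cohorts.
RAW_SCALE = hs.ClassifierParams(center_genes=False)


@pytest.fixture(scope="session")
def default_cohort() -> hs.simulate.Cohort:
    """One moderately noisy five-subtype cohort shared across read-only tests."""
    return hs.generate_cohort(hs.GeneratorParams(seed=20))


@pytest.fixture()
def tiny_matrix() -> pd.DataFrame:
    rng = np.random.default_rng(4)
    return pd.DataFrame(
        rng.normal(8, 1, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(4)],
    )


def pearson_brute(x, y) -> float:
    """Textbook Pearson correlation, written out term by term (test oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = (sum((v - mx) ** 2 for v in x) * sum((w - my) ** 2 for w in y)) ** 0.5
    return num / den
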