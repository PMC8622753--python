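import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hurdlebss import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def synth_small():
    """One mid-sized synthetic cohort shared across tests (n=2000)."""
    return generate_cohort(GeneratorConfig(n_subjects=2000, seed=1))


@pytest.fixture(scope="session")
def synth_large():
    """Larger draw for distributional checks (n=20000)."""
    return generate_cohort(GeneratorConfig(n_subjects=20000, seed=2))


def sample_hurdle_poisson(rng, pi, lam, n):
    """Direct hurdle-law sampler used as an independent data source in tests."""
    pi = np.broadcast_to(np.asarray(pi, float), (n,))
    lam = np.broadcast_to(np.asarray(lam, float), (n,))
    pos = rng.random(n) < pi
    y = np.zeros(n, dtype=int)
    f0 = np.exp(-lam[pos])
    u = rng.random(int(pos.sum()))
    y[pos] = np.maximum(stats.poisson.ppf(f0 + u * (1 - f0), lam[pos]).astype(int), 1)
    return y


@pytest.fixture
def events_frame():
    """Helper: build a one-subject claims event frame from terse tuples."""
    def make(*rows):
        return pd.DataFrame(
            [{"subject_id": "S1", "quarter": q, "icd10_code": c,
              "provider_group": g, "event_kind": k}
             for (q, c, g, k) in rows],
            columns=["subject_id", "quarter", "icd10_code",
                     "provider_group", "event_kind"])
    return make
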