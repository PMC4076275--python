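import numpy as np
import pandas as pd
import pytest

from ctscreen import default_variants, generate_cohort
from ctscreen.params import CohortParams
from ctscreen.cohort import Cohort
from ctscreen.reporting import run_variant_sweep

SEED = 1


@pytest.fixture(scope="session")
def cohort20k():
    return generate_cohort(20_000, SEED)


@pytest.fixture(scope="session")
def ensemble_outcomes(cohort20k):
    """Full 578-scenario sweep for all five shipped variants (shared by the
    frontier/consensus and qualitative-replication tests)."""
    return pd.concat(
        [run_variant_sweep(cohort20k, v, SEED) for v in default_variants()],
        ignore_index=True)


def make_cohort(init_age, quit_age, cpd, n, sex=None, oc_death=100.0,
                seed=0):
    """Hand-built homogeneous cohort (arrays broadcast to length n)."""
    def arr(v, dtype=float):
        return np.full(n, v, dtype=dtype)
    sexes = (np.tile([0, 1], n)[:n].astype(np.int8) if sex is None
             else arr(sex, np.int8))
    smoker = not np.isnan(init_age)
    return Cohort(
        sex=sexes,
        init_age=arr(init_age),
        quit_age=arr(quit_age),
        intensity_class=arr(2 if smoker else -1, np.int8),
        cpd=arr(cpd if smoker else 0.0),
        oc_death_age=arr(oc_death),
        seed=seed, params=CohortParams())
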