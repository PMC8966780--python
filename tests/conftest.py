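import numpy as np
import pandas as pd
import pytest

from omibone import CohortConfig, generate_cohort
from omibone.metabolome import IntensityTable


@pytest.fixture(scope="session")
def small_cohort():
    """A small signal-bearing cohort shared across tests."""
    cfg = CohortConfig(n_samples=150, n_taxa=80, n_metabolites=60, n_qc=15,
                       frac_planted_taxa=0.05, effect_size=0.8, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def toy_intensity():
    """6 biological + 3 QC samples, 4 features, one missing cell."""
    rng = np.random.default_rng(3)
    vals = np.exp(rng.normal(10, 0.3, size=(9, 4)))
    frame = pd.DataFrame(vals, index=[f"s{i}" for i in range(9)],
                         columns=list("abcd"))
    frame.iloc[1, 2] = np.nan
    qc = np.r_[np.zeros(6, dtype=bool), np.ones(3, dtype=bool)]
    return IntensityTable(values=frame, qc=qc)
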