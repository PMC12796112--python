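import numpy as np
import pandas as pd
import pytest

from turbomap import (ApmsSimConfig, CohortSimConfig, IntensityMatrix,
                      SampleDesign, simulate_apms, simulate_cohort)


@pytest.fixture(scope="session")
def apms_data():
    """Seeded AP-MS dataset with 50 planted interactors (effect 4)."""
    cfg = ApmsSimConfig(n_proteins=1500, n_per_group=10, n_true=50,
                        effect_log2fc=4.0, seed=11)
    return simulate_apms(cfg), cfg


@pytest.fixture(scope="session")
def cohort_data():
    """Seeded cohort with 4 planted modules and a Braak effect on module 1."""
    cfg = CohortSimConfig(seed=5, trait_effects={"braak": [0.8, 0, 0, 0],
                                                 "dx_AD": [1.0, 0, 0, 0]})
    return simulate_cohort(cfg), cfg


@pytest.fixture
def tiny_matrix():
    """4 proteins x 4 samples, fully observed."""
    rng = np.random.default_rng(3)
    vals = rng.normal(20, 1, size=(4, 4))
    return IntensityMatrix([f"P{i}" for i in range(4)],
                           [f"s{j}" for j in range(4)],
                           vals, np.ones((4, 4), bool))


@pytest.fixture
def two_group_design():
    return SampleDesign(pd.DataFrame(
        {"group": ["A", "A", "B", "B"]},
        index=pd.Index(["s0", "s1", "s2", "s3"], name="sample_id")))
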