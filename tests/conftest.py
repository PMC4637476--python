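import numpy as np
import pandas as pd
import pytest

from sigpanel.simulate import (
    CohortConfig,
    NoiseModel,
    antibody_ids,
    plant_effect_profile,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    """Compact cohort reused across IO/preprocess tests: 50 samples,
    30 antibodies, 3 rounds."""
    return CohortConfig(
        n_pdac=20,
        n_opd=20,
        n_npc=10,
        subsite_counts={"head": 10, "body": 4, "tail": 2, "other": 2,
                        "unspecified": 2},
        n_rounds=3,
        slides_per_round=3,
        subarrays_per_slide=7,
        n_antibodies=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """(spots, sheet, effects, annotation) for the compact null cohort."""
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def planted_cohort(small_cfg):
    """Compact cohort with 5 planted case-vs-control markers (delta 0.8)."""
    effects = plant_effect_profile(
        antibody_ids(small_cfg.n_antibodies), k_npc=5, k_opd=0, k_site=0,
        delta=0.8, seed=23,
    )
    return simulate_cohort(small_cfg, effects=effects)


@pytest.fixture()
def two_group_matrix():
    """Random 30-sample x 12-antibody log10 matrix with labels, 3 columns
    shifted by 1.0 for the first group."""
    rng = np.random.default_rng(42)
    samples = [f"S{i:02d}" for i in range(30)]
    cols = [f"Ab{i:03d}" for i in range(12)]
    X = pd.DataFrame(rng.normal(3.0, 0.2, size=(30, 12)), index=samples,
                     columns=cols)
    X.iloc[:18, :3] += 1.0
    labels = pd.Series(["case"] * 18 + ["ctrl"] * 12, index=samples)
    return X, labels
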