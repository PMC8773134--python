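import numpy as np
import pandas as pd
import pytest

from gutclock import (
    SyntheticConfig,
    clr_transform,
    generate_cohort,
    multiplicative_replacement,
)


def clr_frame(view):
    """CLR design frame of an abundance view (zeros replaced first)."""
    return clr_transform(multiplicative_replacement(view)).frame


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size two-view cohort with planted signal and mild geographic
    confounding, shared across read-only tests."""
    cfg = SyntheticConfig(
        n_samples=250,
        n_species=30,
        n_pathways=20,
        n_signal_features_per_view=6,
        confound_strength=0.25,
        signal_effect=0.03,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_ages(small_cohort):
    return pd.Series(
        small_cohort.ages, index=small_cohort.metadata.sample_ids, name="age"
    )


@pytest.fixture
def abundance_frame():
    """Tiny hand-checkable composition."""
    return pd.DataFrame(
        [[0.5, 0.5, 0.0], [0.25, 0.25, 0.5], [0.2, 0.3, 0.5]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
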