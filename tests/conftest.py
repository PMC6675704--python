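import numpy as np
import pytest

from pepscreen import array_signal, serostats, synthetic_data


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully-formed synthetic study (20 cases / 40 controls)."""
    cfg = synthetic_data.default_config(seed=42, n_case=20, n_control=40)
    return synthetic_data.generate_study(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    profiles, qc = array_signal.load_cohort(
        small_cohort.manifest, small_cohort.layout, arrays=small_cohort.arrays
    )
    return profiles


@pytest.fixture(scope="session")
def small_calls(small_profiles):
    long = array_signal.profiles_to_long(small_profiles)
    pre = long.loc[long["timepoint"] == "preoperative"]
    cutoffs = serostats.optimize_cutoffs(pre)
    return serostats.classify_cohort(small_profiles, cutoffs)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
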