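import pytest

from itemforest import RFConfig, default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120-subject, 12-item cohort (4 informative at shift 1.5) for unit tests."""
    spec = default_cohort_spec(
        seed=42, n_per_group=60, n_informative=4, n_ados=7, n_adi=5
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_rf_config():
    return RFConfig(n_trees=30, importance_repeats=2, seed=7)
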