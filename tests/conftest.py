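import numpy as np
import pytest

import rapatest as rt


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort (deterministic)."""
    spec = rt.SyntheticCohortSpec(n_control=8, n_mci=3, n_ad=8, seed=11,
                                  histogram_events=5000)
    return rt.generate_cohort(spec)


@pytest.fixture(scope="session")
def expression_default():
    """Default-preset expression matrix with group table and truth sets."""
    spec = rt.SyntheticExpressionSpec(seed=42)
    matrix, groups_df, truth = rt.generate_expression(spec)
    return matrix, groups_df.set_index("sample_id")["group"], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
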