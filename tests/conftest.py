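import numpy as np
import pytest

import cyclebp
from cyclebp import preprocessing as pp
from cyclebp import records


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic subjects plus their ground-truth table."""
    cfg = cyclebp.SyntheticConfig(n_subjects=6, seed=11)
    cohort, truth = cyclebp.synth_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def prepared(small_cohort):
    """Preprocessed samples with the fitted specs for the small cohort."""
    cohort, truth = small_cohort
    window = pp.WindowSpec.from_cohort(cohort)
    converted = records.Cohort(
        [records.convert_record_area(r) for r in cohort], role="train"
    )
    norm = pp.fit_minmax(converted)
    samples = pp.build_dataset(cohort, norm, window)
    return samples, norm, window, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
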