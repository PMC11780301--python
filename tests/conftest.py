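import numpy as np
import pytest

import healthgap as hg


def process(cfg: hg.SyntheticConfig, dimensions=("cognition",)):
    """Cohort -> scored -> divide -> deprivation, one call."""
    table = hg.derive_table(hg.score_table(hg.generate_cohort(cfg)))
    table, _ = hg.rd_table(table, dimensions)
    return table


@pytest.fixture(scope="session")
def processed_2018():
    """A moderately confounded 2018-wave cohort with a real treatment effect,
    fully processed through deprivation, shared across read-only tests."""
    cfg = hg.SyntheticConfig(
        n=1200, seed=7, wave=2018,
        confounding_strength=0.5, treatment_effect_tau=0.3,
    )
    return process(cfg, hg.DIMENSIONS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
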