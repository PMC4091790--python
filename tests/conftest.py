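import pytest

from spermage import SyntheticConfig
from spermage import synthetic as syn


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale cohort: 200 candidate windows with 20+4 planted regions."""
    return SyntheticConfig(
        seed=11,
        n_candidate_windows=200,
        n_probes=2000,
        planted_hypo=20,
        planted_hyper=4,
        min_abs_log2_effect=0.4,
        min_planted_diff=0.035,
    )


@pytest.fixture(scope="session")
def small_fixture(small_config):
    return syn.generate_fixture(small_config)
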