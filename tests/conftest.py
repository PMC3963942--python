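import random

import pytest

from numtscreen import demo_config, load_dm_primers, load_sb_primers, run_full_screen


@pytest.fixture(scope="session")
def dm_pairs():
    return load_dm_primers()


@pytest.fixture(scope="session")
def sb_pairs():
    return load_sb_primers()


@pytest.fixture(scope="session")
def all_pairs(dm_pairs, sb_pairs):
    return dm_pairs + sb_pairs


@pytest.fixture
def rng():
    return random.Random(20140324)


@pytest.fixture(scope="session")
def demo_result():
    """One full pipeline run on the packaged demonstration conditions."""
    return run_full_screen(demo_config(seed=1))
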