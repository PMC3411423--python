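import numpy as np
import pytest

import dqscore as dq
from dqscore.bank import ItemBank, ItemPart, KnowledgeItem, mc_item, open_item


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort (440/88/35), fixed seed."""
    return dq.generate_cohort(dq.GeneratorConfig(), seed=123)


@pytest.fixture(scope="session")
def default_retest(default_cohort):
    return dq.generate_retest(default_cohort, dq.GeneratorConfig(), seed=124)


@pytest.fixture(scope="session")
def small_config():
    """A fast small-cohort configuration for I/O and structural tests."""
    return dq.GeneratorConfig(n_patients=40, n_providers=6, n_controls=5,
                              n_lump_then_mast=3, n_no_treatment=2,
                              retest_n=10, low_completer_rate=0.0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return dq.generate_cohort(small_config, seed=7)


@pytest.fixture
def toy_bank():
    """Hand-built bank: 4-option MC, 5-option MC, open-ended, multi-part."""
    multi = KnowledgeItem(
        item_id="twopart",
        parts=(ItemPart(part_id="a", kind="multiple_choice", correct=1, n_options=4, weight=0.25),
               ItemPart(part_id="b", kind="multiple_choice", correct=0, n_options=5, weight=0.75)))
    return ItemBank([
        mc_item("mc4", correct=2, k=4, in_screener=True),
        mc_item("mc5", correct=0, k=5),
        open_item("open1", lo=80, hi=90),
        multi,
    ])
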