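from datetime import date

import pytest

from emotraj import Lexicon, LexiconEntry, StudyWindow
from emotraj.synthetic import SynthConfig, gen_corpus

FIT_WINDOW = StudyWindow(date(2020, 1, 20), date(2020, 2, 6), date(2020, 1, 23))


@pytest.fixture(scope="session")
def jiayou_lexicon() -> Lexicon:
    """One-entry lexicon holding the published annotation for 加油."""
    return Lexicon([LexiconEntry("加油", 2.000, 5.143)])


@pytest.fixture(scope="session")
def toy_lexicon() -> Lexicon:
    return Lexicon(
        [
            LexiconEntry("加油", 2.000, 5.143),
            LexiconEntry("高兴", 3.0, 6.0),
            LexiconEntry("难过", -2.5, 3.0),
            LexiconEntry("平静", 1.0, 1.0),
            LexiconEntry("愤怒", -3.0, 7.0),
        ]
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A rendered synthetic corpus shared by the slower integration tests."""
    cfg = SynthConfig(seed=7, n_wuhan=20, n_non_hubei=80, p_geotag=1.0)
    return gen_corpus(cfg)
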