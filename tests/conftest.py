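import numpy as np
import pytest

from tss import Corpus, Message


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Handcrafted messages covering single words, phrases and hashtags."""
    msgs = [
        Message(timestamp=10.0, text="I love Apple pie", id="a"),
        Message(timestamp=20.0, text="the fruit of passion", id="b"),
        Message(timestamp=30.0, text="go #WorldCup!!", id="c"),
        Message(timestamp=40.0, text="apple and banana smoothie", id="d"),
        Message(timestamp=50.0, text="passion fruit smoothie", id="e"),
        Message(timestamp=60.0, text="apple banana", id="f"),
    ]
    return Corpus(msgs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
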