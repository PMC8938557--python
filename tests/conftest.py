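import numpy as np
import pytest

from affectbandit.task import RICH, POOR, TrialRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_trials(choices, rewards, deck_classes, subject_id="s1", condition="neutral"):
    """Build an ordered trial sequence from parallel lists.

    ``choices`` uses 0/1 or 'A'/'B'; ``deck_classes`` gives the chosen
    deck's class per trial ('rich'/'poor').
    """
    deck_index = {"A": 0, "B": 1, 0: 0, 1: 1}
    return [
        TrialRecord(
            subject_id=subject_id, condition=condition, block=0, trial=t,
            chosen_deck=deck_index[c], deck_class=d, reward=r,
        )
        for t, (c, r, d) in enumerate(zip(choices, rewards, deck_classes))
    ]


@pytest.fixture
def toy_sequence():
    """Choices [A,A,B,B,A], rewards [1,0,1,1,0], deck A rich throughout."""
    choices = ["A", "A", "B", "B", "A"]
    rewards = [1, 0, 1, 1, 0]
    deck_classes = [RICH if c == "A" else POOR for c in choices]
    return make_trials(choices, rewards, deck_classes)
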