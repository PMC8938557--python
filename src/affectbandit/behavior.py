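"""Behavioral summaries: scores, win-stay/lose-shift strategies, PANAS diffs.

Win-stay is the proportion of rewarded trials on which the same deck was
chosen again on the next trial; lose-shift the proportion of non-rewarded
trials followed by a switch.  Both are split by the feedback trial's deck
class (rich vs poor), giving the four-way strategy profile.  The last trial
of a sequence never contributes (it has no successor), and stay/shift is
evaluated across block boundaries: the decks persist, only their reward
probabilities shift, and the feedback trial's own block defines its class.

Rates with an empty denominator are *undefined* and propagate as NaN; they
are never coerced to zero, and group averages exclude them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError
from .task import POOR, RICH, TrialRecord

WIN, LOSE = "win", "lose"
STAY, SHIFT = "stay", "shift"


@dataclass(frozen=True)
class StrategyEvent:
    feedback: str  # win / lose
    action: str  # stay / shift
    deck_class: str  # rich / poor


@dataclass(frozen=True)
class Rate:
    """A proportion with its event counts retained; undefined when n = 0."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        if self.denominator == 0:
            return math.nan
        return self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


@dataclass(frozen=True)
class StrategySummary:
    win_stay_rich: Rate
    win_stay_poor: Rate
    lose_shift_rich: Rate
    lose_shift_poor: Rate
    win_stay: Rate  # event-weighted pool over deck classes
    lose_shift: Rate


@dataclass(frozen=True)
class PanasDiff:
    """Post-minus-pre mean rating differences per affect subscale."""

    positive_diff: float
    negative_diff: float


def classify_strategy_events(trials: Sequence[TrialRecord]) -> list[StrategyEvent]:
    """One (feedback, action, deck_class) event per trial that has a successor.

    Trials must be ordered by trial index within one subject x condition.
    """
    indices = [t.trial for t in trials]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise DataError("trial indices must be strictly increasing within a sequence")
    events = []
    for cur, nxt in zip(trials, trials[1:]):
        feedback = WIN if cur.reward == 1 else LOSE
        action = STAY if nxt.chosen_deck == cur.chosen_deck else SHIFT
        events.append(StrategyEvent(feedback=feedback, action=action, deck_class=cur.deck_class))
    return events


def strategy_rates(events: Iterable[StrategyEvent]) -> StrategySummary:
    """Four-way win-stay/lose-shift rates plus event-weighted overall rates."""
    counts: dict[tuple[str, str, str], int] = {}
    for e in events:
        key = (e.feedback, e.action, e.deck_class)
        counts[key] = counts.get(key, 0) + 1

    def rate(feedback: str, action: str, deck_class: str | None) -> Rate:
        classes = (RICH, POOR) if deck_class is None else (deck_class,)
        num = sum(counts.get((feedback, action, c), 0) for c in classes)
        den = num + sum(
            counts.get((feedback, other, c), 0)
            for c in classes
            for other in (STAY, SHIFT)
            if other != action
        )
        return Rate(numerator=num, denominator=den)

    return StrategySummary(
        win_stay_rich=rate(WIN, STAY, RICH),
        win_stay_poor=rate(WIN, STAY, POOR),
        lose_shift_rich=rate(LOSE, SHIFT, RICH),
        lose_shift_poor=rate(LOSE, SHIFT, POOR),
        win_stay=rate(WIN, STAY, None),
        lose_shift=rate(LOSE, SHIFT, None),
    )


def total_score(trials: Sequence[TrialRecord]) -> int:
    """Total game points: the sum of the binary rewards."""
    rewards = [t.reward for t in trials]
    if any(r not in (0, 1) for r in rewards):
        raise DataError("rewards must be binary {0, 1}")
    return int(sum(rewards))


def panas_diff(
    pre_ratings: Mapping[str, float],
    post_ratings: Mapping[str, float],
    item_subscale: Mapping[str, str],
) -> PanasDiff:
    """Per-subscale mean(post) - mean(pre) over matched PANAS items.

    ``item_subscale`` maps each item name to ``"positive"`` or ``"negative"``.
    """
    if set(pre_ratings) != set(post_ratings):
        raise DataError("pre and post rating item sets differ")
    if not set(pre_ratings) <= set(item_subscale):
        raise DataError("every rated item must have a subscale label")
    diffs = {}
    for subscale in ("positive", "negative"):
        items = [i for i in pre_ratings if item_subscale[i] == subscale]
        if not items:
            raise DataError(f"no items on the {subscale} subscale")
        diffs[subscale] = float(
            np.mean([post_ratings[i] for i in items]) - np.mean([pre_ratings[i] for i in items])
        )
    return PanasDiff(positive_diff=diffs["positive"], negative_diff=diffs["negative"])
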