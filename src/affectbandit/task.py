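"""Two-choice probabilistic gambling task environment.

The task presents a pair of card decks whose reward probabilities sum to a
fixed total (60% by default) and stand in a rich:poor ratio (e.g. 6:1).  An
experimental session comprises 480 trials pseudorandomly divided into six
blocks of 70-90 trials; the rich/poor assignment and the ratio change from
block to block.  Feedback is a binary point (1/0) drawn independently per
trial from the chosen deck's probability.

A short training phase precedes the experiment: after every 20 trials the
player is probed to identify the rich deck, and training repeats until the
answer is correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError

DECK_LABELS = ("A", "B")

#: canonical deck-class labels
RICH, POOR = "rich", "poor"

DEFAULT_RATIO_SET: tuple[tuple[int, int], ...] = ((6, 1), (1, 6), (3, 1), (1, 3))


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the gambling task environment.

    ``ratio_set`` entries are (share, share) pairs; the larger share always
    belongs to the rich deck, while which *side* (deck A or B) is rich is
    randomized per block.
    """

    n_experimental_trials: int = 480
    n_blocks: int = 6
    block_length_range: tuple[int, int] = (70, 90)
    total_reward_prob: float = 0.60
    ratio_set: tuple[tuple[float, float], ...] = DEFAULT_RATIO_SET
    training_probe_after: int = 20
    baited: bool = False  # reserved; independent Bernoulli feedback only
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.block_length_range
        if lo > hi or lo < 1:
            raise ConfigurationError(
                f"block_length_range must satisfy 1 <= lo <= hi, got {lo}..{hi}"
            )
        if not (0.0 < self.total_reward_prob <= 1.0):
            raise ConfigurationError(
                f"total_reward_prob must lie in (0, 1], got {self.total_reward_prob}"
            )
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if self.n_blocks * lo > self.n_experimental_trials:
            raise ConfigurationError(
                f"infeasible schedule: n_blocks*min_length = {self.n_blocks * lo} "
                f"exceeds n_experimental_trials = {self.n_experimental_trials}"
            )
        if self.n_blocks * hi < self.n_experimental_trials:
            raise ConfigurationError(
                f"infeasible schedule: n_blocks*max_length = {self.n_blocks * hi} "
                f"is below n_experimental_trials = {self.n_experimental_trials}"
            )
        if not self.ratio_set:
            raise ConfigurationError("ratio_set must not be empty")
        for ratio in self.ratio_set:
            if len(ratio) != 2 or ratio[0] <= 0 or ratio[1] <= 0:
                raise ConfigurationError(f"ratio entries must be two positives, got {ratio}")
        if self.training_probe_after < 1:
            raise ConfigurationError("training_probe_after must be >= 1")
        if self.baited:
            raise ConfigurationError("baited reward scheduling is reserved and not implemented")


@dataclass(frozen=True)
class DeckPair:
    """Reward probabilities of the rich and poor decks of one block."""

    p_rich: float
    p_poor: float

    def __post_init__(self) -> None:
        if self.p_rich < self.p_poor:
            raise ConfigurationError("p_rich must be >= p_poor")

    @property
    def total(self) -> float:
        return self.p_rich + self.p_poor


@dataclass(frozen=True)
class Block:
    """One schedule block: trial count, deck pair, and which side is rich."""

    length: int
    ratio: tuple[float, float]
    rich_deck: int  # 0 = deck A, 1 = deck B
    decks: DeckPair

    def prob_of(self, deck: int) -> float:
        return self.decks.p_rich if deck == self.rich_deck else self.decks.p_poor

    def deck_class(self, deck: int) -> str:
        return RICH if deck == self.rich_deck else POOR


@dataclass(frozen=True)
class BlockSchedule:
    blocks: tuple[Block, ...]

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(b.length for b in self.blocks)

    @property
    def n_trials(self) -> int:
        return sum(self.lengths)

    def block_of_trial(self) -> np.ndarray:
        """0-based block index for every trial (half-open block boundaries)."""
        return np.repeat(np.arange(len(self.blocks)), self.lengths)


@dataclass(frozen=True)
class TrialRecord:
    """One gamble: where it happened, what was chosen, and the outcome."""

    subject_id: str
    condition: str
    block: int
    trial: int
    chosen_deck: int
    deck_class: str
    reward: int


def deck_probabilities(ratio: Sequence[float], total: float) -> DeckPair:
    """Split a total reward probability into a rich/poor pair at a given ratio.

    Solves p_rich / p_poor = max(ratio)/min(ratio) and p_rich + p_poor = total,
    e.g. (6, 1) with total 0.6 gives (0.5142857..., 0.0857142...).
    """
    a, b = float(ratio[0]), float(ratio[1])
    if a <= 0 or b <= 0:
        raise DomainError(f"ratio components must be positive, got ({a}, {b})")
    if not (0.0 < total <= 1.0):
        raise DomainError(f"total must lie in (0, 1], got {total}")
    hi, lo = max(a, b), min(a, b)
    p_rich = total * hi / (hi + lo)
    p_poor = total * lo / (hi + lo)
    return DeckPair(p_rich=p_rich, p_poor=p_poor)


from functools import lru_cache


@lru_cache(maxsize=64)
def _composition_counts(n_parts: int, lo: int, hi: int, total: int) -> np.ndarray:
    """ways[k][s] = number of ways to write s as a sum of k values in [lo, hi]."""
    ways = np.zeros((n_parts + 1, total + 1), dtype=float)
    ways[0, 0] = 1.0
    for k in range(1, n_parts + 1):
        csum = np.concatenate([[0.0], np.cumsum(ways[k - 1])])
        for s in range(total + 1):
            a = max(0, s - hi)
            b = s - lo
            if b >= a:
                ways[k, s] = csum[b + 1] - csum[a]
    return ways


def _sample_composition(
    total: int, n_parts: int, lo: int, hi: int, rng: np.random.Generator
) -> list[int]:
    ways = _composition_counts(n_parts, lo, hi, total)
    if ways[n_parts, total] == 0:
        raise ConfigurationError(
            f"no composition of {total} into {n_parts} parts within [{lo}, {hi}]"
        )
    lengths: list[int] = []
    remaining = total
    for k in range(n_parts, 0, -1):
        values = np.arange(lo, hi + 1)
        rests = remaining - values
        valid = (rests >= 0) & (rests <= total)
        weights = np.zeros(len(values))
        weights[valid] = ways[k - 1, rests[valid]]
        weights /= weights.sum()
        length = int(rng.choice(values, p=weights))
        lengths.append(length)
        remaining -= length
    return lengths


def make_block_schedule(config: TaskConfig, rng: np.random.Generator) -> BlockSchedule:
    """Draw a block schedule uniformly over the feasible set.

    Block lengths are drawn exactly uniformly over all compositions of the
    experimental trial count into ``n_blocks`` parts within the per-block
    range (sequential sampling weighted by composition counts, so every
    feasible composition is equally likely even at the edges of the range).
    Each block's ratio is drawn uniformly from the ratio set and the rich
    side is randomized independently.
    """
    lo, hi = config.block_length_range
    n, total = config.n_blocks, config.n_experimental_trials
    lengths = _sample_composition(total, n, lo, hi, rng)
    blocks = []
    for length in lengths:
        ratio = config.ratio_set[rng.integers(len(config.ratio_set))]
        rich_deck = int(rng.integers(2))
        decks = deck_probabilities(ratio, config.total_reward_prob)
        blocks.append(Block(length=int(length), ratio=tuple(ratio), rich_deck=rich_deck, decks=decks))
    return BlockSchedule(blocks=tuple(blocks))


def sample_feedback(chosen_deck_prob: float, rng: np.random.Generator) -> int:
    """Bernoulli point feedback for the chosen deck, independent across trials."""
    if not (0.0 <= chosen_deck_prob <= 1.0):
        raise DomainError(f"probability must lie in [0, 1], got {chosen_deck_prob}")
    return int(rng.random() < chosen_deck_prob)


class TrainingPolicy(Protocol):
    """Minimal interface a training-phase player must offer."""

    def choose(self, trial: int, rng: np.random.Generator) -> int: ...

    def observe(self, trial: int, deck: int, reward: int) -> None: ...

    def identify_rich(self, rng: np.random.Generator) -> int: ...


class EmpiricalCountPolicy:
    """Chooses decks at random and answers the probe from observed reward rates."""

    def __init__(self) -> None:
        self.rewards = [0, 0]
        self.counts = [0, 0]

    def choose(self, trial: int, rng: np.random.Generator) -> int:
        return int(rng.integers(2))

    def observe(self, trial: int, deck: int, reward: int) -> None:
        self.rewards[deck] += reward
        self.counts[deck] += 1

    def identify_rich(self, rng: np.random.Generator) -> int:
        rates = [
            self.rewards[d] / self.counts[d] if self.counts[d] else 0.5 for d in (0, 1)
        ]
        if rates[0] == rates[1]:
            return int(rng.integers(2))
        return int(rates[1] > rates[0])


class ScriptedProbePolicy:
    """Random chooser whose probe answers follow a fixed script (for testing)."""

    def __init__(self, answers: Sequence[int]):
        self.answers = list(answers)
        self._next = 0

    def choose(self, trial: int, rng: np.random.Generator) -> int:
        return int(rng.integers(2))

    def observe(self, trial: int, deck: int, reward: int) -> None:
        pass

    def identify_rich(self, rng: np.random.Generator) -> int:
        answer = self.answers[min(self._next, len(self.answers) - 1)]
        self._next += 1
        return answer


@dataclass(frozen=True)
class TrainingResult:
    first_probe_trial: int
    n_probe_cycles: int
    n_trials: int


def run_training_phase(
    config: TaskConfig,
    policy: TrainingPolicy,
    rng: np.random.Generator,
    max_cycles: int = 1000,
) -> tuple[list[TrialRecord], TrainingResult]:
    """Run training blocks of ``training_probe_after`` trials until the probe
    (identify the rich deck) is answered correctly.

    The training deck pair uses the first ratio in the ratio set with a
    randomized rich side, held fixed across probe cycles.
    """
    decks = deck_probabilities(config.ratio_set[0], config.total_reward_prob)
    rich_deck = int(rng.integers(2))
    block = Block(length=config.training_probe_after, ratio=tuple(config.ratio_set[0]),
                  rich_deck=rich_deck, decks=decks)
    records: list[TrialRecord] = []
    trial = 0
    for cycle in range(1, max_cycles + 1):
        for _ in range(config.training_probe_after):
            deck = policy.choose(trial, rng)
            reward = sample_feedback(block.prob_of(deck), rng)
            policy.observe(trial, deck, reward)
            records.append(
                TrialRecord(
                    subject_id="training", condition="training", block=cycle - 1,
                    trial=trial, chosen_deck=deck,
                    deck_class=block.deck_class(deck), reward=reward,
                )
            )
            trial += 1
        if policy.identify_rich(rng) == rich_deck:
            return records, TrainingResult(
                first_probe_trial=config.training_probe_after,
                n_probe_cycles=cycle,
                n_trials=trial,
            )
    raise DataError(f"training probe never answered correctly in {max_cycles} cycles")


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy one-row-per-trial table (the package's CSV interchange schema)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "condition": [r.condition for r in records],
            "block": [r.block for r in records],
            "trial": [r.trial for r in records],
            "chosen_deck": [DECK_LABELS[r.chosen_deck] for r in records],
            "deck_class": [r.deck_class for r in records],
            "reward": [r.reward for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame`."""
    deck_index = {label: i for i, label in enumerate(DECK_LABELS)}
    return [
        TrialRecord(
            subject_id=row.subject_id, condition=row.condition, block=int(row.block),
            trial=int(row.trial),
            chosen_deck=deck_index.get(row.chosen_deck, row.chosen_deck),
            deck_class=row.deck_class, reward=int(row.reward),
        )
        for row in frame.itertuples(index=False)
    ]
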