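"""Delta-rule / softmax generative choice model.

Each deck carries an expectation Q that is updated after the chosen deck's
binary outcome by the delta (Rescorla-Wagner) rule

    Q(t) = Q(t-1) + alpha * [R(t) - Q(t-1)],

where alpha in [0, 1] is the learning rate and the bracketed term is the
reward prediction error.  Expectations map to choice through a logistic
(softmax) transformation

    P_A(t) = exp(beta * Q_A(t)) / (exp(beta * Q_A(t)) + exp(beta * Q_B(t))),

where beta >= 0 is the choice consistency (inverse temperature).  Only the
chosen deck's expectation is updated; the other deck's is carried forward,
and expectations persist across block boundaries (players are not told
where blocks begin or end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DomainError
from .task import BlockSchedule, TrialRecord, sample_feedback

#: default initial expectation: midpoint of the binary outcome range
DEFAULT_Q0 = 0.5

BETA_MAX = 10.0


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject model parameters plus group/condition bookkeeping."""

    alpha: float
    beta: float
    subject_id: str = "anon"
    group: str = "CTRL"
    condition: str = "neutral"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise DomainError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (0.0 <= self.beta <= BETA_MAX):
            raise DomainError(f"beta must lie in [0, {BETA_MAX}], got {self.beta}")


@dataclass
class ExpectationTrace:
    """Trial-aligned latent state of a simulated subject.

    ``q_a``/``q_b`` hold the expectations *used for the choice* on each
    trial (i.e. before that trial's update); ``p_a`` the softmax probability
    of choosing deck A; ``choice`` and ``reward`` the realized events.
    """

    q_a: np.ndarray
    q_b: np.ndarray
    p_a: np.ndarray
    choice: np.ndarray
    reward: np.ndarray


def update_expectation(q_prev: float, reward: float, alpha: float) -> float:
    """One delta-rule step for the chosen deck."""
    if not (0.0 <= alpha <= 1.0):
        raise DomainError(f"alpha must lie in [0, 1], got {alpha}")
    return q_prev + alpha * (reward - q_prev)


def choice_probability(q_a: float, q_b: float, beta: float) -> float:
    """Softmax probability of choosing deck A, computed overflow-safely."""
    if beta < 0:
        raise DomainError(f"beta must be >= 0, got {beta}")
    return float(expit(beta * (q_a - q_b)))


def simulate_subject(
    params: SubjectParams,
    schedule: BlockSchedule,
    rng: np.random.Generator,
    q0: float | tuple[float, float] = DEFAULT_Q0,
) -> tuple[list[TrialRecord], ExpectationTrace]:
    """Play a full schedule with the delta-rule/softmax agent.

    ``q0`` may be a scalar (both decks) or an (A, B) pair.  Returns one
    trial record per scheduled trial together with the aligned expectation
    trace.  Deterministic given the generator state.
    """
    n = schedule.n_trials
    q = np.broadcast_to(np.asarray(q0, dtype=float), (2,)).copy()
    trace = ExpectationTrace(
        q_a=np.empty(n), q_b=np.empty(n), p_a=np.empty(n),
        choice=np.empty(n, dtype=int), reward=np.empty(n, dtype=int),
    )
    records: list[TrialRecord] = []
    t = 0
    for b, block in enumerate(schedule.blocks):
        for _ in range(block.length):
            p_a = choice_probability(q[0], q[1], params.beta)
            choice = int(rng.random() >= p_a)  # 0 = A with probability p_a
            reward = sample_feedback(block.prob_of(choice), rng)
            trace.q_a[t], trace.q_b[t], trace.p_a[t] = q[0], q[1], p_a
            trace.choice[t], trace.reward[t] = choice, reward
            records.append(
                TrialRecord(
                    subject_id=params.subject_id, condition=params.condition,
                    block=b, trial=t, chosen_deck=choice,
                    deck_class=block.deck_class(choice), reward=reward,
                )
            )
            q[choice] = update_expectation(q[choice], reward, params.alpha)
            t += 1
    return records, trace
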