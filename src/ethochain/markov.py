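"""First-order Markov model of chain progression.

The chain is modelled over states A0..Ak plus an absorbing FAIL state, with
forward-only transitions: from state i the process can move to any strictly
later state j (skips allowed) or to FAIL. Transition probabilities are the
observed transition fractions,

    p_ij = a_ij / sum_j a_ij,

so every row with observations sums to 1. The terminal state Ak ("success",
completion of the chain) and FAIL are absorbing. Because the chain is
forward-only and every non-absorbing row leads strictly forward or to FAIL,
all probability mass is absorbed in at most k steps; the steady-state vector
v = P'v therefore exists and puts all mass on {Ak, FAIL}. The (success,
fail) projection of that vector is the headline summary: the probability
that a chain started at A0 runs to completion versus terminating early.

Convention: the state vector is a column distribution over labels
[A0..Ak, FAIL]; propagation is A_{t+1} = P' A_t with P row-stochastic
(rows = from-state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, stdev

import numpy as np

from .chains import ChainObservation
from .errors import ConvergenceError

FAIL = "FAIL"


def state_labels(k: int) -> list[str]:
    """Labels for a k-post-initial-state chain: A0..Ak plus FAIL."""
    return [f"A{i}" for i in range(k + 1)] + [FAIL]


@dataclass
class TransitionModel:
    """Counts and row-stochastic probabilities over A0..Ak + FAIL.

    ``counts[i, j]`` is the number of observed i -> j transitions; rows are
    from-states. The last index is FAIL; index k is the terminal state.
    """

    counts: np.ndarray
    probs: np.ndarray
    initial_behaviour: str = ""

    @property
    def n_states(self) -> int:
        """k: index of the terminal chain state."""
        return self.counts.shape[0] - 2

    @property
    def labels(self) -> list[str]:
        return state_labels(self.n_states)

    @property
    def terminal_index(self) -> int:
        return self.n_states

    @property
    def fail_index(self) -> int:
        return self.counts.shape[0] - 1


@dataclass
class StateVector:
    """A probability distribution over the model's states at step t."""

    entries: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if np.any(self.entries < -1e-12):
            raise ValueError("state vector entries must be non-negative")
        if abs(self.entries.sum() - 1.0) > 1e-9:
            raise ValueError(f"state vector must sum to 1, got {self.entries.sum()}")

    def projection(self, model: TransitionModel) -> tuple[float, float]:
        """(success, fail) mass: terminal-state entry and everything else."""
        s = float(self.entries[model.terminal_index])
        return s, float(1.0 - s)


@dataclass
class SuccessSummary:
    """Per-initial-behaviour success summary across replicate blocks."""

    initial_behaviour: str
    success_probability: float
    fail_probability: float
    per_block_scores: list[float] = field(default_factory=list)
    n_chains: int = 0

    @property
    def mean(self) -> float | None:
        return mean(self.per_block_scores) if self.per_block_scores else None

    @property
    def sd(self) -> float:
        return stdev(self.per_block_scores) if len(self.per_block_scores) > 1 else 0.0

    @property
    def empty(self) -> bool:
        return not self.per_block_scores


def count_transitions(chains: list[ChainObservation], k: int) -> np.ndarray:
    """Tally a_ij over a set of chains into a (k+2) x (k+2) matrix.

    Every recorded forward step increments one cell; every non-completed
    chain additionally increments (furthest state -> FAIL). Completed chains
    contribute nothing beyond their final forward step.
    """
    n = k + 2
    counts = np.zeros((n, n), dtype=np.int64)
    for ch in chains:
        if ch.furthest_state_index > k:
            raise ValueError(f"chain reaches state {ch.furthest_state_index} > k={k}")
        for i, j, _gap in ch.transitions:
            counts[i, j] += 1
        if not ch.completed:
            counts[ch.furthest_state_index, n - 1] += 1
    return counts


def estimate_probabilities(counts: np.ndarray, initial_behaviour: str = "") -> TransitionModel:
    """Row-normalise counts into a stochastic transition matrix.

    Rows with positive totals become observed transition fractions. The
    terminal and FAIL rows are absorbing (self-probability 1). A
    non-absorbing row with no observations cannot advance, so it is sent to
    FAIL with probability 1 — this keeps the matrix stochastic.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("transition counts must be non-negative")
    n = counts.shape[0]
    k = n - 2
    probs = np.zeros((n, n), dtype=float)
    for i in range(n):
        if i >= k:  # terminal (index k) and FAIL (index k+1) are absorbing
            probs[i, i] = 1.0
            continue
        total = counts[i].sum()
        if total > 0:
            probs[i] = counts[i] / total
        else:
            probs[i, n - 1] = 1.0
    return TransitionModel(counts=np.array(counts, dtype=np.int64), probs=probs,
                           initial_behaviour=initial_behaviour)


def initial_vector(model: TransitionModel) -> StateVector:
    """All probability mass on A0 — a chain starts at the initial act."""
    v = np.zeros(model.probs.shape[0])
    v[0] = 1.0
    return StateVector(entries=v, step_index=0)


def propagate(model: TransitionModel, start: StateVector, t: int) -> StateVector:
    """Distribution after t steps: A_t = (P')^t A_0. Mass is conserved."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if start.entries.shape[0] != model.probs.shape[0]:
        raise ValueError("state vector dimension does not match model")
    v = start.entries.copy()
    for _ in range(t):
        v = model.probs.T @ v
    return StateVector(entries=v, step_index=start.step_index + t)


def steady_state(model: TransitionModel, tol: float = 1e-10, max_iter: int = 10_000
                 ) -> tuple[StateVector, int]:
    """Iterate A_{t+1} = P'A_t from A0 until the vector stops changing.

    Returns (v, step at convergence) with max-norm ||P'v - v|| < tol. For
    absorbing forward chains convergence is geometric and reached within k
    steps exactly; the iteration cap is a guard only.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    v = initial_vector(model).entries
    for step in range(1, max_iter + 1):
        nxt = model.probs.T @ v
        if np.max(np.abs(nxt - v)) < tol:
            return StateVector(entries=nxt, step_index=step), step
        v = nxt
    raise ConvergenceError(f"no steady state within {max_iter} iterations (tol={tol})")


def success_probability(model: TransitionModel) -> tuple[float, float]:
    """Absorption probabilities (success, fail) for a chain started at A0.

    Computed from the steady state of the absorbing chain; success is the
    mass on the terminal state, fail is its complement.
    """
    v, _ = steady_state(model, tol=1e-13)
    s, f = v.projection(model)
    return s, f


def success_scores(chains: list[ChainObservation], k: int,
                   block_key=lambda ch: ch.session_id) -> dict[str, SuccessSummary]:
    """Per-initial-behaviour success scores across replicate blocks.

    The per-block score is the mean completion fraction of the block's
    chains (a chain failing immediately scores 0, a completed chain 1); the
    summary reports mean +/- sd across blocks, with sd = 0 for a single
    block. Initial behaviours with no chains yield an empty-marked summary.
    The block unit defaults to the observation session.
    """
    by_behaviour: dict[str, dict[str, list[ChainObservation]]] = {}
    for ch in chains:
        by_behaviour.setdefault(ch.initial_behaviour, {}).setdefault(block_key(ch), []).append(ch)
    out: dict[str, SuccessSummary] = {}
    for beh, blocks in sorted(by_behaviour.items()):
        scores = [mean([c.completion_fraction for c in blk]) for _, blk in sorted(blocks.items())]
        model = estimate_probabilities(count_transitions(sum(blocks.values(), []), k), beh)
        s, f = success_probability(model)
        out[beh] = SuccessSummary(
            initial_behaviour=beh, success_probability=s, fail_probability=f,
            per_block_scores=scores, n_chains=sum(len(b) for b in blocks.values()),
        )
    return out


def fit_models(chains: list[ChainObservation], k: int) -> dict[str, TransitionModel]:
    """One transition model per initial behaviour."""
    grouped: dict[str, list[ChainObservation]] = {}
    for ch in chains:
        grouped.setdefault(ch.initial_behaviour, []).append(ch)
    return {beh: estimate_probabilities(count_transitions(chs, k), beh)
            for beh, chs in sorted(grouped.items())}
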