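"""Markov model: counting, normalisation, propagation, absorption, scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethochain import (ChainObservation, count_transitions, estimate_probabilities,
                       initial_vector, propagate, steady_state, success_probability,
                       success_scores)
from ethochain.markov import StateVector


def _chain(transitions, furthest, k=3, session="s1", beh="Nobj"):
    return ChainObservation(session_id=session, initial_behaviour=beh, initial_actor="a",
                            start_time_s=0.0, transitions=[(i, j, 1.0) for i, j in transitions],
                            furthest_state_index=furthest, n_states=k)


def random_forward_model(rng, k):
    """Random forward-only chain model over A0..Ak + FAIL."""
    n = k + 2
    counts = np.zeros((n, n), dtype=int)
    for i in range(k):
        counts[i, i + 1:k + 1] = rng.integers(0, 20, k - i)
        counts[i, n - 1] = rng.integers(0, 20)
    return estimate_probabilities(counts)


def enumerated_success(model):
    """Independent oracle: sum of probability products over every strictly
    increasing path from A0 to the terminal state."""
    k = model.terminal_index
    P = model.probs

    def walk(i, p):
        if i == k:
            return p
        return sum(walk(j, p * P[i, j]) for j in range(i + 1, k + 1) if P[i, j] > 0)

    return walk(0, 1.0)


# --- count_transitions -------------------------------------------------------

def test_completed_chain_counts_each_forward_step_once():
    counts = count_transitions([_chain([(0, 1), (1, 2), (2, 3)], 3)], k=3)
    assert counts[0, 1] == counts[1, 2] == counts[2, 3] == 1
    assert counts.sum() == 3  # nothing beyond the last forward step


def test_failed_chain_adds_fail_transition():
    counts = count_transitions([_chain([(0, 1)], 1)], k=3)
    assert counts[0, 1] == 1 and counts[1, 4] == 1
    assert counts.sum() == 2


def test_counts_conserve_simulated_state_visits():
    from ethochain import SimulationConfig, extract_chains, simulate_event_log

    log, truth = simulate_event_log(SimulationConfig(seed=11))
    chains = extract_chains(log)
    counts = count_transitions(chains, k=5)
    # every chain contributes exactly one outgoing transition per visited state
    outgoing = counts.sum()
    per_chain = sum(len(c.transitions) + (0 if c.completed else 1) for c in chains)
    assert outgoing == per_chain
    # chains entering each state = transitions into it
    for j in range(1, 6):
        entered = sum(1 for c in chains if any(t[1] == j for t in c.transitions))
        assert counts[:, j].sum() == entered


# --- estimate_probabilities --------------------------------------------------

def test_row_normalisation_forced_by_counts():
    counts = np.zeros((5, 5), dtype=int)
    counts[0] = [0, 2, 1, 1, 0]
    model = estimate_probabilities(counts)
    assert np.allclose(model.probs[0], [0, 0.5, 0.25, 0.25, 0])


def test_zero_count_row_maps_to_fail():
    counts = np.zeros((5, 5), dtype=int)  # k = 3; A2 never observed
    counts[0, 1] = 1
    model = estimate_probabilities(counts)
    assert model.probs[2, model.fail_index] == 1.0


def test_absorbing_rows_are_self_loops():
    model = estimate_probabilities(np.zeros((5, 5), dtype=int))
    assert model.probs[3, 3] == 1.0 and model.probs[4, 4] == 1.0


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        estimate_probabilities(np.array([[0, -1], [0, 0]]))


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 10_000))
def test_rows_sum_to_one_for_random_count_matrices(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 7))
    counts = rng.integers(0, 50, (k + 2, k + 2))
    model = estimate_probabilities(counts)
    assert np.allclose(model.probs.sum(axis=1), 1.0, atol=1e-12)


# --- propagate / steady state ------------------------------------------------

def test_propagate_identity_model_fixes_any_start():
    model = estimate_probabilities(np.zeros((4, 4), dtype=int))
    model.probs[:] = np.eye(4)
    start = StateVector(entries=np.array([0.4, 0.3, 0.2, 0.1]))
    out = propagate(model, start, 5)
    assert np.allclose(out.entries, start.entries)


def test_propagate_single_step_moves_mass_forward():
    counts = np.zeros((4, 4), dtype=int)
    counts[0, 1] = 7
    model = estimate_probabilities(counts)
    out = propagate(model, initial_vector(model), 1)
    assert out.entries[1] == pytest.approx(1.0)


def test_propagate_conserves_mass_and_absorption_is_monotone():
    rng = np.random.default_rng(3)
    model = random_forward_model(rng, 5)
    v = initial_vector(model)
    absorbed = 0.0
    for _ in range(10):
        v = propagate(model, v, 1)
        assert abs(v.entries.sum() - 1.0) < 1e-12
        now = v.entries[model.terminal_index] + v.entries[model.fail_index]
        assert now >= absorbed - 1e-12
        absorbed = now


def test_step7_equals_step24_after_convergence():
    """Forward chains absorb completely, so late steps agree exactly."""
    rng = np.random.default_rng(17)
    for _ in range(20):
        model = random_forward_model(rng, 5)
        v7 = propagate(model, initial_vector(model), 7)
        v24 = propagate(model, initial_vector(model), 24)
        assert np.allclose(v7.entries, v24.entries, atol=1e-9)


def test_steady_state_satisfies_fixed_point():
    rng = np.random.default_rng(23)
    model = random_forward_model(rng, 5)
    v, step = steady_state(model, tol=1e-12)
    assert np.max(np.abs(model.probs.T @ v.entries - v.entries)) < 1e-12
    assert step <= 10


def test_steady_state_idempotent_under_propagation():
    rng = np.random.default_rng(29)
    model = random_forward_model(rng, 4)
    v, _ = steady_state(model)
    for t in (1, 3, 11):
        assert np.allclose(propagate(model, v, t).entries, v.entries, atol=1e-12)


def test_all_mass_absorbed_at_steady_state():
    rng = np.random.default_rng(31)
    model = random_forward_model(rng, 6)
    v, _ = steady_state(model)
    assert v.entries[model.terminal_index] + v.entries[model.fail_index] == pytest.approx(1.0)


def test_immediate_failure_gives_pure_fail_steady_state():
    counts = np.zeros((4, 4), dtype=int)
    counts[0, 3] = 5  # A0 -> FAIL only
    model = estimate_probabilities(counts)
    v, _ = steady_state(model)
    assert v.entries[model.fail_index] == pytest.approx(1.0)


# --- success probability -----------------------------------------------------

def test_success_one_when_all_forward_probabilities_one():
    counts = np.zeros((5, 5), dtype=int)
    for i in range(3):
        counts[i, i + 1] = 4
    s, f = success_probability(estimate_probabilities(counts))
    assert s == pytest.approx(1.0) and f == pytest.approx(0.0)


def test_success_zero_when_initial_fails():
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 4] = 2
    s, f = success_probability(estimate_probabilities(counts))
    assert s == 0.0 and f == 1.0


def test_success_equals_path_enumeration_on_known_model():
    rng = np.random.default_rng(101)
    model = random_forward_model(rng, 4)
    s, _ = success_probability(model)
    assert s == pytest.approx(enumerated_success(model), abs=1e-12)


# --- success scores ----------------------------------------------------------

def test_all_completed_block_scores_one():
    chains = [_chain([(0, 1), (1, 2), (2, 3)], 3) for _ in range(4)]
    summary = success_scores(chains, k=3)["Nobj"]
    assert summary.mean == pytest.approx(1.0) and summary.sd == 0.0


def test_all_immediate_failures_score_zero():
    chains = [_chain([], 0) for _ in range(4)]
    summary = success_scores(chains, k=3)["Nobj"]
    assert summary.mean == 0.0 and summary.sd == 0.0


def test_scores_average_completion_fraction_per_session():
    chains = [_chain([(0, 1), (1, 2), (2, 3)], 3, session="s1"),
              _chain([], 0, session="s1"),
              _chain([(0, 2)], 2, session="s2")]
    summary = success_scores(chains, k=3)["Nobj"]
    assert summary.per_block_scores == [pytest.approx(0.5), pytest.approx(2 / 3)]


def test_empty_group_is_marked_not_raised():
    assert success_scores([], k=3) == {}


def test_success_score_recovery_from_simulated_blocks():
    """Blocks drawn with a known 0.6 per-step success structure recover the
    ground-truth mean completion within 0.05 at 50 blocks x 20 chains."""
    rng = np.random.default_rng(77)
    k = 3
    advance = 0.6 ** (1 / k)  # overall completion 0.6
    chains = []
    true_fractions = []
    for block in range(50):
        for _ in range(20):
            state = 0
            while state < k and rng.uniform() < advance:
                state += 1
            chains.append(_chain([(i, i + 1) for i in range(state)], state,
                                 session=f"b{block:02d}"))
            true_fractions.append(state / k)
    summary = success_scores(chains, k=k)["Nobj"]
    assert abs(summary.mean - np.mean(true_fractions)) < 1e-12
    assert abs(summary.mean - (advance + advance**2 + advance**3) / 3) < 0.05
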