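"""Chain extraction: adjacency rule, skips, overlap handling, invariants."""

import pytest

from ethochain import (ChainDefinition, SimulationConfig, combine_states,
                       event_log_from_rows, extract_chains, frequency_table,
                       simulate_event_log)
from ethochain.chains import ChainState
from ethochain.errors import ValidationError
from ethochain.simulate import ChainTruth, IndividualSpec


def test_full_sequence_within_gaps_completes(full_chain_log, chain_def):
    (obs,) = extract_chains(full_chain_log, chain_def)
    assert obs.completed and obs.completion_fraction == 1.0
    assert obs.initial_behaviour == "Nobj" and obs.initial_actor == "EU1"
    assert [(i, j) for i, j, _ in obs.transitions] == [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]


def test_gap_at_or_above_threshold_fails_chain(chain_def):
    log = event_log_from_rows([
        ("s1", 0.0, "a", "Nobj"), ("s1", 5.0, "b", "GrpFrmt"), ("s1", 25.0, "c", "Greet")])
    (obs,) = extract_chains(log, chain_def)
    assert not obs.completed
    assert obs.furthest_state_index == 1  # stalls at group formation


def test_gap_of_exactly_threshold_fails():
    """The adjacency rule is strict: a 15.0 s gap does not count."""
    log = event_log_from_rows([("s1", 0.0, "a", "Nobj"), ("s1", 15.0, "b", "GrpFrmt")])
    (obs,) = extract_chains(log)
    assert obs.furthest_state_index == 0


def test_skips_allowed_forward_progression(chain_def):
    log = event_log_from_rows([
        ("s1", 0.0, "a", "Nobj"), ("s1", 10.0, "b", "Greet"), ("s1", 18.0, "c", "LeaveTgh")])
    (obs,) = extract_chains(log, chain_def)
    assert obs.completed
    assert [(i, j) for i, j, _ in obs.transitions] == [(0, 2), (2, 5)]


def test_backward_state_closes_chain():
    log = event_log_from_rows([
        ("s1", 0.0, "a", "Nobj"), ("s1", 5.0, "b", "Greet"), ("s1", 9.0, "c", "GrpFrmt")])
    (obs,) = extract_chains(log)
    assert not obs.completed and obs.furthest_state_index == 2


def test_new_initial_closes_open_chain():
    log = event_log_from_rows([
        ("s1", 0.0, "a", "Nobj"), ("s1", 5.0, "b", "GrpFrmt"),
        ("s1", 10.0, "c", "Run"), ("s1", 14.0, "d", "GrpFrmt")])
    obs = extract_chains(log)
    assert len(obs) == 2
    assert obs[0].initial_behaviour == "Nobj" and obs[0].furthest_state_index == 1
    assert obs[1].initial_behaviour == "Run" and obs[1].furthest_state_index == 1


def test_distractors_do_not_break_or_advance():
    log = event_log_from_rows([
        ("s1", 0.0, "a", "Nobj"), ("s1", 4.0, "b", "Rest"), ("s1", 8.0, "c", "Explore"),
        ("s1", 12.0, "d", "GrpFrmt")])
    (obs,) = extract_chains(log)
    assert obs.furthest_state_index == 1
    assert obs.transitions[0][2] == pytest.approx(12.0)  # timer ran across distractors


def test_session_end_closes_chain_as_failed():
    log = event_log_from_rows([("s1", 0.0, "a", "Nobj"), ("s1", 5.0, "b", "GrpFrmt")])
    (obs,) = extract_chains(log)
    assert not obs.completed and obs.furthest_state_index == 1


def test_definition_validation():
    with pytest.raises(ValidationError):
        ChainDefinition(states=())
    with pytest.raises(ValidationError):
        ChainDefinition(gap_threshold_s=0)
    with pytest.raises(ValidationError):
        ChainDefinition(states=(ChainState("a", ("X",)), ChainState("b", ("X",))))


def test_extraction_is_deterministic(sim_config):
    log, _ = simulate_event_log(sim_config)
    a = extract_chains(log)
    b = extract_chains(log)
    assert a == b


def test_forward_only_and_gap_bound_on_simulated_data(sim_config, chain_def):
    log, _ = simulate_event_log(sim_config)
    for obs in extract_chains(log, chain_def):
        idx = [0] + [j for _, j, _ in obs.transitions]
        assert all(a < b for a, b in zip(idx, idx[1:]))
        assert all(g < chain_def.gap_threshold_s for _, _, g in obs.transitions)


def test_recovers_simulator_ground_truth_exactly():
    """With zero distractors and deterministic advances every simulated chain
    is recovered, and completions match the generator's bookkeeping."""
    cfg = SimulationConfig(
        seed=5, distractor_rate=0.0,
        chain_truth={b: ChainTruth(advance=[1.0] * 5) for b in ("Nobj", "Run", "Forage")})
    log, truth = simulate_event_log(cfg)
    obs = extract_chains(log)
    assert len(obs) == truth.chain_count()
    assert all(o.completed for o in obs)
    assert sum(o.completed for o in obs) == truth.chain_count(completed=True)


def test_recovered_outcomes_match_truth_with_distractors(sim_config):
    log, truth = simulate_event_log(sim_config)
    obs = extract_chains(log)
    assert len(obs) == truth.chain_count()
    got = sorted((o.session_id, o.initial_behaviour, o.furthest_state_index) for o in obs)
    expected = sorted((r.session_id, r.initial_behaviour, r.furthest_state_index)
                      for r in truth.chain_records)
    assert got == expected


# --- combined states ---------------------------------------------------------

def _chains_with_counts(counts):
    """Build minimal observations whose per-state transition tallies are given."""
    from ethochain import ChainObservation

    out = []
    for to_idx, n in counts.items():
        for _ in range(n):
            out.append(ChainObservation(
                session_id="s", initial_behaviour="Nobj", initial_actor="a",
                start_time_s=0.0, transitions=[(to_idx - 1, to_idx, 1.0)],
                furthest_state_index=to_idx, n_states=5))
    return out


def test_equal_frequency_same_category_states_merge(ethogram):
    cd = ChainDefinition(states=(
        ChainState("GrpFrmt", ("GrpFrmt",)),
        ChainState("LickSn", ("LickSn",)),
        ChainState("ExpBelly", ("ExpBelly",)),
        ChainState("LeaveTgh", ("LeaveTgh",)),
    ))
    chains = _chains_with_counts({1: 9, 2: 7, 3: 7, 4: 5})
    merged = combine_states(chains, cd, ethogram)
    assert len(merged.states) == 3
    assert merged.states[1].codes == ("LickSn", "ExpBelly")  # both submissive, both 7


def test_unequal_frequency_states_do_not_merge(ethogram):
    cd = ChainDefinition(states=(
        ChainState("LickSn", ("LickSn",)), ChainState("ExpBelly", ("ExpBelly",))))
    merged = combine_states(_chains_with_counts({1: 7, 2: 9}), cd, ethogram)
    assert len(merged.states) == 2


def test_equal_frequency_different_category_states_do_not_merge(ethogram):
    cd = ChainDefinition(states=(
        ChainState("Greet", ("Greet",)), ChainState("LickSn", ("LickSn",))))
    merged = combine_states(_chains_with_counts({1: 7, 2: 7}), cd, ethogram)
    assert len(merged.states) == 2


# --- frequency table ---------------------------------------------------------

def test_frequency_table_includes_zero_individuals():
    log = event_log_from_rows([
        ("s1", 0.0, "EU2", "Nobj"), ("s1", 5.0, "EU2", "Nobj"),
        ("s1", 9.0, "EU2", "Nobj"), ("s1", 12.0, "EU1", "Rest")])
    assert frequency_table(log, "Nobj") == {"EU1": 0, "EU2": 3}


def test_frequency_table_empty_log():
    from ethochain import EventLog
    assert frequency_table(EventLog([]), "Nobj") == {}


def test_frequency_table_unknown_grouping_key(full_chain_log):
    with pytest.raises(ValueError):
        frequency_table(full_chain_log, "Nobj", by="enclosure")


def test_frequency_table_poisson_mean_recovery():
    """Per-individual counts from a Poisson(5) generator average ~5 at n=200."""
    import numpy as np

    from ethochain import BehaviouralEvent, EventLog

    rng = np.random.default_rng(42)
    events = []
    for i in range(200):
        ind = f"w{i:03d}"
        events.append(BehaviouralEvent("s1", 0.0, ind, "Rest"))  # ensure presence
        for n in range(rng.poisson(5)):
            events.append(BehaviouralEvent("s1", float(n + 1), ind, "Nobj"))
    table = frequency_table(EventLog(events), "Nobj")
    assert len(table) == 200
    assert abs(np.mean(list(table.values())) - 5.0) < 0.5
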