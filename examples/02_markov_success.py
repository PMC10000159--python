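"""Fit first-order Markov chain models of chain progression.

Per initial behaviour: transition counts -> row-normalised probabilities
(p_ij = a_ij / sum_j a_ij), steady-state propagation, and the (success,
fail) absorption projection — the probability that a started chain runs to
completion versus terminating early.
"""

from ethochain import (SimulationConfig, extract_chains, fit_models, initial_vector,
                       propagate, simulate_event_log, steady_state, success_scores)

log, truth = simulate_event_log(SimulationConfig(seed=1))
chains = extract_chains(log)
models = fit_models(chains, k=5)
summaries = success_scores(chains, k=5)

for beh, model in models.items():
    v7 = propagate(model, initial_vector(model), 7).projection(model)
    vs, step = steady_state(model)
    s, f = vs.projection(model)
    smry = summaries[beh]
    print(f"{beh}: steady state [success, fail] = [{s:.2f}, {f:.2f}] "
          f"(converged at step {step}; step-7 projection [{v7[0]:.2f}, {v7[1]:.2f}])")
    print(f"       success score {smry.mean:.2f} +/- {smry.sd:.2f} "
          f"across {len(smry.per_block_scores)} sessions, "
          f"true completion prob {truth.true_success[beh]:.2f}")
# The steady-state success is the absorption probability of the terminal
# state; the success score is the mean completion fraction per session —
# two related but distinct summaries of how far chains get.
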