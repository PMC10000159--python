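# ethochain

Quantitative ethology toolkit for **social-reward behavioural chains**:
sequences of prosocial behaviours that group-living animals direct at a
group member right after it performs a potentially group-beneficial act.
The motivating system is captive grey wolves: after one wolf interacts with
a novel object (a bold act), the rest of the group may form up, greet it,
show submissive gestures, and finally leave the site as a united group.
`ethochain` is for behavioural ecologists who have timestamped event logs
from all-occurrence sampling and want to quantify how often, and how far,
such chains unfold after different initial behaviours — and how that relates
to dominance and personality.

## What it computes

**Chain extraction.** A chain starts at an *initial behaviour* (novel-object
interaction `Nobj`, `Run`, or `Forage`) and advances through the ordered
states *group formation → greeting → snout licking → combined submissive
behaviours → leaving together* whenever the next chain-relevant event maps
to a strictly later state within 15 s (strict `<`; skips allowed, backward
transitions end the chain).

**Markov modelling.** Per initial behaviour, transition counts a_ij over
states A0…Ak plus an absorbing FAIL state are normalised to

  p_ij = a_ij / Σ_j a_ij,

giving a forward-only absorbing first-order Markov chain. The state vector
is propagated, A_{t+1} = P·A_t, until the steady state v = P·v; the mass on
the terminal state is the chain's **success probability** (completion), its
complement the failure probability. A per-session **success score** (mean
completion fraction) summarises the same data non-parametrically.

**Dominance.** David's Score from dyadic win proportions,
DS = w + w2 − l − l2, bounded by ±3 in triads.

**Personality.** Questionnaire subscales (curiosity/openness, playfulness,
…) scored as 100 · Σratings / (n_items · scale_max) after reverse-scoring
negatively phrased items.

**Statistics.** Kruskal–Wallis across initial behaviours, Dunn's pairwise z
tests with Bonferroni adjustment, Wilcoxon rank-sum, Welch/pooled t,
Kolmogorov–Smirnov normality screen, Pearson correlation matrices and
simple linear regression.

**Synthetic data.** A generator with known ground truth (latent boldness
driving novel-object rates, per-state chain progression laws, gap
distributions straddling the 15 s rule, dyadic dominance, questionnaire
noise) makes every stage testable end to end without field data.

## Worked example

```python
from ethochain import (SimulationConfig, extract_chains, fit_models,
                       simulate_event_log, steady_state, success_scores)

log, truth = simulate_event_log(SimulationConfig(seed=1))
chains = extract_chains(log)
models = fit_models(chains, k=5)
for beh, model in models.items():
    v, step = steady_state(model)
    s, f = v.projection(model)
    print(beh, f"[{s:.2f}, {f:.2f}] after {step} steps")
```

prints

```
Forage [0.00, 1.00] after 4 steps
Nobj [0.54, 0.46] after 6 steps
Run [0.05, 0.95] after 6 steps
```

i.e. on this simulated study a chain started by a novel-object interaction
runs to completion 54 % of the time (the generator's true completion
probability is 0.56), whereas chains after running or foraging almost
always terminate early — the pattern the package is designed to detect.
The scripts in `examples/` walk through each capability (simulation and
extraction, Markov fitting, dominance, personality + statistics, and the
one-call pipeline).

A thin CLI mirrors the library:

```bash
ethochain run --simulate --seed 7 --outdir out/   # full deterministic run
ethochain dominance --matrix sociomatrix.csv
ethochain chains extract --log events.csv --out chains.csv
```

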