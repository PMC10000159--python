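# Methods

## The model

A social-reward chain is an ordered template of behavioural states: an
initial act A0 (novel-object interaction, run, or forage) followed by k = 5
group-level states — group formation (A1), greeting (A2), snout licking
(A3), combined submissive behaviours (A4), leaving together (A5, the
terminal state). A realised chain advances whenever the next chain-relevant
event in the session maps to a strictly later state and its onset follows
the previous accepted event's onset by strictly less than the adjacency
threshold (default 15 s). States may be skipped; a backward or repeated
state, a gap at or above the threshold, the end of the session, or a new
initial behaviour all close the chain at its current state. Events that are
neither chain-relevant nor initial acts (distractors) neither advance nor
break a chain, but the adjacency timer keeps running across them. Chains do
not overlap: a fresh initial act closes the open chain as failed and opens
a new one. Gaps are measured between event onsets because all-occurrence
logs carry a single time point per event.

Chain progression is modelled as a forward-only absorbing first-order
Markov chain over A0..A5 plus FAIL. Transition probabilities are observed
transition fractions, p_ij = a_ij / Σ_j a_ij, so each observed row sums
to 1. The terminal state and FAIL are absorbing; a non-absorbing state with
no observed outgoing transitions is sent to FAIL with probability 1, which
keeps the matrix stochastic without inventing progression. The state
distribution is propagated as A_{t+1} = P·A_t from all mass on A0; because
every non-absorbing transition moves strictly forward, all mass is absorbed
within k + 1 steps and the steady state v = P·v exists exactly. The
two-number summary reported everywhere is the (success, fail) projection:
the mass on the terminal state and its complement. The literature this
models sometimes prints the same projection as a two-entry vector; the
package maintains the full distribution internally and exposes the
projection, since a two-state vector cannot represent a six-node chain.

Two related but distinct summaries are reported and deliberately not forced
to agree: the steady-state success probability (an absorption probability
under the fitted first-order model) and the success score (the mean
completion fraction per replicate block, by default the observation
session, summarised as mean ± SD across blocks). The former is model-based,
the latter model-free; on real or simulated data they differ whenever chain
failures cluster by session or completion is partial.

## Dominance and personality

David's Score uses raw dyadic win proportions P_ij = wins_ij / n_ij with
DS = w + w2 − l − l2. The raw-proportion variant (not the sample-size
corrected D_ij) is used because the exact ±3 triad bound — the analytic
anchor of the acceptance checks — holds only for raw proportions.
Unobserved dyads contribute 0 to both directions and are flagged; no
interactions are imputed.

Questionnaire factors are scored as 100 · Σratings / (n_items · scale_max)
after mapping reverse-scored items through rating → scale_min + scale_max −
rating. The default scale is 1–6; the denominator uses the literal maximum
possible subscale score rather than the score range, so an all-minimum
respondent on a 1–6 scale scores 100/6, not 0. Two subscales ship with
items (curiosity/openness, 6 items, one reversed; playfulness, 3 items,
one reversed); the other factor names are placeholders requiring
user-supplied items.

## Statistics

All tests are two-sided. Success scores across initial behaviours are
compared with Kruskal–Wallis (tie-corrected H, chi-square p with k − 1 df)
followed by Dunn's pairwise z tests on pooled ranks with tie correction;
Bonferroni adjustment multiplies each pairwise p by the number of pairs
actually compared, capped at 1. Welch's t is the default for two-sample
mean comparisons (group spreads in this kind of data differ substantially);
the Kolmogorov–Smirnov screen tests against a normal with the sample's own
mean and sd. Correlation matrices use pairwise-complete Pearson r with
t-distributed p (df = n − 2); the simple regression reports R², adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2) and the slope's p. Reports round to 2
decimals; all computation is at full precision.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: 2 groups × 5
individuals observed over 24 sessions of 30 min (desk-scale, comparable to
a season of all-occurrence sampling yielding on the order of a hundred
chains). Each individual has a latent boldness in [0, 1]; boldness weights
the choice of actor for novel-object events, so per-individual novel-object
frequencies are monotone in boldness. Per initial behaviour a ground-truth
progression law gives per-state advance, skip and fail probabilities; the
defaults are calibrated so the overall completion probabilities are 0.56
(novel object), 0.08 (run) and 0.01 (forage) — the scale of contrast the
method is meant to resolve. Advance gaps are uniform(1, 12) s and failure
gaps uniform(20, 60) s, cleanly straddling the 15 s threshold so
threshold-sensitivity can be probed. Distractors are an independent Poisson
overlay (6 per session by default). Dyadic wins are binomial with win
probability logistic in the boldness difference (slope 5, 10 interactions
per dyad, within-group dyads only). Questionnaire items are noisy rounded
discretisations of latent factor percentages (means 43 and 32, sd 17, item
noise sd 0.6 rating points); the curiosity latent is a ρ = 0.7 blend with
boldness so the personality-boldness analysis has signal to recover.

Initial behaviours are placed sequentially, each chain realisation
occupying its own window with a guard before the session end, so realised
chains never interleave and are never truncated. This matches the observed
regime (one animal at a time approaching the apparatus) and makes every
ground-truth quantity exactly recoverable: the extractor finds precisely
the generator's chains and outcomes. What the generator does *not* emulate:
interleaved simultaneous chains, observer error (missed or mislabelled
events), non-stationary rates across a season, reciprocity or contagion in
dominance interactions, and rater bias in questionnaires. Passing tests
therefore demonstrate correctness of the computational pipeline under the
stated generative assumptions, not robustness of the field protocol.

A single root seed feeds per-stream child generators (events, dominance,
questionnaires, boldness) via hashed seed sequences, so stages are
individually reproducible and identical configurations produce
byte-identical output files.

## Numerical choices and edge cases

- Steady-state iteration: max-norm tolerance 1e-10, cap 10 000 iterations
  (absorbing forward chains converge in ≤ k + 1 steps; the cap is a guard).
- Strict inequality for the adjacency rule: a gap of exactly 15.0 s fails.
- Ties in event time keep file order (stable sort), making extraction
  deterministic.
- Equal-frequency/same-category state merging requires adjacency in the
  template and a single shared category over all member codes.
- Empty groups in success scoring return an explicit empty marker, not an
  exception; an empty event log produces a report with empty-chain markers.
- Degenerate statistical inputs (all-identical pooled samples,
  zero-variance KS input, constant regressor) are handled explicitly:
  H = 0/p = 1 where the test is vacuous, errors where the statistic is
  undefined.

## Problem sizes

The default test suite simulates 24-session studies (~90 chains, ~450
events) for end-to-end checks and a 900-session study (~2000 chains per
initial behaviour, ~28 000 events) for the parameter-recovery experiment;
oracle-equivalence checks enumerate all increasing paths on models of up to
7 states across 120 random instances. These sizes give sampling error
comfortably inside the recovery tolerances (0.05 on transition
probabilities, 0.03 on success probability) while the full suite runs in a
few seconds.

## Known limitations

- The engine supports chain templates of any length, but only the 5-state
  template ships with asserted state identities; a longer variant must be
  user-configured.
- Actor semantics are asymmetric by design: the initial act belongs to one
  individual, subsequent states are group-level (any actor counts).
  Analyses of *which* group member responds are out of scope.
- First-order only: progression depends on the current state alone. No
  higher-order dependence, no covariates on transition probabilities.
- The Dunn z test uses the normal approximation; exact small-sample
  permutation p-values are not provided.
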