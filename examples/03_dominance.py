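"""David's Score dominance indices from dyadic win/loss data.

A fully linear triad (A beats B and C always, B beats C always) pins the
scores at the analytic extremes +3 and -3; a simulated 5-wolf hierarchy
shows scores tracking the latent boldness ordering.
"""

import numpy as np

from ethochain import Sociomatrix, SimulationConfig, davids_score, rank_by_ds, simulate_sociomatrix
from ethochain.simulate import IndividualSpec

wins = np.zeros((3, 3), dtype=int)
wins[0, 1] = wins[0, 2] = wins[1, 2] = 5
ds = davids_score(Sociomatrix(["A", "B", "C"], wins))
print("linear triad:", {i: round(ds[i], 2) for i in "ABC"})  # {'A': 3.0, 'B': 0.0, 'C': -3.0}

ids = [f"w{i}" for i in range(5)]
cfg = SimulationConfig(
    seed=4,
    individuals=[IndividualSpec(i, "A", "F", 5.0) for i in ids],
    interactions_per_dyad=30,
)
m, truth = simulate_sociomatrix(cfg)
ds = davids_score(m)
print("simulated hierarchy (descending DS):")
for ind in rank_by_ds(ds):
    print(f"  {ind}: DS = {ds[ind]:+.2f}  (latent boldness {truth.boldness[ind]:.2f})")
# Higher latent boldness -> higher win probability per dyad -> higher DS.
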