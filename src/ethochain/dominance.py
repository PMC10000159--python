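"""David's Score: a cardinal dominance index from dyadic win/loss data.

For each ordered dyad (i, j) with at least one decided interaction the win
proportion is P_ij = wins_ij / (wins_ij + wins_ji); unobserved dyads
contribute 0 in both directions (no interactions are invented, and any
unobserved dyad is flagged). From the win proportions,

    w_i  = sum_j P_ij            (direct wins)
    w2_i = sum_j P_ij * w_j      (wins weighted by opponents' wins)
    l_i  = sum_j P_ji            (direct losses)
    l2_i = sum_j P_ji * l_j      (losses weighted by opponents' losses)

    DS_i = w_i + w2_i - l_i - l2_i.

Scores sum to zero over the group, and for a triad lie in [-3, 3]: a fully
linear triad (one individual winning every interaction, one losing every
interaction) pins the extremes at exactly +3 and -3. The raw win-proportion
variant is used, not the sample-size-corrected Dij variant, because the
triad bound holds exactly only for raw proportions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Sociomatrix:
    """Square matrix of dyadic wins: wins[i, j] = interactions i won over j."""

    individuals: list[str]
    wins: np.ndarray

    def __post_init__(self) -> None:
        self.wins = np.asarray(self.wins)
        n = len(self.individuals)
        if self.wins.shape != (n, n):
            raise ValueError(f"wins must be {n}x{n}, got {self.wins.shape}")
        if np.any(self.wins < 0):
            raise ValueError("win counts must be non-negative")
        if np.any(np.diag(self.wins) != 0):
            raise ValueError("diagonal of the sociomatrix must be zero")


@dataclass
class DavidsScores:
    """Per-individual components and final DS, plus the win proportions used."""

    individuals: list[str]
    P: np.ndarray
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    ds: np.ndarray
    unobserved_dyads: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, individual: str) -> float:
        return float(self.ds[self.individuals.index(individual)])

    def as_dict(self) -> dict[str, float]:
        return {ind: float(d) for ind, d in zip(self.individuals, self.ds)}


def davids_score(m: Sociomatrix) -> DavidsScores:
    """Compute David's Scores from a sociomatrix (>= 2 individuals)."""
    n = len(m.individuals)
    if n < 2:
        raise ValueError("David's Score needs at least 2 individuals")
    wins = m.wins.astype(float)
    totals = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(totals > 0, wins / np.where(totals > 0, totals, 1), 0.0)
    np.fill_diagonal(P, 0.0)
    unobserved = [
        (m.individuals[i], m.individuals[j])
        for i in range(n) for j in range(i + 1, n)
        if totals[i, j] == 0
    ]
    if unobserved:
        shown = ", ".join(f"{a}-{b}" for a, b in unobserved[:4])
        more = "" if len(unobserved) <= 4 else f", ... ({len(unobserved) - 4} more)"
        logger.warning("%d dyad(s) with no interactions contribute 0 to David's "
                       "Scores: %s%s", len(unobserved), shown, more)
    w = P.sum(axis=1)
    w2 = P @ w
    l = P.sum(axis=0)
    l2 = P.T @ l
    ds = w + w2 - l - l2
    return DavidsScores(individuals=list(m.individuals), P=P, w=w, w2=w2, l=l, l2=l2,
                        ds=ds, unobserved_dyads=unobserved)


def rank_by_ds(scores: DavidsScores) -> list[str]:
    """Individuals in descending DS order; ties broken by id."""
    return [ind for ind, _ in sorted(zip(scores.individuals, scores.ds),
                                     key=lambda t: (-t[1], t[0]))]


def read_sociomatrix(path: str | Path) -> Sociomatrix:
    """Read a square CSV sociomatrix with a header row and id column."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    ids = [c.strip() for c in rows[0][1:]]
    wins = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for r, row in enumerate(rows[1:]):
        if row[0].strip() != ids[r]:
            raise ValueError(f"{path}: row ids must match column ids ({row[0]!r} vs {ids[r]!r})")
        wins[r] = [int(float(v)) for v in row[1:]]
    return Sociomatrix(individuals=ids, wins=wins)


def write_sociomatrix(m: Sociomatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + m.individuals)
        for ind, row in zip(m.individuals, m.wins):
            writer.writerow([ind] + [int(v) for v in row])
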