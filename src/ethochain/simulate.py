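"""Synthetic study generator: event logs, sociomatrices and questionnaires
with known ground truth.

The generator emulates the structure of the observational study the
pipeline is built for: two captive wolf groups of five individuals observed
over repeated all-occurrence-sampling sessions. Each individual carries a
latent boldness in [0, 1] which multiplies its propensity to perform the
novel-object initial behaviour; after every initial act a social-reward
chain realisation is drawn from a per-initial-behaviour transition truth
(per-state advance/skip/fail probabilities), with inter-state gaps from a
mixture that straddles the 15 s adjacency rule (advance gaps uniform on
[1, 12] s, failure gaps on [20, 60] s). Distractor behaviours are
interleaved as an independent Poisson process. Dyadic dominance outcomes
are binomial with win probability increasing in the boldness difference,
and questionnaire items are noisy discretisations of latent factor scores,
with the curiosity latent correlated with boldness.

Initial behaviours are placed sequentially so that each chain realisation
occupies its own time window and realised chains never interleave; this
matches the observation that only one animal approached the apparatus at a
time, and makes every ground-truth quantity exactly recoverable by the
pipeline. All randomness flows from a single root seed through per-stream
child generators (events, dominance, questionnaires), so identical configs
and seeds give byte-identical output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .chains import DEFAULT_INITIAL_BEHAVIOURS, ChainDefinition
from .dominance import Sociomatrix
from .errors import ConfigurationError
from .event_io import BehaviouralEvent, EventLog
from .personality import DEFAULT_FACTORS, FactorDefinition, ResponseSet, reverse

#: Behaviours emitted as chain-irrelevant background activity.
DISTRACTOR_CODES = ("Rest", "Explore", "Amble", "Wander", "Orient", "SolPlay", "Cache")


@dataclass(frozen=True)
class IndividualSpec:
    individual_id: str
    group_id: str
    sex: str
    age: float


@dataclass
class ChainTruth:
    """Ground-truth progression law for one initial behaviour.

    From state s (0-based, k = number of post-initial states) the chain
    advances to s+1 with ``advance[s]``, skips to s+2 with ``skip[s]``
    (zero whenever s+2 > k), and otherwise fails. A failed step emits,
    half the time, a late next-state event beyond the adjacency threshold.
    """

    advance: list[float]
    skip: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.advance)
        if not self.skip:
            self.skip = [0.0] * k
        if len(self.skip) != k:
            raise ConfigurationError("skip must have one entry per state")
        for s, (a, sk) in enumerate(zip(self.advance, self.skip)):
            sk = sk if s + 2 <= k else 0.0
            if not (0 <= a <= 1 and 0 <= sk <= 1 and a + sk <= 1):
                raise ConfigurationError(f"invalid probabilities at state {s}: {a}, {sk}")

    @property
    def k(self) -> int:
        return len(self.advance)

    @classmethod
    def from_success(cls, success: float, k: int) -> "ChainTruth":
        """Uniform per-step advance probability giving the stated overall
        completion probability (no skips)."""
        if not 0 <= success <= 1:
            raise ConfigurationError("success must be a probability")
        return cls(advance=[success ** (1.0 / k)] * k)

    def transition_matrix(self) -> np.ndarray:
        """The true (k+2)x(k+2) row-stochastic matrix (last index = FAIL)."""
        k = self.k
        P = np.zeros((k + 2, k + 2))
        for s in range(k):
            a = self.advance[s]
            sk = self.skip[s] if s + 2 <= k else 0.0
            P[s, s + 1] = a
            if sk:
                P[s, s + 2] = sk
            P[s, k + 1] = 1.0 - a - sk
        P[k, k] = 1.0
        P[k + 1, k + 1] = 1.0
        return P

    def success_probability(self) -> float:
        """Exact completion probability under this truth."""
        k = self.k
        # forward dynamic program over reach probabilities
        reach = np.zeros(k + 1)
        reach[0] = 1.0
        for s in range(k):
            a = self.advance[s]
            sk = self.skip[s] if s + 2 <= k else 0.0
            reach[s + 1] += reach[s] * a
            if sk:
                reach[s + 2] += reach[s] * sk
        return float(reach[k])


def default_individuals() -> list[IndividualSpec]:
    """Two groups of five, desk-scale mirror of the study population."""
    specs = []
    ages_a = [3.0, 3.0, 8.0, 7.0, 4.0]
    ages_b = [10.0, 10.0, 10.0, 8.0, 10.0]
    sexes_a = ["F", "M", "F", "M", "F"]
    sexes_b = ["M", "M", "F", "M", "F"]
    for i in range(5):
        specs.append(IndividualSpec(f"EU{i+1}", "A", sexes_a[i], ages_a[i]))
    for i in range(5):
        specs.append(IndividualSpec(f"EUW{i+1}", "B", sexes_b[i], ages_b[i]))
    return specs


@dataclass
class SimulationConfig:
    """All knobs of the generator, with study-scale defaults."""

    seed: int = 0
    individuals: list[IndividualSpec] = field(default_factory=default_individuals)
    latent_boldness: dict[str, float] | None = None
    #: expected initial-behaviour events per session, before boldness weighting
    initial_rates: dict[str, float] = field(
        default_factory=lambda: {"Nobj": 1.5, "Run": 1.5, "Forage": 1.5})
    chain_truth: dict[str, ChainTruth] = field(
        default_factory=lambda: {
            "Nobj": ChainTruth.from_success(0.56, 5),
            "Run": ChainTruth.from_success(0.08, 5),
            "Forage": ChainTruth.from_success(0.01, 5),
        })
    advance_gap_s: tuple[float, float] = (1.0, 12.0)
    fail_gap_s: tuple[float, float] = (20.0, 60.0)
    late_event_probability: float = 0.5
    distractor_rate: float = 6.0  # expected distractor events per session
    n_sessions: int = 24
    session_duration_s: float = 1800.0
    chain_spacing_s: float = 90.0  # mean idle time between chain windows
    # dominance
    interactions_per_dyad: int = 10
    dominance_steepness: float = 5.0  # logistic slope on boldness difference
    within_group_dyads_only: bool = True
    # questionnaires
    factors: tuple[FactorDefinition, ...] = DEFAULT_FACTORS
    factor_percent_means: dict[str, float] = field(
        default_factory=lambda: {"curiosity/openness": 43.0, "playfulness": 32.0})
    factor_percent_sd: float = 17.0
    item_noise_sd: float = 0.6
    boldness_curiosity_rho: float = 0.7

    def __post_init__(self) -> None:
        for beh, p in [("late_event_probability", self.late_event_probability)]:
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{beh} must be in [0, 1]")
        for beh, r in self.initial_rates.items():
            if r < 0:
                raise ConfigurationError(f"rate for {beh!r} must be non-negative")
        if self.distractor_rate < 0:
            raise ConfigurationError("distractor_rate must be non-negative")

    def rng_for(self, stream: str, seed: int | None = None) -> np.random.Generator:
        root = self.seed if seed is None else seed
        ss = np.random.SeedSequence([root, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)

    def boldness(self, rng: np.random.Generator | None = None) -> dict[str, float]:
        if self.latent_boldness is not None:
            return dict(self.latent_boldness)
        rng = rng if rng is not None else self.rng_for("boldness")
        return {ind.individual_id: float(b)
                for ind, b in zip(self.individuals, rng.uniform(0.05, 0.95, len(self.individuals)))}


@dataclass
class ChainRecord:
    """Ground truth of one realised chain."""

    session_id: str
    initial_behaviour: str
    actor_id: str
    start_time_s: float
    furthest_state_index: int
    completed: bool


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline should recover."""

    boldness: dict[str, float] = field(default_factory=dict)
    chain_records: list[ChainRecord] = field(default_factory=list)
    true_matrices: dict[str, np.ndarray] = field(default_factory=dict)
    true_success: dict[str, float] = field(default_factory=dict)
    initial_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    win_probs: np.ndarray | None = None
    ds_order: list[str] = field(default_factory=list)
    factor_latents: dict[str, dict[str, float]] = field(default_factory=dict)

    def chain_count(self, behaviour: str | None = None, completed: bool | None = None) -> int:
        recs = self.chain_records
        if behaviour is not None:
            recs = [r for r in recs if r.initial_behaviour == behaviour]
        if completed is not None:
            recs = [r for r in recs if r.completed == completed]
        return len(recs)


# state codes emitted for template index 1..k (canonical code per state)
def _state_codes(chain_def: ChainDefinition) -> list[str]:
    return [st.codes[0] for st in chain_def.states]


def simulate_event_log(cfg: SimulationConfig, chain_def: ChainDefinition | None = None,
                       seed: int | None = None) -> tuple[EventLog, GroundTruth]:
    """Generate a full event log plus its ground truth.

    Sessions are filled with sequential chain windows: an initial act by a
    boldness-weighted (for novel-object) or uniform (otherwise) actor, then
    the drawn chain realisation, then idle spacing. Distractors are overlaid
    independently.
    """
    chain_def = chain_def or ChainDefinition()
    codes = _state_codes(chain_def)
    k = chain_def.n_states
    for beh, truth in cfg.chain_truth.items():
        if truth.k != k:
            raise ConfigurationError(
                f"chain truth for {beh!r} has {truth.k} states, template has {k}")
    rng = cfg.rng_for("events", seed)
    bold = cfg.boldness(cfg.rng_for("boldness", seed))
    inds = cfg.individuals
    by_group: dict[str, list[IndividualSpec]] = {}
    for ind in inds:
        by_group.setdefault(ind.group_id, []).append(ind)

    behaviours = [b for b in cfg.initial_rates if cfg.initial_rates[b] > 0]
    rate_total = sum(cfg.initial_rates[b] for b in behaviours)
    truth = GroundTruth(boldness=bold,
                        true_matrices={b: t.transition_matrix() for b, t in cfg.chain_truth.items()},
                        true_success={b: t.success_probability() for b, t in cfg.chain_truth.items()},
                        initial_counts={b: {i.individual_id: 0 for i in inds} for b in behaviours})
    events: list[BehaviouralEvent] = []
    group_ids = sorted(by_group)
    for s in range(cfg.n_sessions):
        session_id = f"S{s+1:03d}"
        group_id = group_ids[s % len(group_ids)]
        members = by_group[group_id]
        ids = [m.individual_id for m in members]
        # mean spacing chosen so the expected number of windows matches the rates
        mean_gap = max(cfg.chain_spacing_s, cfg.session_duration_s / max(rate_total, 1e-9))
        # reserve room for a full realisation so no chain is truncated by
        # the session boundary (truncation would bias transition estimates)
        guard = k * cfg.advance_gap_s[1] + cfg.fail_gap_s[1]
        t = float(rng.exponential(mean_gap))
        while t < cfg.session_duration_s - guard:
            beh = str(rng.choice(behaviours, p=[cfg.initial_rates[b] / rate_total for b in behaviours]))
            if beh == "Nobj":  # boldness drives novel-object propensity
                wts = np.array([bold[i] for i in ids])
                actor = str(rng.choice(ids, p=wts / wts.sum()))
            else:
                actor = str(rng.choice(ids))
            truth.initial_counts[beh][actor] += 1
            events.append(BehaviouralEvent(session_id, t, actor, beh, group_id))
            # draw the chain realisation
            law = cfg.chain_truth.get(beh)
            state, t_cur = 0, t
            responders = [i for i in ids if i != actor] or ids
            while law is not None and state < k:
                a = law.advance[state]
                sk = law.skip[state] if state + 2 <= k else 0.0
                u = rng.uniform()
                if u < a:
                    nxt = state + 1
                elif u < a + sk:
                    nxt = state + 2
                else:  # failure; maybe a late, out-of-window next event
                    if rng.uniform() < cfg.late_event_probability:
                        t_cur += rng.uniform(*cfg.fail_gap_s)
                        if t_cur < cfg.session_duration_s:
                            events.append(BehaviouralEvent(
                                session_id, t_cur, str(rng.choice(responders)),
                                codes[state], group_id))
                    break
                t_cur += rng.uniform(*cfg.advance_gap_s)
                if t_cur >= cfg.session_duration_s:
                    break  # session ends mid-chain; chain stays where it was
                events.append(BehaviouralEvent(
                    session_id, t_cur, str(rng.choice(responders)), codes[nxt - 1], group_id))
                state = nxt
            truth.chain_records.append(ChainRecord(
                session_id=session_id, initial_behaviour=beh, actor_id=actor,
                start_time_s=t, furthest_state_index=state, completed=state == k))
            t = t_cur + float(rng.exponential(mean_gap)) + cfg.chain_spacing_s
        # independent distractor overlay
        n_distr = rng.poisson(cfg.distractor_rate)
        for td in np.sort(rng.uniform(0, cfg.session_duration_s, n_distr)):
            events.append(BehaviouralEvent(
                session_id, float(td), str(rng.choice(ids)),
                str(rng.choice(DISTRACTOR_CODES)), group_id))
    return EventLog(events), truth


def simulate_sociomatrix(cfg: SimulationConfig, seed: int | None = None
                         ) -> tuple[Sociomatrix, GroundTruth]:
    """Binomial dyadic wins with win probability increasing in boldness.

    P(i beats j) is a logistic function of the boldness difference; dyads
    across groups are unobserved by default (captive groups do not meet).
    """
    rng = cfg.rng_for("dominance", seed)
    bold = cfg.boldness(cfg.rng_for("boldness", seed))
    ids = [ind.individual_id for ind in cfg.individuals]
    groups = {ind.individual_id: ind.group_id for ind in cfg.individuals}
    n = len(ids)
    wins = np.zeros((n, n), dtype=np.int64)
    win_probs = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            if cfg.within_group_dyads_only and groups[ids[i]] != groups[ids[j]]:
                continue
            p = 1.0 / (1.0 + np.exp(-cfg.dominance_steepness * (bold[ids[i]] - bold[ids[j]])))
            win_probs[i, j], win_probs[j, i] = p, 1 - p
            wij = rng.binomial(cfg.interactions_per_dyad, p)
            wins[i, j] = wij
            wins[j, i] = cfg.interactions_per_dyad - wij
    truth = GroundTruth(boldness=bold, win_probs=win_probs,
                        ds_order=sorted(ids, key=lambda x: -bold[x]))
    return Sociomatrix(individuals=ids, wins=wins), truth


def simulate_questionnaires(cfg: SimulationConfig, seed: int | None = None
                            ) -> tuple[list[ResponseSet], GroundTruth]:
    """Likert responses as noisy discretisations of latent factor scores.

    Each individual's latent factor score (percentage scale) is normal
    around the configured mean; the curiosity latent is a correlated blend
    with boldness. Item ratings are the latent mapped onto the rating
    scale plus noise, rounded and clipped; reverse-scored items are
    inverted at generation so that scoring recovers the latent.
    """
    rng = cfg.rng_for("questionnaires", seed)
    bold = cfg.boldness(cfg.rng_for("boldness", seed))
    ids = [ind.individual_id for ind in cfg.individuals]
    bvals = np.array([bold[i] for i in ids])
    bz = (bvals - bvals.mean()) / (bvals.std() or 1.0)
    truth = GroundTruth(boldness=bold)
    responses = [ResponseSet(i) for i in ids]
    for f in cfg.factors:
        mu = cfg.factor_percent_means.get(f.name, 40.0)
        noise = rng.normal(0.0, 1.0, len(ids))
        if f.name == "curiosity/openness" and len(ids) > 1:
            rho = cfg.boldness_curiosity_rho
            z = rho * bz + np.sqrt(max(0.0, 1 - rho**2)) * noise
        else:
            z = noise
        latent_pct = np.clip(mu + cfg.factor_percent_sd * z, 0.0, 100.0)
        truth.factor_latents[f.name] = {i: float(v) for i, v in zip(ids, latent_pct)}
        target = latent_pct / 100.0 * f.scale_max  # rating whose score is the latent
        for r, tgt in zip(responses, target):
            for item in f.items:
                raw = float(np.clip(np.round(tgt + rng.normal(0.0, cfg.item_noise_sd)),
                                    f.scale_min, f.scale_max))
                r.ratings[item.item_id] = (reverse(raw, f.scale_min, f.scale_max)
                                           if item.reverse_scored else raw)
    return responses, truth
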