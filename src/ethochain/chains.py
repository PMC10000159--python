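"""Social-reward chain extraction from event streams.

A chain starts at an *initial behaviour* (by default novel-object
interaction, run or forage) performed by one individual, and advances
through an ordered template of group-level states — group formation,
greeting, snout licking, combined submissive behaviours, leaving together —
whenever the next chain-relevant event maps to a strictly later state and
follows within the adjacency window (default: strictly less than 15 s
between event onsets). States may be skipped, but the chain is forward-only:
a backward or repeated state closes the chain as failed, as does a gap at or
above the threshold, the end of the session, or a new initial behaviour
(chains never overlap — a fresh initial act closes the open chain at its
current state and opens a new one).

Events that are neither chain-relevant nor initial behaviours (distractors)
neither advance nor break a chain, but the adjacency timer keeps running
across them.

State indexing convention: index 0 is the initial act (A0); the template's
states occupy indices 1..k in order, with index k the terminal/success
state. ``completion_fraction`` is ``furthest_state_index / k``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError, ValidationError
from .ethogram import Ethogram
from .event_io import BehaviouralEvent, EventLog

DEFAULT_GAP_THRESHOLD_S = 15.0

#: Template of the social-reward chain: five post-initial states.
DEFAULT_STATES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("GrpFrmt", ("GrpFrmt",)),
    ("Greet", ("Greet", "TailWag", "BodyRub", "SniffNose")),
    ("LickSn", ("LickSn",)),
    ("C.SubmBhv", ("C.SubmBhv", "ExpBelly", "LowPost", "DownLick")),
    ("LeaveTgh", ("LeaveTgh",)),
)

DEFAULT_INITIAL_BEHAVIOURS = ("Nobj", "Run", "Forage")


@dataclass(frozen=True)
class ChainState:
    """One slot of the chain template: a name and the codes that realise it."""

    name: str
    codes: tuple[str, ...]


@dataclass(frozen=True)
class CombinedState(ChainState):
    """Several equally frequent, same-category behaviours merged into one state."""

    rule: str = "equal-frequency-same-category"


@dataclass(frozen=True)
class ChainDefinition:
    """The ordered state template a chain is matched against."""

    initial_behaviours: frozenset[str] = frozenset(DEFAULT_INITIAL_BEHAVIOURS)
    states: tuple[ChainState, ...] = tuple(ChainState(n, c) for n, c in DEFAULT_STATES)
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S
    allow_skip: bool = True

    def __post_init__(self) -> None:
        if not self.states:
            raise ValidationError("chain definition needs at least one state")
        if self.gap_threshold_s <= 0:
            raise ValidationError("gap_threshold_s must be positive")
        seen: set[str] = set()
        for st in self.states:
            dup = seen.intersection(st.codes)
            if dup:
                raise ValidationError(f"code(s) {sorted(dup)} appear in more than one state")
            seen.update(st.codes)

    @property
    def n_states(self) -> int:
        """Number of post-initial states (terminal index)."""
        return len(self.states)

    def state_index(self, code: str) -> int | None:
        """1-based template index realised by ``code``, or None."""
        for i, st in enumerate(self.states, start=1):
            if code in st.codes:
                return i
        return None

    @property
    def state_labels(self) -> list[str]:
        """A0 plus the template state names (indices 0..k)."""
        return ["A0"] + [st.name for st in self.states]


@dataclass
class ChainObservation:
    """One extracted chain realisation.

    ``transitions`` holds (from_index, to_index, gap_s) for every accepted
    forward step; indices are strictly increasing and every gap is below the
    threshold. ``completed`` is true iff the terminal state was reached.
    """

    session_id: str
    initial_behaviour: str
    initial_actor: str
    start_time_s: float
    transitions: list[tuple[int, int, float]] = field(default_factory=list)
    furthest_state_index: int = 0
    n_states: int = len(DEFAULT_STATES)

    @property
    def completed(self) -> bool:
        return self.furthest_state_index == self.n_states

    @property
    def completion_fraction(self) -> float:
        return self.furthest_state_index / self.n_states


def load_chain_definition(text: str, *, source: str = "<config>") -> ChainDefinition:
    """Parse a YAML chain-definition config.

    Schema: ``initial_behaviours: [codes]``, ``states: [{name, codes}]``,
    optional ``gap_threshold_s`` and ``allow_skip``.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{source}: {exc}") from exc
    if not isinstance(doc, dict) or "states" not in doc:
        raise ConfigurationError(f"{source}: expected a mapping with a 'states' list")
    states = tuple(
        ChainState(name=str(s["name"]), codes=tuple(str(c).strip() for c in s["codes"]))
        for s in doc["states"]
    )
    return ChainDefinition(
        initial_behaviours=frozenset(str(c).strip() for c in doc.get("initial_behaviours", DEFAULT_INITIAL_BEHAVIOURS)),
        states=states,
        gap_threshold_s=float(doc.get("gap_threshold_s", DEFAULT_GAP_THRESHOLD_S)),
        allow_skip=bool(doc.get("allow_skip", True)),
    )


def load_chain_definition_file(path: str | Path) -> ChainDefinition:
    path = Path(path)
    return load_chain_definition(path.read_text(encoding="utf-8"), source=str(path))


def write_chain_definition(cd: ChainDefinition) -> str:
    doc = {
        "initial_behaviours": sorted(cd.initial_behaviours),
        "states": [{"name": s.name, "codes": list(s.codes)} for s in cd.states],
        "gap_threshold_s": cd.gap_threshold_s,
        "allow_skip": cd.allow_skip,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def extract_chains(log: EventLog, cd: ChainDefinition | None = None) -> list[ChainObservation]:
    """Detect every chain realisation in the log.

    One observation is produced per occurrence of an initial behaviour.
    Extraction is a single deterministic pass per session; re-running it on
    the same log yields an identical list.
    """
    cd = cd or ChainDefinition()
    chains: list[ChainObservation] = []
    for session_id, events in log.sessions():
        open_chain: ChainObservation | None = None
        last_time = 0.0  # onset time of the last accepted chain event
        for ev in events:
            is_initial = ev.behaviour_code in cd.initial_behaviours
            state_idx = cd.state_index(ev.behaviour_code)
            if is_initial:
                if open_chain is not None:
                    chains.append(open_chain)  # close as failed at current state
                open_chain = ChainObservation(
                    session_id=session_id,
                    initial_behaviour=ev.behaviour_code,
                    initial_actor=ev.actor_id,
                    start_time_s=ev.time_s,
                    n_states=cd.n_states,
                )
                last_time = ev.time_s
                continue
            if state_idx is None or open_chain is None:
                continue  # distractor, or orphan chain event: timer keeps running
            gap = ev.time_s - last_time
            cur = open_chain.furthest_state_index
            if gap >= cd.gap_threshold_s or state_idx <= cur:
                # late, backward or repeated: chain is over
                chains.append(open_chain)
                open_chain = None
                continue
            if not cd.allow_skip and state_idx != cur + 1:
                chains.append(open_chain)
                open_chain = None
                continue
            open_chain.transitions.append((cur, state_idx, gap))
            open_chain.furthest_state_index = state_idx
            last_time = ev.time_s
            if state_idx == cd.n_states:  # terminal reached
                chains.append(open_chain)
                open_chain = None
        if open_chain is not None:  # session ended with a chain open
            chains.append(open_chain)
    return chains


def combine_states(chains: list[ChainObservation], cd: ChainDefinition, eth: Ethogram) -> ChainDefinition:
    """Merge equally frequent, same-category adjacent template states.

    States whose realised occurrence counts are equal and whose member
    behaviours all fall in one behavioural category are collapsed into a
    single :class:`CombinedState`; the revised definition is returned.
    """
    if not chains:
        raise ValidationError("combine_states needs at least one chain")
    counts = Counter()
    for ch in chains:
        for _, to_idx, _ in ch.transitions:
            counts[to_idx] += 1
    new_states: list[ChainState] = []
    i = 0
    states = list(cd.states)
    while i < len(states):
        j = i + 1
        cats_i = {eth.category_of(c) for c in states[i].codes}
        run = [states[i]]
        while (
            j < len(states)
            and counts[j + 1] == counts[i + 1]
            and {eth.category_of(c) for c in states[j].codes} == cats_i
            and len(cats_i) == 1
        ):
            run.append(states[j])
            j += 1
        if len(run) > 1:
            merged_codes = tuple(c for st in run for c in st.codes)
            name = "C." + "+".join(st.name for st in run)
            new_states.append(CombinedState(name=name, codes=merged_codes))
        else:
            new_states.append(states[i])
        i = j
    return replace(cd, states=tuple(new_states))


def frequency_table(log: EventLog, behaviour: str, by: str = "actor_id") -> dict[str, int]:
    """Occurrences of one behaviour per individual (or per group).

    Individuals present anywhere in the log but never performing the
    behaviour are included with count 0.
    """
    if by not in ("actor_id", "group_id"):
        raise ValueError(f"unknown grouping key {by!r}; use 'actor_id' or 'group_id'")
    keys = sorted({getattr(e, by) for e in log})
    table = {k: 0 for k in keys}
    for e in log:
        if e.behaviour_code == behaviour:
            table[getattr(e, by)] += 1
    return table
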