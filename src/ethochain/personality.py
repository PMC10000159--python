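"""Questionnaire-based personality factors as percentage scores.

Keeper-rated questionnaire items (Likert ratings, default scale 1-6) are
grouped into factor subscales — curiosity/openness, playfulness,
extraversion, sociability, motivation, calmness/neuroticism, training
focus. Negatively phrased items are reverse-scored (rating -> scale_min +
scale_max - rating) before summing; the factor score is the summed raw
score divided by the maximum possible subscale score, as a percentage:

    score = 100 * sum(ratings) / (n_items * scale_max).

Profiles attach an individual's David's Score when available so the factor
scores can feed correlation and regression analyses against behavioural
frequencies.

The packaged default factor definitions transcribe the curiosity/openness
(6 items, one reverse-scored) and playfulness (3 items, one reverse-scored)
subscales; the remaining factors are named placeholders whose items must be
supplied by the user.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dominance import DavidsScores
from .errors import ConfigurationError, ScoringError

logger = logging.getLogger(__name__)

DEFAULT_SCALE = (1, 6)


@dataclass(frozen=True)
class Item:
    item_id: str
    text: str = ""
    reverse_scored: bool = False


@dataclass(frozen=True)
class FactorDefinition:
    """One factor subscale: its items and the rating scale they use."""

    name: str
    items: tuple[Item, ...]
    scale_min: int = DEFAULT_SCALE[0]
    scale_max: int = DEFAULT_SCALE[1]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"factor {self.name!r} needs at least one item")
        if self.scale_max <= self.scale_min:
            raise ValueError("scale_max must exceed scale_min")


@dataclass
class ResponseSet:
    """One individual's ratings, item_id -> numeric rating."""

    individual_id: str
    ratings: dict[str, float] = field(default_factory=dict)


@dataclass
class PersonalityProfile:
    """Factor percentage scores for one individual, optionally with its DS."""

    individual_id: str
    scores: dict[str, float] = field(default_factory=dict)
    davids_score: float | None = None


def reverse(rating: float, scale_min: int, scale_max: int) -> float:
    """Reverse-score a rating; applying twice restores the original."""
    return scale_min + scale_max - rating


def score_factor(r: ResponseSet, f: FactorDefinition) -> float:
    """Percentage score of one factor for one individual.

    Every item of the subscale must be answered and lie on the scale;
    otherwise a :class:`ScoringError` names the offending item.
    """
    total = 0.0
    for item in f.items:
        if item.item_id not in r.ratings:
            raise ScoringError(
                f"{r.individual_id}: missing rating for item {item.item_id!r} of {f.name!r}")
        rating = r.ratings[item.item_id]
        if not (f.scale_min <= rating <= f.scale_max):
            raise ScoringError(
                f"{r.individual_id}: rating {rating} for {item.item_id!r} outside "
                f"[{f.scale_min}, {f.scale_max}]")
        total += reverse(rating, f.scale_min, f.scale_max) if item.reverse_scored else rating
    return 100.0 * total / (len(f.items) * f.scale_max)


def build_profiles(responses: list[ResponseSet], factors: list[FactorDefinition],
                   ds: DavidsScores | None = None) -> list[PersonalityProfile]:
    """One profile per respondent; DS attached where the id is known."""
    if not factors:
        logger.warning("empty factor list: profiles will carry no scores")
    ds_map = ds.as_dict() if ds is not None else {}
    profiles = []
    for r in responses:
        if ds is not None and r.individual_id not in ds_map:
            logger.warning("individual %s has no David's Score; profile emitted without one",
                           r.individual_id)
        profiles.append(PersonalityProfile(
            individual_id=r.individual_id,
            scores={f.name: score_factor(r, f) for f in factors},
            davids_score=ds_map.get(r.individual_id),
        ))
    return profiles


def factor_summary(profiles: list[PersonalityProfile]) -> dict[str, tuple[float, float]]:
    """Group-level mean and sd per factor (sd = 0 for a single profile)."""
    from statistics import mean, stdev

    names = sorted({n for p in profiles for n in p.scores})
    out = {}
    for n in names:
        vals = [p.scores[n] for p in profiles if n in p.scores]
        out[n] = (mean(vals), stdev(vals) if len(vals) > 1 else 0.0)
    return out


#: Transcribed default subscales (1-6 scale). The second curiosity item and
#: the third playfulness item are negatively phrased, hence reverse-scored.
DEFAULT_FACTORS: tuple[FactorDefinition, ...] = (
    FactorDefinition(
        name="curiosity/openness",
        items=(
            Item("crs1", "inventive and resourceful in finding hidden food or toys"),
            Item("crs2", "few interests beyond eating and sleeping; unexplorative, uncurious",
                 reverse_scored=True),
            Item("crs3", "good grasp of things, learns quickly"),
            Item("crs4", "attentive"),
            Item("crs5", "intelligent"),
            Item("crs6", "clever"),
        ),
    ),
    FactorDefinition(
        name="playfulness",
        items=(
            Item("play1", "enthusiastic, encourages peers to play"),
            Item("play2", "easy to excite about new play ideas"),
            Item("play3", "often does not understand what is asked in play situations",
                 reverse_scored=True),
        ),
    ),
)

#: Factors named in the questionnaires whose item lists must be user-supplied.
PLACEHOLDER_FACTOR_NAMES = (
    "extraversion", "sociability", "motivation", "calmness/neuroticism", "training focus",
)


def load_factor_definitions(text: str, *, source: str = "<config>") -> list[FactorDefinition]:
    """Parse factor definitions from YAML.

    Schema: ``factors: [{name, scale_min, scale_max,
    items: [{item_id, text, reverse_scored}]}]``.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{source}: {exc}") from exc
    if not isinstance(doc, dict) or "factors" not in doc:
        raise ConfigurationError(f"{source}: expected a top-level 'factors' list")
    factors = []
    for f in doc["factors"]:
        factors.append(FactorDefinition(
            name=str(f["name"]),
            items=tuple(Item(str(i["item_id"]), str(i.get("text", "")),
                             bool(i.get("reverse_scored", False))) for i in f["items"]),
            scale_min=int(f.get("scale_min", DEFAULT_SCALE[0])),
            scale_max=int(f.get("scale_max", DEFAULT_SCALE[1])),
        ))
    return factors


def read_responses(path: str | Path) -> list[ResponseSet]:
    """Read a responses CSV with columns individual_id,item_id,rating."""
    path = Path(path)
    by_ind: dict[str, ResponseSet] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ind = row["individual_id"].strip()
            by_ind.setdefault(ind, ResponseSet(ind)).ratings[row["item_id"].strip()] = float(row["rating"])
    return list(by_ind.values())


def write_responses(responses: list[ResponseSet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id", "item_id", "rating"])
        for r in responses:
            for item_id, rating in r.ratings.items():
                writer.writerow([r.individual_id, item_id, format(rating, "g")])
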