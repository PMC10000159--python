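"""Behavioural taxonomy: behaviour codes grouped into categories.

An ethogram is a catalogue of the behaviours of a species organised by
behavioural category (agonistic, play, caregiving, submissive, feeding,
greeting, locomotion/exploratory, scent-marking, other, predation, resting).
Every behaviour code belongs to exactly one category; chain definitions are
validated against the ethogram so that downstream joins across CSV files are
unambiguous.

The packaged default (``load_default_ethogram``) is a modified wolf ethogram
with 11 categories, including a dedicated submissive category and the
behaviours that make up the social-reward chain (group formation, greeting,
snout licking, combined submissive behaviours, leaving together) plus the
candidate initial behaviours (novel-object interaction, run, forage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .errors import ConfigurationError, ValidationError

UNKNOWN_CATEGORY = "unknown"

_DEFAULT_RESOURCE = "goodmann2002_modified.yaml"


@dataclass(frozen=True)
class Behaviour:
    """A single behaviour: short code, human-readable label, owning category."""

    code: str
    label: str
    category: str


@dataclass
class BehaviourCategory:
    """A named group of behaviour codes (one level of the taxonomy)."""

    name: str
    behaviours: dict[str, Behaviour] = field(default_factory=dict)

    @property
    def codes(self) -> set[str]:
        return set(self.behaviours)


@dataclass
class Ethogram:
    """Full taxonomy: categories plus a flat code -> Behaviour index.

    Codes are case-sensitive, whitespace-trimmed tokens and must be unique
    across the whole ethogram.
    """

    categories: dict[str, BehaviourCategory] = field(default_factory=dict)
    version_label: str = ""

    def __post_init__(self) -> None:
        self._index: dict[str, Behaviour] = {}
        for cat in self.categories.values():
            for code, beh in cat.behaviours.items():
                if code in self._index:
                    raise ValidationError(
                        f"behaviour code {code!r} listed under both "
                        f"{self._index[code].category!r} and {cat.name!r}"
                    )
                self._index[code] = beh

    def __contains__(self, code: str) -> bool:
        return code in self._index

    @property
    def codes(self) -> set[str]:
        return set(self._index)

    def category_of(self, code: str) -> str:
        """Owning category name, or the ``unknown`` marker for absent codes."""
        beh = self._index.get(code)
        return beh.category if beh is not None else UNKNOWN_CATEGORY

    def behaviour(self, code: str) -> Behaviour | None:
        return self._index.get(code)


def categorize(code: str, eth: Ethogram) -> str:
    """Map a behaviour code to its category; unknown codes map to ``unknown``."""
    return eth.category_of(code.strip())


def _build(doc: dict, source: str) -> Ethogram:
    if not isinstance(doc, dict) or "categories" not in doc:
        raise ConfigurationError(f"{source}: expected a top-level 'categories' mapping")
    cats: dict[str, BehaviourCategory] = {}
    for name, entries in doc["categories"].items():
        name = str(name).strip()
        if name in cats:
            raise ValidationError(f"{source}: duplicate category {name!r}")
        cat = BehaviourCategory(name=name)
        for entry in entries or []:
            if not isinstance(entry, dict) or "code" not in entry:
                raise ConfigurationError(
                    f"{source}: category {name!r} entries must be mappings with a 'code'"
                )
            code = str(entry["code"]).strip()
            if not code:
                raise ValidationError(f"{source}: empty behaviour code in {name!r}")
            if code in cat.behaviours:
                raise ValidationError(f"{source}: duplicate code {code!r} in {name!r}")
            cat.behaviours[code] = Behaviour(
                code=code, label=str(entry.get("label", code)), category=name
            )
        cats[name] = cat
    return Ethogram(categories=cats, version_label=str(doc.get("version_label", "")))


def load_ethogram(config_text: str, *, source: str = "<config>") -> Ethogram:
    """Parse a YAML ethogram config into an :class:`Ethogram`.

    Raises :class:`ConfigurationError` on parse failure (with line context
    from the YAML parser) and :class:`ValidationError` on duplicate codes.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # yaml errors carry line/column marks
        raise ConfigurationError(f"{source}: {exc}") from exc
    return _build(doc, source)


def load_ethogram_file(path: str | Path) -> Ethogram:
    path = Path(path)
    return load_ethogram(path.read_text(encoding="utf-8"), source=str(path))


def load_default_ethogram() -> Ethogram:
    """The packaged 11-category modified wolf ethogram."""
    text = resources.files("ethochain.data").joinpath(_DEFAULT_RESOURCE).read_text("utf-8")
    return load_ethogram(text, source=_DEFAULT_RESOURCE)


def write_ethogram(eth: Ethogram) -> str:
    """Serialise an ethogram back to its YAML config form (round-trips)."""
    doc = {
        "version_label": eth.version_label,
        "categories": {
            name: [
                {"code": b.code, "label": b.label}
                for b in cat.behaviours.values()
            ]
            for name, cat in eth.categories.items()
        },
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def validate_codes(codes: Iterable[str], eth: Ethogram) -> list[str]:
    """Return the codes not present in the ethogram (empty list if all known)."""
    return [c for c in codes if c not in eth]
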