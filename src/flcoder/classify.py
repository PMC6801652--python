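"""Keyword/tag classification of facilities into food-environment categories.

Each facility is assigned exactly one of four food categories --
fast-food restaurant, bar/restaurant, supermarket, or convenience store &
others -- or ``non_food`` when nothing matches.  Curated source tags
(e.g. ``shop=supermarket``) outrank evidence from the storefront name,
which is scanned for whole-token keyword phrases from a multi-language
lexicon (Spanish, Catalan and English by default).  When several
categories hit, a configurable precedence order decides; the default puts
the more specific categories first (fast food before the generic
bar/restaurant).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .text import normalize_text

__all__ = [
    "CategoryLabel",
    "KeywordLexicon",
    "normalize_text",
    "classify_facility",
    "classify_all",
    "FOOD_CATEGORIES",
]


class CategoryLabel(str, enum.Enum):
    FAST_FOOD = "fast_food"
    BAR_RESTAURANT = "bar_restaurant"
    SUPERMARKET = "supermarket"
    CONVENIENCE_OTHER = "convenience_other"
    NON_FOOD = "non_food"

    def __str__(self) -> str:
        return self.value


FOOD_CATEGORIES: tuple[CategoryLabel, ...] = (
    CategoryLabel.FAST_FOOD,
    CategoryLabel.BAR_RESTAURANT,
    CategoryLabel.SUPERMARKET,
    CategoryLabel.CONVENIENCE_OTHER,
)

DEFAULT_PRECEDENCE: tuple[CategoryLabel, ...] = (
    CategoryLabel.FAST_FOOD,
    CategoryLabel.SUPERMARKET,
    CategoryLabel.BAR_RESTAURANT,
    CategoryLabel.CONVENIENCE_OTHER,
)


@dataclass
class KeywordLexicon:
    """Per-category tag values and normalized keyword phrases.

    ``keywords[category][language]`` holds phrases already passed through
    :func:`normalize_text`; ``tags[category]`` holds ``key=value`` source
    tag patterns.  ``precedence`` is a permutation of the four food
    categories applied when multiple categories match.
    """

    tags: dict[CategoryLabel, list[str]] = field(default_factory=dict)
    keywords: dict[CategoryLabel, dict[str, list[str]]] = field(default_factory=dict)
    precedence: tuple[CategoryLabel, ...] = DEFAULT_PRECEDENCE

    def __post_init__(self) -> None:
        if sorted(c.value for c in self.precedence) != sorted(c.value for c in FOOD_CATEGORIES):
            raise ValueError("precedence must be a permutation of the four food categories")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "KeywordLexicon":
        precedence = tuple(CategoryLabel(c) for c in data.get("precedence", [c.value for c in DEFAULT_PRECEDENCE]))
        tags: dict[CategoryLabel, list[str]] = {}
        keywords: dict[CategoryLabel, dict[str, list[str]]] = {}
        for cat_name, block in data.get("categories", {}).items():
            cat = CategoryLabel(cat_name)
            tags[cat] = [str(t).strip().lower() for t in block.get("tags", [])]
            keywords[cat] = {
                lang: [normalize_text(str(kw)) for kw in kws]
                for lang, kws in (block.get("keywords") or {}).items()
            }
        return cls(tags=tags, keywords=keywords, precedence=precedence)

    @classmethod
    def from_yaml(cls, path: str) -> "KeywordLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "KeywordLexicon":
        ref = resources.files("flcoder.data") / "lexicon.yaml"
        return cls.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))

    def all_keywords(self, category: CategoryLabel) -> list[str]:
        return [kw for kws in self.keywords.get(category, {}).values() for kw in kws if kw]

    def languages(self) -> list[str]:
        langs: list[str] = []
        for block in self.keywords.values():
            for lang in block:
                if lang not in langs:
                    langs.append(lang)
        return langs


def _phrase_in_name(phrase: str, name_tokens: Sequence[str]) -> bool:
    """Whole-token substring: the phrase's tokens appear consecutively."""
    ptoks = phrase.split()
    if not ptoks:
        return False
    n, m = len(name_tokens), len(ptoks)
    return any(list(name_tokens[i : i + m]) == ptoks for i in range(n - m + 1))


def classify_facility(facility, lexicon: KeywordLexicon) -> CategoryLabel:
    """Assign one category to a facility record.

    Rule order: (1) source-tag match, precedence deciding among multiple
    tag hits; (2) keyword phrases in the canonical name, first category in
    precedence order with a hit; (3) otherwise ``non_food``.
    """
    tag_pairs = {
        f"{str(k).strip().lower()}={str(v).strip().lower()}"
        for k, v in getattr(facility, "tags", {}).items()
    }
    for cat in lexicon.precedence:
        if tag_pairs & set(lexicon.tags.get(cat, [])):
            return cat

    name = getattr(facility, "canonical_name", None) or normalize_text(
        getattr(facility, "name", "") or ""
    )
    tokens = name.split()
    for cat in lexicon.precedence:
        if any(_phrase_in_name(kw, tokens) for kw in lexicon.all_keywords(cat)):
            return cat
    return CategoryLabel.NON_FOOD


def classify_all(facilities: Iterable, lexicon: KeywordLexicon):
    """Classify every facility; return (facilities, tally, shares).

    ``tally`` maps every category (including ``non_food``) to a count;
    ``shares`` to the fraction of the input.  Non-food facilities are kept
    in the output but are excluded from food-environment analyses
    downstream (their ``category`` says so explicitly).
    """
    facilities = list(facilities)
    tally = {cat: 0 for cat in CategoryLabel}
    for fac in facilities:
        cat = classify_facility(fac, lexicon)
        fac.category = cat
        tally[cat] += 1
    total = len(facilities)
    shares = {cat: (n / total if total else 0.0) for cat, n in tally.items()}
    return facilities, tally, shares
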