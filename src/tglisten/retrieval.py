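"""Boolean keyword retrieval over normalized query text.

A strategy is an ordered list of clauses; a clause is either a single
lexicon category (OR over its terms) or a pair of categories combined
with AND.  A post is retrieved when at least one clause matches its
query text.  Matching is substring containment on normalized text,
uniformly for both bundled lexicon languages.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Iterable

from pydantic import BaseModel, Field, model_validator

from .corpus_model import Lexicon, RawPost, data_path, normalize_text

__all__ = [
    "ClauseKind",
    "SearchClause",
    "SearchStrategy",
    "default_strategy",
    "load_strategy",
    "match_category",
    "match_clause",
    "retrieve",
]


class ClauseKind(str, Enum):
    single = "single"
    pair = "pair"


class SearchClause(BaseModel):
    kind: ClauseKind
    categories: tuple[str, ...]

    @model_validator(mode="after")
    def _check_arity(self) -> "SearchClause":
        if self.kind is ClauseKind.single and len(self.categories) != 1:
            raise ValueError("single clause must name exactly one category")
        if self.kind is ClauseKind.pair:
            if len(self.categories) != 2 or self.categories[0] == self.categories[1]:
                raise ValueError("pair clause must name two distinct categories")
        return self

    def label(self) -> str:
        return "+".join(self.categories)


class SearchStrategy(BaseModel):
    clauses: list[SearchClause] = Field(min_length=1)


def load_strategy(path: str | Path) -> SearchStrategy:
    with open(path, "r", encoding="utf-8") as fh:
        return SearchStrategy.model_validate(json.load(fh))


def default_strategy() -> SearchStrategy:
    """The bundled default: 3 single-category clauses plus 11 pair clauses."""
    return load_strategy(data_path("strategy_default.json"))


def match_category(text: str, lexicon: Lexicon, category: str) -> bool:
    """True iff any term of ``category`` occurs as a substring of ``text``.

    ``text`` is expected to be normalized already; empty text matches nothing.
    Unknown categories raise ``KeyError``.
    """
    terms = lexicon.terms(category)
    if not text:
        return False
    return any(term in text for term in terms)


def match_clause(text: str, lexicon: Lexicon, clause: SearchClause) -> bool:
    if clause.kind is ClauseKind.single:
        return match_category(text, lexicon, clause.categories[0])
    return match_category(text, lexicon, clause.categories[0]) and match_category(
        text, lexicon, clause.categories[1]
    )


def retrieve(
    posts: Iterable[RawPost],
    lexicon: Lexicon,
    strategy: SearchStrategy | None = None,
) -> tuple[list[RawPost], dict[str, list[str]]]:
    """Keep posts whose query text satisfies at least one strategy clause.

    Returns the kept posts in input order plus, per kept post_id, the labels
    of every matching clause (retained as diagnostics for keyword reports).
    Matching considers query_text only; responses are analyzed downstream.
    """
    if strategy is None:
        strategy = default_strategy()
    kept: list[RawPost] = []
    matched: dict[str, list[str]] = {}
    for post in posts:
        text = normalize_text(post.query_text)
        labels = [c.label() for c in strategy.clauses if match_clause(text, lexicon, c)]
        if labels:
            kept.append(post)
            matched[post.post_id] = labels
    return kept, matched
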