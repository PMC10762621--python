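"""Domain types for consultation corpora plus JSONL I/O and text normalization.

The interchange format is one JSON object per line with a fixed schema
(see :data:`CORPUS_SCHEMA_FIELDS`).  All text matching downstream operates
on strings canonicalized by :func:`normalize_text`; lexicon terms are
stored already normalized so that matching is plain substring containment.
"""

from __future__ import annotations

import json
import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

from pydantic import BaseModel, Field, ValidationError, field_validator

__all__ = [
    "PlatformType",
    "ResponderTitle",
    "Platform",
    "RawResponse",
    "RawPost",
    "Lexicon",
    "LEXICON_CATEGORIES",
    "CorpusFormatError",
    "LexiconConfigError",
    "normalize_text",
    "read_corpus",
    "write_corpus",
    "load_lexicon",
    "bundled_lexicon",
    "data_path",
]

YEAR_MIN = 2004
YEAR_MAX = 2020

#: The seven keyword category codes used by retrieval, filtering and extraction.
LEXICON_CATEGORIES = ("I-a", "I-b", "II-a", "II-b", "III", "IV-a", "IV-b")

CORPUS_SCHEMA_FIELDS = (
    "post_id",
    "platform",
    "platform_type",
    "year",
    "query_text",
    "responses",
)


class PlatformType(str, Enum):
    qa_search = "qa_search"
    online_consultation = "online_consultation"


class ResponderTitle(str, Enum):
    chief = "chief"
    associate_chief = "associate_chief"
    attending = "attending"
    resident = "resident"
    nurse = "nurse"
    other = "other"
    unknown = "unknown"


class Platform(BaseModel):
    name: str = Field(min_length=1)
    platform_type: PlatformType


class RawResponse(BaseModel):
    response_id: str = Field(min_length=1)
    text: str
    responder_title: Optional[ResponderTitle] = None
    responder_region: Optional[str] = None
    hospital_level: Optional[str] = None


class RawPost(BaseModel):
    post_id: str = Field(min_length=1)
    platform: Platform
    year: int = Field(ge=YEAR_MIN, le=YEAR_MAX)
    query_text: str
    responses: list[RawResponse] = Field(default_factory=list)

    @field_validator("responses")
    @classmethod
    def _unique_response_ids(cls, v: list[RawResponse]) -> list[RawResponse]:
        ids = [r.response_id for r in v]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate response_id within post")
        return v


class CorpusFormatError(ValueError):
    """A corpus line failed JSON parsing or schema validation."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class LexiconConfigError(ValueError):
    """A lexicon config is missing a category or contains invalid terms."""


_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Canonicalize free text for substring matching.

    Lower-cases, maps full-width ASCII forms (U+FF01..U+FF5E and the
    ideographic space) to their half-width equivalents, collapses whitespace
    runs to single spaces and strips the ends.  Idempotent, and never yields
    more characters than the input (case mappings that would expand, such as
    the dotted capital I, are left unchanged).
    """
    out: list[str] = []
    for ch in text:
        o = ord(ch)
        if 0xFF01 <= o <= 0xFF5E:
            ch = chr(o - 0xFEE0)
        elif o == 0x3000:
            ch = " "
        low = ch.lower()
        out.append(low if len(low) == 1 else ch)
    return _WS_RE.sub(" ", "".join(out)).strip()


class Lexicon(BaseModel):
    """Keyword category system: category code -> normalized term list."""

    language: str = "en"
    categories: dict[str, list[str]]

    @field_validator("categories")
    @classmethod
    def _check_categories(cls, v: dict[str, list[str]]) -> dict[str, list[str]]:
        for cat in LEXICON_CATEGORIES:
            if cat not in v:
                raise ValueError(f"missing lexicon category {cat!r}")
            if not v[cat]:
                raise ValueError(f"lexicon category {cat!r} is empty")
            if any(t == "" for t in v[cat]):
                raise ValueError(f"lexicon category {cat!r} contains empty term")
        return v

    def terms(self, category: str) -> list[str]:
        try:
            return self.categories[category]
        except KeyError:
            raise KeyError(f"unknown lexicon category {category!r}") from None


def _post_to_canonical_dict(post: RawPost) -> dict:
    d = post.model_dump(mode="json")
    d["platform_type"] = d["platform"]["platform_type"]
    d["platform"] = d["platform"]["name"]
    return {k: d[k] for k in CORPUS_SCHEMA_FIELDS}


def _post_from_dict(d: dict) -> RawPost:
    if not isinstance(d, dict):
        raise ValueError("corpus line is not a JSON object")
    payload = dict(d)
    platform = {
        "name": payload.pop("platform", None),
        "platform_type": payload.pop("platform_type", None),
    }
    payload["platform"] = platform
    return RawPost.model_validate(payload)


def read_corpus(path: str | Path) -> Iterator[RawPost]:
    """Yield :class:`RawPost` objects from a JSONL corpus, in file order.

    Raises :class:`CorpusFormatError` naming the 1-based line number on the
    first malformed or schema-invalid line.
    """
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(lineno, f"invalid JSON ({exc.msg})") from exc
            try:
                yield _post_from_dict(obj)
            except (ValidationError, ValueError) as exc:
                raise CorpusFormatError(lineno, str(exc)) from exc


def write_corpus(posts: Iterable[RawPost], path: str | Path) -> int:
    """Write posts as canonical JSONL (sorted keys within nested objects,
    fixed top-level field order); returns the number of records written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(
                json.dumps(
                    _post_to_canonical_dict(post),
                    ensure_ascii=False,
                    separators=(",", ":"),
                )
            )
            fh.write("\n")
            n += 1
    return n


def data_path(name: str) -> Path:
    """Path to a bundled data file shipped with the package."""
    return Path(__file__).parent / "data" / name


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon config (JSON: {"language": ..., "categories": {...}}).

    Every term is normalized via :func:`normalize_text`; duplicates within a
    category are removed (first occurrence wins).  A missing category raises
    :class:`LexiconConfigError` naming the category.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    cats = raw.get("categories", {})
    for cat in LEXICON_CATEGORIES:
        if cat not in cats:
            raise LexiconConfigError(f"lexicon config missing category {cat!r}")
    normalized: dict[str, list[str]] = {}
    for cat, terms in cats.items():
        seen: list[str] = []
        for t in terms:
            nt = normalize_text(str(t))
            if nt and nt not in seen:
                seen.append(nt)
        if not seen:
            raise LexiconConfigError(f"lexicon category {cat!r} has no usable terms")
        normalized[cat] = seen
    return Lexicon(language=raw.get("language", "en"), categories=normalized)


def bundled_lexicon(language: str = "en") -> Lexicon:
    """Load one of the two lexicons shipped with the package ("en" or "zh")."""
    if language not in ("en", "zh"):
        raise LexiconConfigError(f"no bundled lexicon for language {language!r}")
    return load_lexicon(data_path(f"lexicon_{language}.json"))
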