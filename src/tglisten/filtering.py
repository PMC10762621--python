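"""Exclusion filtering: duplicate IDs, advertisements, popular-science posts,
and non-topic posts (every extracted TG value below 1.7 mmol/L).

Rules fire in a fixed precedence — duplicate, advertisement, popular_science,
non_topic — and the first rule that fires is recorded.  The study's trained
text-classification models are replaced by these deterministic rules; a small
token-frequency classifier is provided purely for comparison and never
overrides a rule verdict.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel

from .classification import TG_THRESHOLD
from .corpus_model import Lexicon, RawPost, data_path, normalize_text
from .extraction import extract_tg_values, has_condition_evidence

__all__ = [
    "Verdict",
    "FilterRule",
    "FilterDecision",
    "MarkerConfig",
    "bundled_markers",
    "drop_duplicates",
    "is_advertisement",
    "is_popular_science",
    "is_non_topic",
    "apply_filters",
    "NgramClassifier",
    "train_stand_in_classifier",
    "classify",
    "decisions_to_csv",
]


class Verdict(str, Enum):
    keep = "keep"
    drop = "drop"


class FilterRule(str, Enum):
    duplicate = "duplicate"
    advertisement = "advertisement"
    popular_science = "popular_science"
    non_topic = "non_topic"
    none = "none"


class FilterDecision(BaseModel):
    post_id: str
    verdict: Verdict
    rule_fired: FilterRule

    def model_post_init(self, __context) -> None:
        keep = self.verdict is Verdict.keep
        if keep != (self.rule_fired is FilterRule.none):
            raise ValueError("verdict=keep iff rule_fired=none")


class MarkerConfig(BaseModel):
    """Editable marker lists driving the advertisement/science rules."""

    language: str = "en"
    link_tokens: list[str]
    promotion_markers: list[str]
    science_markers: list[str]


def bundled_markers(language: str = "en") -> MarkerConfig:
    with open(data_path(f"markers_{language}.json"), "r", encoding="utf-8") as fh:
        return MarkerConfig.model_validate(json.load(fh))


def drop_duplicates(posts: Iterable[RawPost]) -> tuple[list[RawPost], list[FilterDecision]]:
    """Keep the first occurrence of each post_id; later ones drop as duplicates."""
    seen: set[str] = set()
    kept: list[RawPost] = []
    decisions: list[FilterDecision] = []
    for post in posts:
        if post.post_id in seen:
            decisions.append(
                FilterDecision(post_id=post.post_id, verdict=Verdict.drop,
                               rule_fired=FilterRule.duplicate)
            )
        else:
            seen.add(post.post_id)
            kept.append(post)
            decisions.append(
                FilterDecision(post_id=post.post_id, verdict=Verdict.keep,
                               rule_fired=FilterRule.none)
            )
    return kept, decisions


def _tg_terms(lexicon: Optional[Lexicon]) -> Sequence[str]:
    from .extraction import DEFAULT_TG_TERMS

    return tuple(lexicon.terms("II-a")) if lexicon is not None else DEFAULT_TG_TERMS


def is_advertisement(
    post: RawPost,
    lexicon: Optional[Lexicon] = None,
    markers: Optional[MarkerConfig] = None,
) -> bool:
    """True iff a link/promotion marker occurs and no condition evidence does."""
    markers = markers or bundled_markers()
    text = normalize_text(post.query_text)
    has_marker = any(t in text for t in markers.link_tokens) or any(
        t in text for t in markers.promotion_markers
    )
    return has_marker and not has_condition_evidence(text, _tg_terms(lexicon))


def is_popular_science(
    post: RawPost,
    markers: Optional[MarkerConfig] = None,
    lexicon: Optional[Lexicon] = None,
) -> bool:
    """True iff encyclopedic/definitional phrasing occurs without any
    personal-condition evidence."""
    markers = markers or bundled_markers()
    text = normalize_text(post.query_text)
    return any(t in text for t in markers.science_markers) and not has_condition_evidence(
        text, _tg_terms(lexicon)
    )


def is_non_topic(post: RawPost, lexicon: Optional[Lexicon] = None) -> bool:
    """True iff at least one TG value was extracted and all are below the
    inclusion threshold; posts with no extractable value are not flagged."""
    values = extract_tg_values(normalize_text(post.query_text), _tg_terms(lexicon))
    return bool(values) and all(v < TG_THRESHOLD for v in values)


def apply_filters(
    posts: Iterable[RawPost],
    lexicon: Optional[Lexicon] = None,
    markers: Optional[MarkerConfig] = None,
) -> tuple[list[RawPost], list[FilterDecision]]:
    """Run all exclusion rules in precedence order; one decision per post.

    Idempotent on its own kept output, and |kept| + |dropped| = |input|.
    """
    markers = markers or bundled_markers()
    deduped, dedup_decisions = drop_duplicates(posts)
    kept: list[RawPost] = []
    decisions: list[FilterDecision] = []
    kept_idx = 0
    for dec in dedup_decisions:
        if dec.rule_fired is FilterRule.duplicate:
            decisions.append(dec)
            continue
        post = deduped[kept_idx]
        kept_idx += 1
        if is_advertisement(post, lexicon, markers):
            rule = FilterRule.advertisement
        elif is_popular_science(post, markers, lexicon):
            rule = FilterRule.popular_science
        elif is_non_topic(post, lexicon):
            rule = FilterRule.non_topic
        else:
            rule = FilterRule.none
            kept.append(post)
        decisions.append(
            FilterDecision(
                post_id=post.post_id,
                verdict=Verdict.keep if rule is FilterRule.none else Verdict.drop,
                rule_fired=rule,
            )
        )
    return kept, decisions


def decisions_to_csv(decisions: Sequence[FilterDecision], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("post_id,verdict,rule_fired\n")
        for d in decisions:
            fh.write(f"{d.post_id},{d.verdict.value},{d.rule_fired.value}\n")


# ---------------------------------------------------------------------------
# stand-in classifier (comparison only; never overrides rule verdicts)


class NgramClassifier(BaseModel):
    """Multinomial naive Bayes over character n-grams, add-one smoothing."""

    n: int = 3
    classes: list[str]
    class_log_prior: dict[str, float]
    ngram_log_prob: dict[str, dict[str, float]]
    default_log_prob: dict[str, float]


def _ngrams(text: str, n: int) -> list[str]:
    text = normalize_text(text)
    if len(text) < n:
        return [text] if text else []
    return [text[i : i + n] for i in range(len(text) - n + 1)]


def train_stand_in_classifier(
    labeled: Sequence[tuple[str, str]], n: int = 3
) -> NgramClassifier:
    """Train deterministically on (text, label) pairs; needs >= 2 labels."""
    labels = sorted({lab for _, lab in labeled})
    if len(labels) < 2:
        raise ValueError("training data must contain at least two distinct labels")
    counts: dict[str, Counter] = {lab: Counter() for lab in labels}
    class_counts: Counter = Counter()
    for text, lab in labeled:
        class_counts[lab] += 1
        counts[lab].update(_ngrams(text, n))
    vocab = sorted(set().union(*counts.values()))
    v = len(vocab)
    total = sum(class_counts.values())
    log_prior = {lab: math.log(class_counts[lab] / total) for lab in labels}
    ngram_log_prob: dict[str, dict[str, float]] = {}
    default_log_prob: dict[str, float] = {}
    for lab in labels:
        denom = sum(counts[lab].values()) + v + 1
        ngram_log_prob[lab] = {
            g: math.log((counts[lab][g] + 1) / denom) for g in vocab
        }
        default_log_prob[lab] = math.log(1 / denom)
    return NgramClassifier(
        n=n,
        classes=labels,
        class_log_prior=log_prior,
        ngram_log_prob=ngram_log_prob,
        default_log_prob=default_log_prob,
    )


def classify(clf: NgramClassifier, text: str) -> str:
    """Most probable label; ties resolved by label sort order."""
    scores = {lab: clf.class_log_prior[lab] for lab in clf.classes}
    for g in _ngrams(text, clf.n):
        for lab in clf.classes:
            scores[lab] += clf.ngram_log_prob[lab].get(g, clf.default_log_prob[lab])
    return max(sorted(scores), key=lambda lab: scores[lab])
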