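"""Rule-based extraction of patient attributes from consultation text.

All extractors are pure functions over normalized text (see
:func:`tglisten.corpus_model.normalize_text`).  Vocabularies are flat
substring lists; there is no tokenization, negation scoping or parsing.
Laboratory values are returned in mmol/L (mg/dL inputs are converted with
the standard divisor 88.57).
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .corpus_model import Lexicon, RawPost, RawResponse, normalize_text

__all__ = [
    "PatientRecord",
    "ResponseContent",
    "MG_DL_PER_MMOL_L",
    "extract_gender",
    "extract_age",
    "extract_tg_values",
    "extract_pregnancy",
    "extract_chol_elevated",
    "extract_symptoms",
    "extract_secondary",
    "extract_interventions",
    "extract_response_content",
    "has_condition_evidence",
    "build_patient_record",
]

MG_DL_PER_MMOL_L = 88.57

# ---------------------------------------------------------------------------
# vocabularies

#: Relation word -> patient gender for proxy consultations.
RELATION_GENDER = {
    "father": "male",
    "dad": "male",
    "husband": "male",
    "brother": "male",
    "son": "male",
    "grandfather": "male",
    "uncle": "male",
    "mother": "female",
    "mom": "female",
    "wife": "female",
    "sister": "female",
    "daughter": "female",
    "grandmother": "female",
    "aunt": "female",
    "parent": "unknown",
    "spouse": "unknown",
    "relative": "unknown",
}

_SELF_FEMALE = ("woman", "female", "girl", "lady")
_SELF_MALE = ("man", "male", "boy", "gentleman")

_relation_alt = "|".join(sorted(RELATION_GENDER, key=len, reverse=True))
_RELATION_RE = re.compile(rf"\b(?:my|our)\b[^.!?]{{0,30}}?\b({_relation_alt})\b")
_self_alt = "|".join(_SELF_FEMALE + _SELF_MALE)
_SELF_RE = re.compile(rf"\bi am (?:an? )?[^.!?]{{0,30}}?\b({_self_alt})\b")

_AGE_DIRECT_RES = (
    re.compile(r"\b(\d{1,3})[\s-]*(?:years?|yrs?)[\s-]*old\b"),
    re.compile(r"\b(?:age|aged)[:\s]*(\d{1,3})\b"),
)

_DECADES = {
    "twenties": 25,
    "thirties": 35,
    "forties": 45,
    "fifties": 55,
    "sixties": 65,
    "seventies": 75,
    "eighties": 85,
}
_AGE_INDIRECT = {
    f"in {pron} {decade}": mid
    for decade, mid in _DECADES.items()
    for pron in ("my", "his", "her", "their")
}
_AGE_INDIRECT.update(
    {"over sixty": 65, "over seventy": 75, "over eighty": 85, "under twenty": 15}
)

_SUBJECT_CUE_RE = re.compile(rf"\b(?:i am|my (?:{_relation_alt}))\b")

PREGNANCY_TERMS = ("pregnant", "pregnancy", "gestation")

SYMPTOM_VOCAB = {
    "head": ("dizziness", "dizzy", "headache"),
    "chest": ("chest tightness", "chest pain", "palpitation", "shortness of breath"),
    "other": ("fatigue", "numbness", "blurred vision", "tinnitus"),
}

SECONDARY_VOCAB = {
    "ascvd_cardiac": ("coronary heart disease", "myocardial infarction"),
    "ascvd_cerebral": ("cerebral infarction", "stroke"),
    "pancreatitis": ("pancreatitis",),
}

LIFESTYLE_VOCAB = {
    "smoking_cessation": ("quit smoking", "stop smoking", "stopped smoking", "smoking cessation"),
    "weight_control": ("control my weight", "control your weight", "lose weight", "losing weight", "weight control"),
    "exercise": ("exercise",),
    "limit_carbohydrate": ("limit carbohydrate", "less carbohydrate", "cut down on carbohydrate", "limit carbs"),
    "limit_alcohol": ("limit alcohol", "less alcohol", "stopped drinking alcohol", "alcohol restriction"),
    "limit_oil": ("limit oil", "use less oil", "less cooking oil"),
    "diet_control": ("control my diet", "control your diet", "diet control", "watch my diet"),
}

DRUG_VOCAB = {
    "fibrate": ("fenofibrate", "bezafibrate", "lipanthyl", "fibrate", "bate"),
    "statin": ("statin",),  # substring covers all -statin compound names
    "tcm": ("xuezhikang", "zhibituo", "zhikening", "jiangzhining"),
    "niacin": ("niacin", "nicotinic acid"),
    "fish_oil": ("fish oil",),
    "other": ("ezetimibe", "probucol"),
}

FACTOR_VOCAB = {
    "safety": ("safety", "safe", "side effect"),
    "effectiveness": ("effective", "efficacy", "works well"),
    "economics": ("expensive", "cheap", "economical", "price", "cost"),
    "brand": ("brand",),
    "tcm_preference": ("prefer traditional chinese medicine", "prefer chinese medicine", "want chinese medicine"),
}

#: Response-suggestion vocabulary; diet control without a specific item maps
#: to ``diet_control_unspecified`` (see :func:`extract_response_content`).
RESPONSE_LIFESTYLE_VOCAB = {
    "reduce_fats": ("reduce fat", "fatty food", "less fat", "low-fat", "limit fat"),
    "exercise": ("exercise",),
    "smoking_cessation": LIFESTYLE_VOCAB["smoking_cessation"],
    "weight_control": LIFESTYLE_VOCAB["weight_control"],
    "limit_carbohydrate": LIFESTYLE_VOCAB["limit_carbohydrate"],
    "limit_alcohol": LIFESTYLE_VOCAB["limit_alcohol"],
    "limit_oil": LIFESTYLE_VOCAB["limit_oil"],
}
_DIET_CONTROL_PHRASES = LIFESTYLE_VOCAB["diet_control"]

SUPPLEMENT_TERMS = ("supplement", "health product")
LIPID_DIET_TERMS = ("lipid-lowering diet", "lipid lowering diet")

DEFAULT_TG_TERMS = ("triglyceride", "triacylglycerol", "tg")

_CHOL_RE = re.compile(
    r"(?:high|elevated|raised)[^.!?]{0,30}cholesterol|cholesterol[^.!?]{0,40}(?:high|elevated|raised)"
)

_EVIDENCE_RE = re.compile(
    r"\b(?:i|my|his|her)\b[^.!?]{0,60}?\b(?:is|am|are|was|were|has|have|had|feel|feels|felt)\b"
)

_NUMBER_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(mmol\s*/\s*l|mg\s*/\s*dl)?")
_NON_LAB_FOLLOW_RE = re.compile(r"\s*-?\s*(?:years?|yrs?|weeks?|months?|days?|times?|%)\b")


# ---------------------------------------------------------------------------
# domain types


class PatientRecord(BaseModel):
    """Extracted (and later classified) attributes of one kept post."""

    post_id: str
    gender: str = "unknown"
    is_proxy: bool = False
    relation: Optional[str] = None
    age_years: Optional[int] = None
    pregnant: bool = False
    tg_mmol_per_l: list[float] = Field(default_factory=list)
    chol_elevated: bool = False
    symptoms: list[str] = Field(default_factory=list)
    secondary_conditions: list[str] = Field(default_factory=list)
    current_lifestyle: list[str] = Field(default_factory=list)
    current_drugs: list[str] = Field(default_factory=list)
    drug_combination_size: Optional[int] = Field(default=None, ge=2)
    selection_factors: list[str] = Field(default_factory=list)
    # filled in by the classification stage
    severity: Optional[str] = None
    htg_type: Optional[str] = None
    demand: Optional[str] = None
    demand_group: Optional[str] = None
    # carried along for aggregation convenience
    year: Optional[int] = None
    platform_type: Optional[str] = None

    @model_validator(mode="after")
    def _invariants(self) -> "PatientRecord":
        if any(v <= 0 for v in self.tg_mmol_per_l):
            raise ValueError("TG values must be positive")
        if self.pregnant and self.gender == "unknown":
            self.gender = "female"
        for name in ("symptoms", "secondary_conditions", "current_lifestyle",
                     "current_drugs", "selection_factors"):
            setattr(self, name, sorted(set(getattr(self, name))))
        return self


class ResponseContent(BaseModel):
    """Suggestion content extracted from one response."""

    response_id: str
    lifestyle_suggestions: list[str] = Field(default_factory=list)
    drugs_recommended: list[str] = Field(default_factory=list)
    supplements: bool = False
    lipid_lowering_diet: bool = False
    medication_suggested: bool = False
    word_count: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _invariants(self) -> "ResponseContent":
        self.lifestyle_suggestions = sorted(set(self.lifestyle_suggestions))
        self.drugs_recommended = sorted(set(self.drugs_recommended))
        self.medication_suggested = bool(self.drugs_recommended)
        return self


# ---------------------------------------------------------------------------
# extractors


def _match_any(text: str, terms: Iterable[str]) -> bool:
    return any(t in text for t in terms)


def _vocab_hits(text: str, vocab: dict[str, tuple[str, ...]]) -> list[str]:
    return sorted(label for label, terms in vocab.items() if _match_any(text, terms))


def extract_gender(text: str) -> tuple[str, bool, Optional[str]]:
    """Return (gender, is_proxy, relation).

    Relational cues ("my father ...") take precedence and mark the post as a
    proxy consultation; direct self-descriptions ("i am a ... woman") set the
    gender with is_proxy False; otherwise ("unknown", False, None).
    """
    m = _RELATION_RE.search(text)
    if m:
        relation = m.group(1)
        return RELATION_GENDER[relation], True, relation
    m = _SELF_RE.search(text)
    if m:
        return ("female" if m.group(1) in _SELF_FEMALE else "male"), False, None
    return "unknown", False, None


def extract_age(text: str) -> Optional[int]:
    """Patient age in years from direct or indirect phrasing, else None.

    With several direct ages, the one nearest after a subject cue wins,
    otherwise the first one in the text.
    """
    matches = []
    for rx in _AGE_DIRECT_RES:
        matches.extend(rx.finditer(text))
    matches.sort(key=lambda m: m.start())
    if matches:
        if len(matches) > 1:
            cues = [c.end() for c in _SUBJECT_CUE_RE.finditer(text)]
            for m in matches:
                if any(0 <= m.start() - ce <= 40 for ce in cues):
                    return int(m.group(1))
        return int(matches[0].group(1))
    for phrase, midpoint in _AGE_INDIRECT.items():
        if phrase in text:
            return midpoint
    return None


def extract_tg_values(text: str, tg_terms: Sequence[str] = DEFAULT_TG_TERMS) -> list[float]:
    """All triglyceride values in mmol/L, in order of appearance.

    A number counts as a TG value when a TG term precedes it within 60
    characters (30 for unitless numbers).  ``mg/dl`` values are divided by
    88.57; unitless numbers are accepted only in [0.1, 100] and only when not
    followed by a duration/percent token.  Numbers with cholesterol mentioned
    between the TG term and the value are rejected.
    """
    term_spans: list[tuple[int, int]] = []
    for term in tg_terms:
        term_spans.extend(m.span() for m in re.finditer(re.escape(term), text))
    if not term_spans:
        return []
    values: list[float] = []
    for m in _NUMBER_RE.finditer(text):
        raw, unit = m.group(1), m.group(2)
        window = 60 if unit else 30
        anchored = False
        for ts, te in term_spans:
            if te <= m.start() and m.start() - te <= window:
                if "cholesterol" in text[te:m.start()]:
                    continue
                anchored = True
                break
        if not anchored:
            continue
        value = float(raw)
        if unit is None:
            if _NON_LAB_FOLLOW_RE.match(text[m.end():]):
                continue
            if not (0.1 <= value <= 100):
                continue
        elif "mg" in unit:
            value = value / MG_DL_PER_MMOL_L
        values.append(value)
    return values


def extract_pregnancy(text: str) -> bool:
    return _match_any(text, PREGNANCY_TERMS)


def extract_chol_elevated(text: str) -> bool:
    return bool(_CHOL_RE.search(text))


def extract_symptoms(text: str) -> set[str]:
    return set(_vocab_hits(text, SYMPTOM_VOCAB))


def extract_secondary(text: str) -> set[str]:
    return set(_vocab_hits(text, SECONDARY_VOCAB))


def extract_interventions(
    text: str,
) -> tuple[set[str], set[str], Optional[int], set[str]]:
    """Return (lifestyle set, drug-class set, combination size, factor set).

    Combination size is the number of distinct drug classes mentioned, present
    only when at least two classes co-occur in the post.
    """
    lifestyle = set(_vocab_hits(text, LIFESTYLE_VOCAB))
    drugs = set(_vocab_hits(text, DRUG_VOCAB))
    factors = set(_vocab_hits(text, FACTOR_VOCAB))
    combination = len(drugs) if len(drugs) >= 2 else None
    return lifestyle, drugs, combination, factors


def has_condition_evidence(text: str, tg_terms: Sequence[str] = DEFAULT_TG_TERMS) -> bool:
    """Heuristic for 'the post describes someone's actual condition'.

    True when a TG value is extractable, a symptom term occurs, or a
    first/third-person statement pattern ("my/his/her ... is/has") appears.
    Used by the advertisement and popular-science filters.
    """
    if extract_tg_values(text, tg_terms):
        return True
    if extract_symptoms(text):
        return True
    return bool(_EVIDENCE_RE.search(text))


def extract_response_content(response: RawResponse, language: str = "en") -> ResponseContent:
    """Extract suggestion labels from one response.

    ``diet_control_unspecified`` is set only when a diet-control phrase occurs
    without any specific lifestyle item.  Word count is whitespace tokens for
    English and non-whitespace characters for Chinese.
    """
    text = normalize_text(response.text)
    lifestyle = _vocab_hits(text, RESPONSE_LIFESTYLE_VOCAB)
    if not lifestyle and _match_any(text, _DIET_CONTROL_PHRASES):
        lifestyle = ["diet_control_unspecified"]
    drugs = _vocab_hits(text, DRUG_VOCAB)
    if language == "zh":
        word_count = len(re.sub(r"\s", "", text))
    else:
        word_count = len(text.split())
    return ResponseContent(
        response_id=response.response_id,
        lifestyle_suggestions=lifestyle,
        drugs_recommended=drugs,
        supplements=_match_any(text, SUPPLEMENT_TERMS),
        lipid_lowering_diet=_match_any(text, LIPID_DIET_TERMS),
        medication_suggested=bool(drugs),
        word_count=word_count,
    )


def build_patient_record(post: RawPost, lexicon: Optional[Lexicon] = None) -> PatientRecord:
    """Run every extractor over a post's query text and assemble the record."""
    text = normalize_text(post.query_text)
    tg_terms = tuple(lexicon.terms("II-a")) if lexicon is not None else DEFAULT_TG_TERMS
    gender, is_proxy, relation = extract_gender(text)
    lifestyle, drugs, combination, factors = extract_interventions(text)
    return PatientRecord(
        post_id=post.post_id,
        gender=gender,
        is_proxy=is_proxy,
        relation=relation,
        age_years=extract_age(text),
        pregnant=extract_pregnancy(text),
        tg_mmol_per_l=extract_tg_values(text, tg_terms),
        chol_elevated=extract_chol_elevated(text),
        symptoms=sorted(extract_symptoms(text)),
        secondary_conditions=sorted(extract_secondary(text)),
        current_lifestyle=sorted(lifestyle),
        current_drugs=sorted(drugs),
        drug_combination_size=combination,
        selection_factors=sorted(factors),
        year=post.year,
        platform_type=post.platform.platform_type.value,
    )
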