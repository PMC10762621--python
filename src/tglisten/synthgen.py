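"""Synthetic consultation-corpus generator with full ground-truth labels.

Posts are produced by slot-filling sentence templates whose slots embed
lexicon terms, so that every clean post's text passed through the extraction
and classification stages reproduces its own ground-truth labels exactly.
Contaminants (duplicate IDs, advertisements, popular-science posts and
below-threshold TG posts) are generated in addition to ``n_posts`` clean
posts, at per-clean-post expected rates, and are appended after the clean
block so a duplicate always follows its source occurrence.

Generation is fully deterministic: identical (config, seed) pairs yield
byte-identical corpora under :func:`tglisten.corpus_model.write_corpus`.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .corpus_model import Platform, PlatformType, RawPost, RawResponse
from .extraction import PatientRecord
from .filtering import FilterDecision, Verdict

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "ResponseTruth",
    "GroundTruth",
    "generate",
    "write_truth",
    "read_truth",
    "recovery_report",
]

_YEARS = tuple(range(2004, 2021))
# ramp up to 2017 then decline, mirroring the observed annual-volume shape
_YEAR_WEIGHTS = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 11, 8, 6], float)
_YEAR_WEIGHTS /= _YEAR_WEIGHTS.sum()

_QA_PLATFORMS = tuple(f"qa platform {i}" for i in range(1, 7))
_CONSULT_PLATFORMS = tuple(f"consultation platform {i}" for i in range(1, 15))

_SEVERITY_BANDS = {
    "edge": (1.7, 2.3),
    "mild_moderate": (2.3, 5.6),
    "severe": (5.6, 20.0),
}

_DEMAND_DEFAULT_COUNTS = {
    "how_to_treat": 14194,
    "drug_selection": 9782,
    "disease_concepts": 6281,
    "lifestyle_precautions": 3789,
    "disease_causes": 3477,
    "medication": 3042,
    "dietary_control": 2551,
    "lipid_lowering_foods": 1994,
    "disease_impact": 1973,
    "diagnosis_criteria": 1814,
}
_DEMAND_TOTAL = sum(_DEMAND_DEFAULT_COUNTS.values())

_DEMAND_PHRASES = {
    "how_to_treat": "how to treat this",
    "drug_selection": "what drug should i take",
    "disease_concepts": "what are triglycerides exactly",
    "lifestyle_precautions": "what should i pay attention to in daily life",
    "disease_causes": "what causes this, is it hereditary",
    "medication": "do i need medication",
    "dietary_control": "what can i not eat",
    "lipid_lowering_foods": "what foods to eat to reduce blood lipids",
    "disease_impact": "what hazards could this bring",
    "diagnosis_criteria": "how serious is a high tg level like this",
}

_MALE_RELATIONS = ("father", "husband", "brother")
_FEMALE_RELATIONS = ("mother", "wife", "sister")

_DRUG_SURFACES = {
    "fibrate": ("fenofibrate", "bezafibrate"),
    "statin": ("atorvastatin", "simvastatin", "rosuvastatin"),
    "tcm": ("xuezhikang", "zhibituo"),
    "niacin": ("niacin",),
    "fish_oil": ("fish oil",),
    "other": ("ezetimibe", "probucol"),
}
_DRUG_CLASSES = tuple(_DRUG_SURFACES)
_DRUG_CLASS_WEIGHTS = (0.45, 0.30, 0.12, 0.05, 0.05, 0.03)

_LIFESTYLE_PHRASES = {
    "smoking_cessation": "quit smoking",
    "weight_control": "lose weight",
    "exercise": "exercise every day",
    "limit_carbohydrate": "limit carbohydrate intake",
    "limit_alcohol": "limit alcohol",
    "limit_oil": "use less oil",
    "diet_control": "control my diet",
}
_LIFESTYLE_LABELS = tuple(_LIFESTYLE_PHRASES)

_FACTOR_PHRASES = {
    "safety": "i care most about safety.",
    "effectiveness": "i want something effective.",
    "economics": "i hope it is not expensive.",
    "brand": "i care about the brand.",
    "tcm_preference": "i would prefer traditional chinese medicine.",
}
_FACTOR_LABELS = tuple(_FACTOR_PHRASES)
_FACTOR_WEIGHTS = (0.50, 0.30, 0.08, 0.05, 0.07)

_RESPONSE_LIFESTYLE_PHRASES = {
    "reduce_fats": "reduce fatty food",
    "exercise": "do proper exercise",
    "smoking_cessation": "quit smoking",
    "weight_control": "control your weight",
    "limit_carbohydrate": "limit carbohydrate intake",
    "limit_alcohol": "limit alcohol",
    "limit_oil": "use less oil",
}
_RESPONSE_LIFESTYLE_RATES = {
    "reduce_fats": 0.772,
    "exercise": 0.630,
    "smoking_cessation": 0.12,
    "weight_control": 0.12,
    "limit_carbohydrate": 0.14,
    "limit_alcohol": 0.20,
    "limit_oil": 0.15,
}

_TITLES = ("attending", "resident", "associate_chief", "chief", "nurse", "other")
_TITLE_WEIGHTS = (0.371, 0.215, 0.181, 0.122, 0.108, 0.003)
_REGIONS = ("shandong", "hebei", "liaoning", "henan", "jiangxi", "jilin",
            "guangdong", "sichuan", "hunan", "beijing")
_REGION_WEIGHTS = (0.16, 0.14, 0.13, 0.10, 0.09, 0.08, 0.08, 0.08, 0.07, 0.07)
_HOSPITAL_LEVELS = ("tertiary a", "tertiary b", "secondary", "primary")
_HOSPITAL_WEIGHTS = (0.35, 0.25, 0.25, 0.15)

_AD_TEMPLATES = (
    "our clinic lowers triglycerides fast, click http://lipid-offer.example for a special offer.",
    "special offer on triglyceride lowering products, visit www.lipid-deal.example today.",
    "free trial of our product for high tg, add the group now to claim it.",
)
_SCIENCE_TEMPLATES = (
    "triglycerides are a kind of fat found in the blood. this article explains how the body stores energy.",
    "hypertriglyceridemia refers to an elevated level of triglycerides in the blood. health knowledge: the liver packages them into lipoproteins.",
)


def _normalize_mix(mix: dict[str, float]) -> None:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture probabilities sum to {total}, expected 1")


class ContaminationConfig(BaseModel):
    duplicate_rate: float = Field(default=0.05, ge=0, le=1)
    ad_rate: float = Field(default=0.05, ge=0, le=1)
    science_rate: float = Field(default=0.05, ge=0, le=1)
    low_tg_rate: float = Field(default=0.05, ge=0, le=1)


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic corpus; defaults mirror published marginals."""

    n_posts: int = Field(ge=1)
    seed: int = 0
    platform_mix: float = Field(default=0.53, ge=0, le=1)  # P(qa_search)
    gender_mix: float = Field(default=0.43, ge=0, le=1)  # P(female)
    proxy_rate_female: float = Field(default=0.276, ge=0, le=1)
    proxy_rate_male: float = Field(default=0.208, ge=0, le=1)
    pregnancy_rate: float = Field(default=0.158, ge=0, le=1)  # among females
    age_distribution: dict[str, float] = Field(
        default_factory=lambda: {"le20": 0.05, "21_60": 0.86, "gt60": 0.09}
    )
    severity_mix: dict[str, float] = Field(
        default_factory=lambda: {"edge": 0.193, "mild_moderate": 0.523, "severe": 0.284}
    )
    chol_co_elevation_rate: float = Field(default=0.267, ge=0, le=1)
    contamination: ContaminationConfig = Field(default_factory=ContaminationConfig)
    demand_mix: dict[str, float] = Field(
        default_factory=lambda: {
            k: v / _DEMAND_TOTAL for k, v in _DEMAND_DEFAULT_COUNTS.items()
        }
    )
    intervention_mention_rate: float = Field(default=0.10, ge=0, le=1)
    symptom_rate: float = Field(default=0.127, ge=0, le=1)
    secondary_rate: float = Field(default=0.025, ge=0, le=1)
    response_count_mean: dict[str, float] = Field(
        default_factory=lambda: {"qa_search": 1.34, "online_consultation": 1.88}
    )
    medication_rec_rates: dict[str, float] = Field(
        default_factory=lambda: {"edge": 0.662, "mild_moderate": 0.778, "severe": 0.881}
    )
    template_language: str = "en"

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        _normalize_mix(self.age_distribution)
        _normalize_mix(self.severity_mix)
        _normalize_mix(self.demand_mix)
        if set(self.severity_mix) != set(_SEVERITY_BANDS):
            raise ValueError("severity_mix must cover edge/mild_moderate/severe")
        if set(self.demand_mix) != set(_DEMAND_DEFAULT_COUNTS):
            raise ValueError("demand_mix must cover the ten demand labels")
        if self.template_language != "en":
            # The zh lexicon/markers are bundled for matching, but post
            # templates are authored in English only.
            raise ValueError("only template_language='en' is supported")
        return self


class ResponseTruth(BaseModel):
    response_id: str
    lifestyle_suggestions: list[str] = Field(default_factory=list)
    drugs_recommended: list[str] = Field(default_factory=list)
    supplements: bool = False
    lipid_lowering_diet: bool = False
    medication_suggested: bool = False
    responder_title: Optional[str] = None
    responder_region: Optional[str] = None
    hospital_level: Optional[str] = None


class TruthRecord(BaseModel):
    """True labels for one generated post (clean or contaminant)."""

    post_id: str
    is_contaminant: bool = False
    contaminant_kind: Optional[str] = None
    gender: Optional[str] = None
    is_proxy: Optional[bool] = None
    relation: Optional[str] = None
    age_years: Optional[int] = None
    pregnant: Optional[bool] = None
    tg_values: list[float] = Field(default_factory=list)
    chol_elevated: Optional[bool] = None
    severity: Optional[str] = None
    htg_type: Optional[str] = None
    demand: Optional[str] = None
    demand_group: Optional[str] = None
    symptoms: list[str] = Field(default_factory=list)
    secondary_conditions: list[str] = Field(default_factory=list)
    current_lifestyle: list[str] = Field(default_factory=list)
    current_drugs: list[str] = Field(default_factory=list)
    drug_combination_size: Optional[int] = None
    selection_factors: list[str] = Field(default_factory=list)
    responses: list[ResponseTruth] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "TruthRecord":
        if self.is_contaminant and self.gender is not None:
            raise ValueError("contaminant truth records carry no patient labels")
        return self


class GroundTruth(BaseModel):
    """One truth record per generated post occurrence, in corpus order.

    ``clean_by_id`` indexes the clean records; duplicate contaminants share a
    post_id with their source and are only reachable through ``records``.
    """

    records: list[TruthRecord]

    @property
    def clean_by_id(self) -> dict[str, TruthRecord]:
        return {r.post_id: r for r in self.records if not r.is_contaminant}

    @property
    def contaminants(self) -> list[TruthRecord]:
        return [r for r in self.records if r.is_contaminant]


def _choice(rng: np.random.Generator, items: Sequence, weights: Sequence[float]):
    idx = rng.choice(len(items), p=np.asarray(weights, float) / np.sum(weights))
    return items[int(idx)]


def _band_value(rng: np.random.Generator, severity: str) -> float:
    low, high = _SEVERITY_BANDS[severity]
    # floor to 2 decimals, sampling short of the boundary so the printed
    # value can never cross into the next band
    u = rng.uniform(low, high - 0.011)
    return float(np.floor(u * 100) / 100)


def _clean_post(
    rng: np.random.Generator, config: GeneratorConfig, index: int
) -> tuple[RawPost, TruthRecord]:
    post_id = f"p{index:06d}"
    qa = rng.random() < config.platform_mix
    ptype = PlatformType.qa_search if qa else PlatformType.online_consultation
    platform = Platform(
        name=_choice(rng, _QA_PLATFORMS if qa else _CONSULT_PLATFORMS,
                     [1] * (6 if qa else 14)),
        platform_type=ptype,
    )
    year = int(_choice(rng, _YEARS, _YEAR_WEIGHTS))

    gender = "female" if rng.random() < config.gender_mix else "male"
    proxy_rate = config.proxy_rate_female if gender == "female" else config.proxy_rate_male
    is_proxy = rng.random() < proxy_rate
    relation = None
    if is_proxy:
        pool = _FEMALE_RELATIONS if gender == "female" else _MALE_RELATIONS
        relation = str(_choice(rng, pool, [1] * 3))

    band = _choice(rng, tuple(config.age_distribution),
                   tuple(config.age_distribution.values()))
    if band == "le20":
        age = int(rng.integers(12, 21))
    elif band == "21_60":
        age = int(rng.integers(21, 61))
    else:
        age = int(rng.integers(61, 86))

    pregnant = gender == "female" and rng.random() < config.pregnancy_rate
    severity = str(_choice(rng, tuple(config.severity_mix),
                           tuple(config.severity_mix.values())))
    tg_value = _band_value(rng, severity)
    chol = rng.random() < config.chol_co_elevation_rate
    demand = str(_choice(rng, tuple(config.demand_mix), tuple(config.demand_mix.values())))

    symptoms: list[str] = []
    if rng.random() < config.symptom_rate:
        symptoms = list(_choice(rng, (("head",), ("chest",), ("head", "chest")),
                                (0.55, 0.30, 0.15)))
    secondary: list[str] = []
    if rng.random() < config.secondary_rate:
        secondary = [str(_choice(rng, ("ascvd_cardiac", "ascvd_cerebral", "pancreatitis"),
                                 (0.5, 0.3, 0.2)))]

    lifestyle: list[str] = []
    drugs: list[str] = []
    factors: list[str] = []
    if rng.random() < config.intervention_mention_rate:
        k = int(_choice(rng, (1, 2, 3), (0.85, 0.12, 0.03)))
        w = np.asarray(_DRUG_CLASS_WEIGHTS)
        drugs = list(
            np.array(_DRUG_CLASSES)[
                rng.choice(len(_DRUG_CLASSES), size=k, replace=False, p=w / w.sum())
            ]
        )
        if rng.random() < 0.5:
            m = int(_choice(rng, (1, 2), (0.7, 0.3)))
            lifestyle = list(
                np.array(_LIFESTYLE_LABELS)[
                    rng.choice(len(_LIFESTYLE_LABELS), size=m, replace=False)
                ]
            )
        if rng.random() < 0.4:
            factors = [str(_choice(rng, _FACTOR_LABELS, _FACTOR_WEIGHTS))]

    # --- assemble text ---------------------------------------------------
    sentences: list[str] = []
    preg_clause = ""
    if pregnant:
        preg_clause = f" and {int(rng.integers(8, 39))} weeks pregnant"
    if is_proxy:
        sentences.append(f"my {relation} is {age} years old{preg_clause}.")
    else:
        noun = "woman" if gender == "female" else "man"
        sentences.append(f"i am a {age} year old {noun}{preg_clause}.")
    tg_term = str(_choice(rng, ("triglyceride", "tg"), (0.7, 0.3)))
    sentences.append(f"the {tg_term} level is {tg_value:.2f} mmol/l.")
    if chol:
        sentences.append("the cholesterol level is also high.")
    if symptoms:
        phr = {
            "head": str(_choice(rng, ("dizziness", "headache"), (0.6, 0.4))),
            "chest": str(_choice(rng, ("chest tightness", "chest pain",
                                       "palpitation", "shortness of breath"),
                                 (0.3, 0.3, 0.2, 0.2))),
        }
        sentences.append("recently there is often " + " and ".join(phr[s] for s in symptoms) + ".")
    if secondary:
        sec_phr = {
            "ascvd_cardiac": "there was a myocardial infarction two years ago.",
            "ascvd_cerebral": "there was a cerebral infarction last year.",
            "pancreatitis": "there was an episode of pancreatitis before.",
        }
        sentences.append(sec_phr[secondary[0]])
    if drugs:
        surfaces = [str(_choice(rng, _DRUG_SURFACES[d], [1] * len(_DRUG_SURFACES[d])))
                    for d in drugs]
        sentences.append("currently taking " + " and ".join(surfaces) + ".")
    if lifestyle:
        sentences.append(
            "i already " + " and ".join(_LIFESTYLE_PHRASES[l] for l in lifestyle) + "."
        )
    if factors:
        sentences.append(_FACTOR_PHRASES[factors[0]])
    sentences.append(f"please tell me {_DEMAND_PHRASES[demand]}?")
    query_text = " ".join(sentences)

    # --- responses -------------------------------------------------------
    n_resp = int(rng.poisson(config.response_count_mean[ptype.value]))
    responses: list[RawResponse] = []
    response_truths: list[ResponseTruth] = []
    for j in range(n_resp):
        rid = f"{post_id}r{j}"
        rsent: list[str] = []
        if rng.random() < 0.124:
            labels = ["diet_control_unspecified"]
            rsent.append("please control your diet.")
        else:
            labels = [
                lab for lab in _RESPONSE_LIFESTYLE_PHRASES
                if rng.random() < _RESPONSE_LIFESTYLE_RATES[lab]
            ]
            if labels:
                rsent.append(
                    "i suggest that you "
                    + " and ".join(_RESPONSE_LIFESTYLE_PHRASES[lab] for lab in labels)
                    + "."
                )
        rdrugs: list[str] = []
        if rng.random() < config.medication_rec_rates[severity]:
            kk = int(_choice(rng, (1, 2), (0.7, 0.3)))
            w = np.asarray((0.40, 0.37, 0.09, 0.05, 0.05, 0.04))
            rdrugs = sorted(
                np.array(_DRUG_CLASSES)[
                    rng.choice(len(_DRUG_CLASSES), size=kk, replace=False, p=w / w.sum())
                ]
            )
            rsurfaces = [str(_choice(rng, _DRUG_SURFACES[d], [1] * len(_DRUG_SURFACES[d])))
                         for d in rdrugs]
            rsent.append("you can take " + " and ".join(rsurfaces) + ".")
        supplements = rng.random() < 0.03
        if supplements:
            rsent.append("you could also consider a health product supplement.")
        lipid_diet = rng.random() < 0.10
        if lipid_diet:
            rsent.append("a lipid-lowering diet may also help.")
        if not rsent:
            rsent.append("please recheck the blood lipid panel in two weeks.")
        if ptype is PlatformType.online_consultation:
            title = str(_choice(rng, _TITLES, _TITLE_WEIGHTS))
            region = str(_choice(rng, _REGIONS, _REGION_WEIGHTS))
            level = str(_choice(rng, _HOSPITAL_LEVELS, _HOSPITAL_WEIGHTS))
        else:
            title, region, level = "unknown", None, None
        responses.append(
            RawResponse(response_id=rid, text=" ".join(rsent),
                        responder_title=title, responder_region=region,
                        hospital_level=level)
        )
        response_truths.append(
            ResponseTruth(
                response_id=rid,
                lifestyle_suggestions=sorted(labels),
                drugs_recommended=list(rdrugs),
                supplements=supplements,
                lipid_lowering_diet=lipid_diet,
                medication_suggested=bool(rdrugs),
                responder_title=title,
                responder_region=region,
                hospital_level=level,
            )
        )

    post = RawPost(post_id=post_id, platform=platform, year=year,
                   query_text=query_text, responses=responses)
    truth = TruthRecord(
        post_id=post_id,
        gender=gender,
        is_proxy=is_proxy,
        relation=relation,
        age_years=age,
        pregnant=pregnant,
        tg_values=[tg_value],
        chol_elevated=chol,
        severity=severity,
        htg_type="tg_plus_chol" if chol else "tg_only",
        demand=demand,
        demand_group={
            "how_to_treat": "how_to_intervene",
            "drug_selection": "drug_intervention",
            "medication": "drug_intervention",
            "disease_concepts": "disease_cognition",
            "disease_causes": "disease_cognition",
            "disease_impact": "disease_cognition",
            "diagnosis_criteria": "disease_cognition",
            "lifestyle_precautions": "lifestyle_intervention",
            "dietary_control": "lifestyle_intervention",
            "lipid_lowering_foods": "lifestyle_intervention",
        }[demand],
        symptoms=sorted(symptoms),
        secondary_conditions=sorted(secondary),
        current_lifestyle=sorted(lifestyle),
        current_drugs=sorted(drugs),
        drug_combination_size=len(drugs) if len(drugs) >= 2 else None,
        selection_factors=sorted(factors),
        responses=response_truths,
    )
    return post, truth


def _contaminant_platform(rng: np.random.Generator, config: GeneratorConfig) -> tuple[Platform, int]:
    qa = rng.random() < config.platform_mix
    platform = Platform(
        name=str(_choice(rng, _QA_PLATFORMS if qa else _CONSULT_PLATFORMS,
                         [1] * (6 if qa else 14))),
        platform_type=PlatformType.qa_search if qa else PlatformType.online_consultation,
    )
    return platform, int(_choice(rng, _YEARS, _YEAR_WEIGHTS))


def generate(config: GeneratorConfig) -> tuple[list[RawPost], GroundTruth]:
    """Generate the corpus and its ground truth.

    Returns exactly ``n_posts`` clean posts followed by the contaminant block
    (binomially sized per rate, shuffled within itself).
    """
    rng = np.random.default_rng(config.seed)
    posts: list[RawPost] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_posts):
        post, truth = _clean_post(rng, config, i)
        posts.append(post)
        truths.append(truth)

    contaminants: list[tuple[RawPost, TruthRecord]] = []
    c = config.contamination
    n_dup = int(rng.binomial(config.n_posts, c.duplicate_rate))
    n_ad = int(rng.binomial(config.n_posts, c.ad_rate))
    n_sci = int(rng.binomial(config.n_posts, c.science_rate))
    n_low = int(rng.binomial(config.n_posts, c.low_tg_rate))
    for _ in range(n_dup):
        src = posts[int(rng.integers(0, config.n_posts))]
        contaminants.append(
            (src.model_copy(deep=True),
             TruthRecord(post_id=src.post_id, is_contaminant=True,
                         contaminant_kind="duplicate"))
        )
    for i in range(n_ad):
        platform, year = _contaminant_platform(rng, config)
        text = str(_choice(rng, _AD_TEMPLATES, [1] * len(_AD_TEMPLATES)))
        pid = f"a{i:06d}"
        contaminants.append(
            (RawPost(post_id=pid, platform=platform, year=year, query_text=text),
             TruthRecord(post_id=pid, is_contaminant=True,
                         contaminant_kind="advertisement"))
        )
    for i in range(n_sci):
        platform, year = _contaminant_platform(rng, config)
        text = str(_choice(rng, _SCIENCE_TEMPLATES, [1] * len(_SCIENCE_TEMPLATES)))
        pid = f"s{i:06d}"
        contaminants.append(
            (RawPost(post_id=pid, platform=platform, year=year, query_text=text),
             TruthRecord(post_id=pid, is_contaminant=True,
                         contaminant_kind="popular_science"))
        )
    for i in range(n_low):
        platform, year = _contaminant_platform(rng, config)
        v = float(np.floor(rng.uniform(0.5, 1.69) * 100) / 100)
        pid = f"l{i:06d}"
        text = f"my triglyceride was {v:.2f} mmol/l on the last report, is that a problem?"
        contaminants.append(
            (RawPost(post_id=pid, platform=platform, year=year, query_text=text),
             TruthRecord(post_id=pid, is_contaminant=True, contaminant_kind="non_topic"))
        )
    if contaminants:
        order = rng.permutation(len(contaminants))
        contaminants = [contaminants[int(k)] for k in order]
    for post, truth in contaminants:
        posts.append(post)
        truths.append(truth)
    return posts, GroundTruth(records=truths)


def write_truth(truth: GroundTruth, path: str | Path) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in truth.records:
            fh.write(json.dumps(rec.model_dump(mode="json"), ensure_ascii=False,
                                sort_keys=True, separators=(",", ":")))
            fh.write("\n")
    return len(truth.records)


def read_truth(path: str | Path) -> GroundTruth:
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(TruthRecord.model_validate(json.loads(line)))
    return GroundTruth(records=records)


# ---------------------------------------------------------------------------
# recovery report


def _accuracy(pairs: list[tuple[object, object]]) -> float:
    if not pairs:
        return float("nan")
    return sum(1 for a, b in pairs if a == b) / len(pairs)


def _proportion_errors(true_vals: list, pred_vals: list) -> dict[str, float]:
    n_t, n_p = len(true_vals), len(pred_vals)
    ct, cp = Counter(true_vals), Counter(pred_vals)
    out = {}
    for cls in sorted(set(ct) | set(cp), key=str):
        out[str(cls)] = abs(ct[cls] / n_t - cp[cls] / n_p) if n_t and n_p else float("nan")
    return out


def recovery_report(
    truth: GroundTruth,
    records: Iterable[PatientRecord],
    decisions: Iterable[FilterDecision],
) -> dict:
    """Compare pipeline output against ground truth.

    Per clean-post attribute: exact-match accuracy and absolute error of each
    recovered class proportion.  Per contaminant class: detection precision
    and recall from the filter decisions.  Raises on post_ids in ``records``
    unknown to the truth.
    """
    clean = truth.clean_by_id
    rec_by_id: dict[str, PatientRecord] = {}
    for r in records:
        if r.post_id not in clean:
            raise KeyError(f"record post_id {r.post_id!r} not present in ground truth")
        rec_by_id[r.post_id] = r

    attributes = {
        "gender": (lambda t: t.gender, lambda r: r.gender),
        "proxy": (lambda t: t.is_proxy, lambda r: r.is_proxy),
        "pregnancy": (lambda t: t.pregnant, lambda r: r.pregnant),
        "tg_values": (lambda t: tuple(t.tg_values), lambda r: tuple(r.tg_mmol_per_l)),
        "severity": (lambda t: t.severity, lambda r: r.severity),
        "demand": (lambda t: t.demand, lambda r: r.demand),
    }
    attr_report: dict[str, dict] = {}
    joined = [(clean[pid], rec_by_id[pid]) for pid in rec_by_id]
    for name, (t_get, r_get) in attributes.items():
        pairs = [(t_get(t), r_get(r)) for t, r in joined]
        attr_report[name] = {
            "accuracy": _accuracy(pairs),
            "proportion_abs_error": _proportion_errors(
                [a for a, _ in pairs], [b for _, b in pairs]
            ),
        }

    true_counts: Counter = Counter()
    for rec in truth.contaminants:
        true_counts[(rec.post_id, rec.contaminant_kind)] += 1
    pred_counts: Counter = Counter()
    rule_to_kind = {
        "duplicate": "duplicate",
        "advertisement": "advertisement",
        "popular_science": "popular_science",
        "non_topic": "non_topic",
    }
    for d in decisions:
        if d.verdict is Verdict.drop:
            pred_counts[(d.post_id, rule_to_kind[d.rule_fired.value])] += 1

    contaminant_report: dict[str, dict[str, float]] = {}
    for kind in ("duplicate", "advertisement", "popular_science", "non_topic"):
        tp = sum(
            min(n, pred_counts.get((pid, k), 0))
            for (pid, k), n in true_counts.items()
            if k == kind
        )
        n_true = sum(n for (_, k), n in true_counts.items() if k == kind)
        n_pred = sum(n for (_, k), n in pred_counts.items() if k == kind)
        contaminant_report[kind] = {
            "precision": tp / n_pred if n_pred else 1.0,
            "recall": tp / n_true if n_true else 1.0,
            "n_true": float(n_true),
            "n_pred": float(n_pred),
        }
    return {"attributes": attr_report, "contaminants": contaminant_report}
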