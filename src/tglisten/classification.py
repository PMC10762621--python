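"""Severity banding, hypertriglyceridemia typing, and demand assignment.

Severity bands are left-closed on configurable cut-points (defaults 2.3 and
5.6 mmol/L above the 1.7 mmol/L inclusion threshold).  Demands form a fixed
ten-label taxonomy with a priority rank; when several demand phrase lists
match a text, the lowest rank wins, independent of phrase-list order.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel

from .extraction import PatientRecord

__all__ = [
    "SEVERITY_CLASSES",
    "TG_THRESHOLD",
    "DEFAULT_CUTPOINTS",
    "DEMAND_TAXONOMY",
    "DEMAND_GROUPS",
    "DemandLabel",
    "classify_severity",
    "classify_htg_type",
    "classify_demand",
    "classify_record",
]

SEVERITY_CLASSES = ("edge", "mild_moderate", "severe")
TG_THRESHOLD = 1.7
DEFAULT_CUTPOINTS = (2.3, 5.6)

#: (priority rank, label, group, phrase list) — rank breaks multi-match ties.
DEMAND_TAXONOMY: tuple[tuple[int, str, str, tuple[str, ...]], ...] = (
    (1, "how_to_treat", "how_to_intervene",
     ("how to treat", "how do i treat", "how to bring it down", "what should i do about")),
    (2, "drug_selection", "drug_intervention",
     ("what drug should i take", "what drug to take", "which drug is best",
      "what medicine should i take")),
    (3, "disease_concepts", "disease_cognition",
     ("what are triglycerides", "what is hyperlipidemia", "what is hypertriglyceridemia",
      "what does triglyceride mean")),
    (4, "lifestyle_precautions", "lifestyle_intervention",
     ("what to pay attention to in daily life", "what should i pay attention to")),
    (5, "disease_causes", "disease_cognition",
     ("what causes", "is it hereditary", "why is it elevated")),
    (6, "medication", "drug_intervention",
     ("do i need medication", "need medication", "do i need to take medicine")),
    (7, "dietary_control", "lifestyle_intervention",
     ("what can i not eat", "what should i not eat", "how should i adjust my diet")),
    (8, "lipid_lowering_foods", "lifestyle_intervention",
     ("what foods to eat to reduce blood lipids", "which foods lower blood lipids",
      "what food helps lower")),
    (9, "disease_impact", "disease_cognition",
     ("what hazards", "what harm", "what are the dangers")),
    (10, "diagnosis_criteria", "disease_cognition",
     ("how serious is a high tg level", "how serious is this level", "is this level serious")),
)

DEMAND_GROUPS = ("how_to_intervene", "drug_intervention", "disease_cognition",
                 "lifestyle_intervention")

DEMAND_LABELS = tuple(label for _, label, _, _ in DEMAND_TAXONOMY)
DEMAND_GROUP_OF = {label: group for _, label, group, _ in DEMAND_TAXONOMY}
DEMAND_RANK_OF = {label: rank for rank, label, _, _ in DEMAND_TAXONOMY}


class DemandLabel(BaseModel):
    label: str
    group: str
    rank: int


def classify_severity(
    tg_max: float,
    cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS,
    threshold: float = TG_THRESHOLD,
) -> str:
    """Band a maximal TG value: [threshold, c1) edge, [c1, c2) mild_moderate,
    [c2, inf) severe.  Values below threshold are a domain error (such records
    are excluded upstream as non-topic)."""
    if tg_max < threshold:
        raise ValueError(f"TG {tg_max} below inclusion threshold {threshold}")
    c1, c2 = cutpoints
    if tg_max < c1:
        return "edge"
    if tg_max < c2:
        return "mild_moderate"
    return "severe"


def classify_htg_type(record: PatientRecord) -> str:
    if not record.tg_mmol_per_l:
        raise ValueError("record has no TG value; cannot type hypertriglyceridemia")
    return "tg_plus_chol" if record.chol_elevated else "tg_only"


def classify_demand(text: str) -> Optional[DemandLabel]:
    """Assign the highest-priority matching demand, or None."""
    best: Optional[DemandLabel] = None
    for rank, label, group, phrases in DEMAND_TAXONOMY:
        if any(p in text for p in phrases):
            if best is None or rank < best.rank:
                best = DemandLabel(label=label, group=group, rank=rank)
    return best


def classify_record(
    record: PatientRecord,
    normalized_query: str,
    cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS,
) -> PatientRecord:
    """Fill severity, type and demand fields of an extracted record in place."""
    if record.tg_mmol_per_l:
        record.severity = classify_severity(max(record.tg_mmol_per_l), cutpoints)
        record.htg_type = classify_htg_type(record)
    demand = classify_demand(normalized_query)
    if demand is not None:
        record.demand = demand.label
        record.demand_group = demand.group
    return record
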