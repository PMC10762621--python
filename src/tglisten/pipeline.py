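"""End-to-end orchestration: retrieval -> filtering -> extraction ->
classification, plus sidecar serialization helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field

from .classification import classify_record
from .corpus_model import Lexicon, RawPost, bundled_lexicon, normalize_text
from .extraction import (
    PatientRecord,
    ResponseContent,
    build_patient_record,
    extract_response_content,
)
from .filtering import FilterDecision, MarkerConfig, apply_filters
from .retrieval import SearchStrategy, retrieve

__all__ = ["PipelineResult", "run_pipeline", "write_jsonl_models", "read_records"]


class PipelineResult(BaseModel):
    records: list[PatientRecord] = Field(default_factory=list)
    response_contents: list[ResponseContent] = Field(default_factory=list)
    decisions: list[FilterDecision] = Field(default_factory=list)
    matched_clauses: dict[str, list[str]] = Field(default_factory=dict)
    n_input: int = 0
    n_retrieved: int = 0
    n_kept: int = 0


def run_pipeline(
    posts: Iterable[RawPost],
    lexicon: Optional[Lexicon] = None,
    strategy: Optional[SearchStrategy] = None,
    markers: Optional[MarkerConfig] = None,
) -> PipelineResult:
    """Run the full analysis pipeline over a corpus."""
    lexicon = lexicon or bundled_lexicon("en")
    posts = list(posts)
    retrieved, matched = retrieve(posts, lexicon, strategy)
    kept, decisions = apply_filters(retrieved, lexicon, markers)
    records: list[PatientRecord] = []
    contents: list[ResponseContent] = []
    for post in kept:
        record = build_patient_record(post, lexicon)
        classify_record(record, normalize_text(post.query_text))
        records.append(record)
        for response in post.responses:
            contents.append(extract_response_content(response, lexicon.language))
    return PipelineResult(
        records=records,
        response_contents=contents,
        decisions=decisions,
        matched_clauses=matched,
        n_input=len(posts),
        n_retrieved=len(retrieved),
        n_kept=len(kept),
    )


def write_jsonl_models(models: Sequence[BaseModel], path: str | Path) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        for m in models:
            fh.write(json.dumps(m.model_dump(mode="json"), ensure_ascii=False,
                                sort_keys=True, separators=(",", ":")))
            fh.write("\n")
    return len(models)


def read_records(path: str | Path) -> list[PatientRecord]:
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(PatientRecord.model_validate(json.loads(line)))
    return records
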