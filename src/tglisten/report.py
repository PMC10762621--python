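"""Descriptive aggregation: frequency tables, time series, platform
statistics, and arithmetic consistency checks against published counts.

Percentages are rounded half-up (matching how the published tables print)
and exclusive-category percent columns close to 100 within rounding slack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .classification import DEMAND_GROUP_OF, DEMAND_LABELS, DEMAND_RANK_OF, SEVERITY_CLASSES
from .corpus_model import Lexicon, RawPost, data_path, normalize_text
from .extraction import DRUG_VOCAB, PatientRecord, RESPONSE_LIFESTYLE_VOCAB, ResponseContent

__all__ = [
    "percent",
    "severity_distribution",
    "demand_ranking",
    "demand_by_age",
    "demand_by_severity",
    "intervention_frequencies",
    "response_rates",
    "responses_frame",
    "lifestyle_suggestion_frequencies",
    "medication_rate_by_severity",
    "drug_recommendation_frequencies",
    "annual_volume",
    "keyword_frequency",
    "mean_response_word_count",
    "records_from_cohort_counts",
    "ConsistencyResult",
    "run_consistency_checks",
    "published_counts_path",
]

YEARS = tuple(range(2004, 2021))


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100*n/d, rounded half-up to ``decimals``; zero denominator is an error."""
    if denominator == 0:
        raise ZeroDivisionError("percent undefined for zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# patient-record tables


def _records_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "post_id": r.post_id,
            "gender": r.gender,
            "pregnant": r.pregnant,
            "age_years": r.age_years,
            "severity": r.severity,
            "htg_type": r.htg_type,
            "demand": r.demand,
            "demand_group": r.demand_group,
            "has_tg": bool(r.tg_mmol_per_l),
            "year": r.year,
            "platform_type": r.platform_type,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["post_id", "gender", "pregnant", "age_years", "severity", "htg_type",
                 "demand", "demand_group", "has_tg", "year", "platform_type"],
    )


_SEVERITY_ROWS = (
    "tg_only", "tg_plus_chol", "pregnant_tg_only", "pregnant_tg_plus_chol", "total",
)


def severity_distribution(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Severity counts/percents per cohort.

    Rows: the two exclusive cohorts (TG only, TG plus cholesterol), their
    pregnant sub-cohorts, and a total row.  Pregnant rows are subsets of the
    main cohorts; the total sums only the two exclusive cohorts.  Percents
    are within-row, one decimal, half-up.
    """
    df = _records_frame(records)
    df = df[df["has_tg"] & df["severity"].notna()]

    def row_counts(mask: pd.Series) -> dict[str, int]:
        sub = df[mask]
        return {s: int((sub["severity"] == s).sum()) for s in SEVERITY_CLASSES}

    masks = {
        "tg_only": df["htg_type"] == "tg_only",
        "tg_plus_chol": df["htg_type"] == "tg_plus_chol",
        "pregnant_tg_only": (df["htg_type"] == "tg_only") & df["pregnant"],
        "pregnant_tg_plus_chol": (df["htg_type"] == "tg_plus_chol") & df["pregnant"],
    }
    table: dict[str, dict] = {}
    for name, mask in masks.items():
        table[name] = row_counts(mask)
    table["total"] = {
        s: table["tg_only"][s] + table["tg_plus_chol"][s] for s in SEVERITY_CLASSES
    }
    out = pd.DataFrame.from_dict(table, orient="index").loc[list(_SEVERITY_ROWS)]
    out["n"] = out[list(SEVERITY_CLASSES)].sum(axis=1)
    for s in SEVERITY_CLASSES:
        out[f"{s}_pct"] = [
            percent(int(c), int(n), 1) if n else 0.0
            for c, n in zip(out[s], out["n"])
        ]
    return out


def demand_ranking(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Demand labels sorted by descending count; ties break by priority rank."""
    df = _records_frame(records)
    df = df[df["demand"].notna()]
    counts = {label: int((df["demand"] == label).sum()) for label in DEMAND_LABELS}
    total = sum(counts.values())
    order = sorted(counts, key=lambda lab: (-counts[lab], DEMAND_RANK_OF[lab]))
    return pd.DataFrame(
        {
            "demand": order,
            "group": [DEMAND_GROUP_OF[lab] for lab in order],
            "count": [counts[lab] for lab in order],
            "pct": [percent(counts[lab], total, 1) if total else 0.0 for lab in order],
        }
    )


def _group_composition(df: pd.DataFrame, by: str) -> pd.DataFrame:
    """Demand-group percent composition per value of ``by`` (columns close to 100)."""
    groups = sorted(df[by].dropna().unique(), key=str)
    out = {}
    for g in groups:
        sub = df[(df[by] == g) & df["demand_group"].notna()]
        n = len(sub)
        out[str(g)] = {
            dg: percent(int((sub["demand_group"] == dg).sum()), n, 1) if n else 0.0
            for dg in sorted(set(DEMAND_GROUP_OF.values()))
        }
    return pd.DataFrame(out)


def demand_by_age(records: Iterable[PatientRecord], split_age: int = 50) -> pd.DataFrame:
    """Demand-group composition for under/over the split age.

    Records with unknown age are excluded (known-age denominator).
    """
    df = _records_frame(records)
    df = df[df["age_years"].notna()].copy()
    df["age_band"] = df["age_years"].map(
        lambda a: f"under_{split_age}" if a < split_age else f"{split_age}_and_over"
    )
    return _group_composition(df, "age_band")


def demand_by_severity(records: Iterable[PatientRecord]) -> pd.DataFrame:
    df = _records_frame(records)
    df = df[df["severity"].notna()]
    return _group_composition(df, "severity")


def intervention_frequencies(records: Iterable[PatientRecord]) -> dict[str, pd.DataFrame]:
    """Multi-select frequency tables of mentioned interventions and factors.

    Denominators are the number of records mentioning at least one item of
    the table's kind; percents may exceed 100 in sum (flagged multi-select).
    """
    recs = list(records)
    tables: dict[str, pd.DataFrame] = {}
    specs = {
        "lifestyle": lambda r: r.current_lifestyle,
        "drugs": lambda r: r.current_drugs,
        "factors": lambda r: r.selection_factors,
    }
    for name, get in specs.items():
        mentioners = [r for r in recs if get(r)]
        n = len(mentioners)
        labels = sorted({lab for r in mentioners for lab in get(r)})
        counts = {lab: sum(1 for r in mentioners if lab in get(r)) for lab in labels}
        tables[name] = pd.DataFrame(
            {
                "label": labels,
                "count": [counts[lab] for lab in labels],
                "pct": [percent(counts[lab], n, 1) if n else 0.0 for lab in labels],
            }
        ).sort_values("count", ascending=False, kind="stable").reset_index(drop=True)
        tables[name].attrs["multi_select"] = True
        tables[name].attrs["n"] = n
    return tables


# ---------------------------------------------------------------------------
# corpus / response tables


def response_rates(posts: Iterable[RawPost]) -> dict[str, float]:
    """Responses per query within each platform type, rounded to 2 decimals."""
    queries: dict[str, int] = {}
    responses: dict[str, int] = {}
    for p in posts:
        pt = p.platform.platform_type.value
        queries[pt] = queries.get(pt, 0) + 1
        responses[pt] = responses.get(pt, 0) + len(p.responses)
    return {
        pt: _round_half_up(responses[pt] / queries[pt], 2)
        for pt in sorted(queries)
        if queries[pt] > 0
    }


def responses_frame(
    posts: Iterable[RawPost],
    contents: Iterable[ResponseContent],
    records: Optional[Iterable[PatientRecord]] = None,
) -> pd.DataFrame:
    """Join response contents to their posts (and optionally records).

    Raises ``KeyError`` listing response_ids that match no post.
    """
    post_of_response: dict[str, RawPost] = {}
    for p in posts:
        for r in p.responses:
            post_of_response[r.response_id] = p
    severity_of_post: dict[str, Optional[str]] = {}
    if records is not None:
        severity_of_post = {r.post_id: r.severity for r in records}
    rows = []
    orphans = []
    for c in contents:
        p = post_of_response.get(c.response_id)
        if p is None:
            orphans.append(c.response_id)
            continue
        rows.append(
            {
                "response_id": c.response_id,
                "post_id": p.post_id,
                "platform_type": p.platform.platform_type.value,
                "severity": severity_of_post.get(p.post_id),
                "medication_suggested": c.medication_suggested,
                "lifestyle_suggestions": tuple(c.lifestyle_suggestions),
                "drugs_recommended": tuple(c.drugs_recommended),
                "supplements": c.supplements,
                "lipid_lowering_diet": c.lipid_lowering_diet,
                "word_count": c.word_count,
            }
        )
    if orphans:
        raise KeyError(f"orphan response_ids with no matching post: {orphans[:10]}")
    return pd.DataFrame(
        rows,
        columns=["response_id", "post_id", "platform_type", "severity",
                 "medication_suggested", "lifestyle_suggestions", "drugs_recommended",
                 "supplements", "lipid_lowering_diet", "word_count"],
    )


def _label_frequencies(
    frame: pd.DataFrame, column: str, labels: Sequence[str]
) -> pd.DataFrame:
    """Per-platform-type percent of responses carrying each label (multi-select)."""
    out = {}
    for pt, sub in frame.groupby("platform_type"):
        n = len(sub)
        out[pt] = {
            lab: percent(int(sub[column].map(lambda s: lab in s).sum()), n, 1) if n else 0.0
            for lab in labels
        }
    df = pd.DataFrame(out)
    df.attrs["multi_select"] = True
    return df


def lifestyle_suggestion_frequencies(frame: pd.DataFrame) -> pd.DataFrame:
    labels = sorted(RESPONSE_LIFESTYLE_VOCAB) + ["diet_control_unspecified"]
    return _label_frequencies(frame, "lifestyle_suggestions", labels)


def drug_recommendation_frequencies(frame: pd.DataFrame) -> pd.DataFrame:
    """Share of each drug class among medication-suggesting responses."""
    sub = frame[frame["medication_suggested"]]
    return _label_frequencies(sub, "drugs_recommended", sorted(DRUG_VOCAB))


def medication_rate_by_severity(frame: pd.DataFrame) -> pd.DataFrame:
    """Fraction of responses (to posts with a TG value) that suggest drugs,
    per severity stratum of the post."""
    sub = frame[frame["severity"].notna()]
    rows = []
    for s in SEVERITY_CLASSES:
        stratum = sub[sub["severity"] == s]
        n = len(stratum)
        k = int(stratum["medication_suggested"].sum())
        rows.append({"severity": s, "n_responses": n,
                     "medication_rate": (k / n) if n else float("nan"),
                     "medication_pct": percent(k, n, 1) if n else float("nan")})
    return pd.DataFrame(rows)


def mean_response_word_count(frame: pd.DataFrame) -> dict[str, float]:
    return {
        str(pt): _round_half_up(float(sub["word_count"].mean()), 1)
        for pt, sub in frame.groupby("platform_type")
        if len(sub)
    }


def annual_volume(posts: Iterable[RawPost]) -> pd.DataFrame:
    """Post counts per year (2004-2020) and platform type; missing years are 0."""
    counts: dict[tuple[int, str], int] = {}
    ptypes = set()
    for p in posts:
        pt = p.platform.platform_type.value
        ptypes.add(pt)
        counts[(p.year, pt)] = counts.get((p.year, pt), 0) + 1
    cols = sorted(ptypes) or ["qa_search", "online_consultation"]
    df = pd.DataFrame(
        {pt: [counts.get((y, pt), 0) for y in YEARS] for pt in cols}, index=list(YEARS)
    )
    df["total"] = df.sum(axis=1)
    return df


def keyword_frequency(
    texts: Iterable[str],
    lexicon: Lexicon,
    stoplist: Sequence[str] = (),
    extra_terms: Sequence[str] = (),
) -> list[tuple[str, int]]:
    """Total substring occurrence counts of lexicon (plus extra) terms,
    stoplist removed, in descending count order (ties alphabetical)."""
    terms = sorted(
        {t for cat_terms in lexicon.categories.values() for t in cat_terms}
        | set(extra_terms)
    )
    stop = set(stoplist)
    counts: dict[str, int] = {t: 0 for t in terms if t not in stop}
    for raw in texts:
        text = normalize_text(raw)
        for t in counts:
            counts[t] += text.count(t)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


_SEVERITY_REP_TG = {"edge": 2.0, "mild_moderate": 3.0, "severe": 8.0}


def records_from_cohort_counts(severity_table: dict) -> list[PatientRecord]:
    """Expand published cohort x severity counts into individual records.

    ``severity_table`` maps the two exclusive cohorts (tg_only, tg_plus_chol)
    and their pregnant sub-cohorts to per-severity counts; pregnant rows are
    subsets, so only (cohort - pregnant) non-pregnant records are created.
    Used to drive :func:`severity_distribution` additivity checks.
    """
    recs: list[PatientRecord] = []
    i = 0
    for htg in ("tg_only", "tg_plus_chol"):
        cohort = severity_table[htg]
        pregnant_cohort = severity_table.get(f"pregnant_{htg}", {})
        for severity, n in cohort.items():
            n_pregnant = int(pregnant_cohort.get(severity, 0))
            if n_pregnant > n:
                raise ValueError(f"pregnant subset exceeds cohort for {htg}/{severity}")
            for pregnant in (False, True):
                count = (n - n_pregnant) if not pregnant else n_pregnant
                for _ in range(count):
                    recs.append(
                        PatientRecord(
                            post_id=f"c{i:07d}",
                            pregnant=pregnant,
                            tg_mmol_per_l=[_SEVERITY_REP_TG[severity]],
                            chol_elevated=htg == "tg_plus_chol",
                            severity=severity,
                            htg_type=htg,
                        )
                    )
                    i += 1
    return recs


# ---------------------------------------------------------------------------
# consistency checks against published counts


@dataclass
class ConsistencyResult:
    check_id: str
    name: str
    inputs: dict
    computed: float
    expected: float
    passed: bool


def published_counts_path() -> Path:
    return data_path("published_counts.json")


def _evaluate_check(check: dict) -> float:
    op = check["op"]
    if op == "percent":
        return percent(check["numerator"], check["denominator"], check["decimals"])
    if op == "sum":
        return float(sum(check["terms"]))
    if op == "rate":
        denom = check["platform_share"] * check["total_queries"]
        return _round_half_up(check["responses"] / denom, check["decimals"])
    raise ValueError(f"unknown consistency-check op {op!r}")


def run_consistency_checks(path: Optional[str | Path] = None) -> list[ConsistencyResult]:
    """Recompute every published summary quantity and compare to its printed
    value.  Pass tolerance is half a unit in the last printed decimal for
    ratios, exact for counts."""
    path = Path(path) if path is not None else published_counts_path()
    if not path.exists():
        raise FileNotFoundError(f"published-counts file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        spec = json.load(fh)
    results: list[ConsistencyResult] = []
    for check in spec.get("checks", []):
        computed = _evaluate_check(check)
        expected = float(check["expected"])
        if check["op"] == "sum":
            tol = 0.0
        else:
            tol = 0.5 * 10 ** (-check["decimals"])
        inputs = {k: v for k, v in check.items() if k not in ("id", "name", "op", "expected")}
        results.append(
            ConsistencyResult(
                check_id=check["id"],
                name=check["name"],
                inputs=inputs,
                computed=computed,
                expected=expected,
                passed=abs(computed - expected) <= tol,
            )
        )
    return results
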