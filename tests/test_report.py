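import json
from collections import Counter

import pytest

from tglisten import report as rm
from tglisten.extraction import PatientRecord
from tglisten.pipeline import run_pipeline


@pytest.fixture(scope="module")
def pipeline_result(lexicon):
    from tglisten.synthgen import GeneratorConfig, generate
    from tests.conftest import NO_CONTAMINATION

    posts, truth = generate(GeneratorConfig(n_posts=600, seed=13, contamination=NO_CONTAMINATION))
    result = run_pipeline(posts, lexicon)
    kept_ids = {r.post_id for r in result.records}
    kept_posts = [p for p in posts if p.post_id in kept_ids]
    frame = rm.responses_frame(kept_posts, result.response_contents, result.records)
    return posts, truth, result, frame


class TestPercent:
    def test_printed_examples(self):
        assert rm.percent(4788, 26603, 1) == 18.0
        assert rm.percent(7495, 13155, 2) == 56.97

    def test_zero_numerator(self):
        assert rm.percent(0, 5, 1) == 0.0

    def test_half_up(self):
        assert rm.percent(1, 8, 1) == 12.5
        assert rm.percent(1, 16, 1) == 6.3  # 6.25 rounds up, not banker's

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            rm.percent(1, 0, 1)


class TestSeverityDistribution:
    def test_empty_input(self):
        table = rm.severity_distribution([])
        assert int(table["n"].sum()) == 0

    def test_additivity_and_subset_rows(self, pipeline_result):
        _, _, result, _ = pipeline_result
        table = rm.severity_distribution(result.records)
        for severity in ("edge", "mild_moderate", "severe"):
            assert (
                table.loc["total", severity]
                == table.loc["tg_only", severity] + table.loc["tg_plus_chol", severity]
            )
            assert table.loc["pregnant_tg_only", severity] <= table.loc["tg_only", severity]

    def test_total_conservation(self, pipeline_result):
        _, _, result, _ = pipeline_result
        table = rm.severity_distribution(result.records)
        n_with_tg = sum(1 for r in result.records if r.tg_mmol_per_l)
        assert int(table.loc["total", "n"]) == n_with_tg

    def test_brute_force_recount(self, pipeline_result):
        _, _, result, _ = pipeline_result
        table = rm.severity_distribution(result.records)
        brute = Counter(
            (r.htg_type, r.severity) for r in result.records if r.tg_mmol_per_l
        )
        for htg in ("tg_only", "tg_plus_chol"):
            for severity in ("edge", "mild_moderate", "severe"):
                assert table.loc[htg, severity] == brute[(htg, severity)]

    def test_percent_closure(self, pipeline_result):
        _, _, result, _ = pipeline_result
        table = rm.severity_distribution(result.records)
        for row in table.index:
            if table.loc[row, "n"]:
                total = sum(table.loc[row, f"{s}_pct"] for s in ("edge", "mild_moderate", "severe"))
                assert abs(total - 100.0) <= 0.2


class TestDemandTables:
    def test_single_demand_ranked_first(self):
        records = [
            PatientRecord(post_id=f"p{i}", demand="medication",
                          demand_group="drug_intervention")
            for i in range(5)
        ]
        table = rm.demand_ranking(records)
        assert table.iloc[0]["demand"] == "medication"

    def test_tie_broken_by_priority(self):
        records = [
            PatientRecord(post_id="a", demand="drug_selection", demand_group="drug_intervention"),
            PatientRecord(post_id="b", demand="how_to_treat", demand_group="how_to_intervene"),
        ]
        table = rm.demand_ranking(records)
        assert list(table["demand"][:2]) == ["how_to_treat", "drug_selection"]

    def test_brute_force_recount(self, pipeline_result):
        _, _, result, _ = pipeline_result
        table = rm.demand_ranking(result.records)
        brute = Counter(r.demand for r in result.records if r.demand)
        for _, row in table.iterrows():
            assert row["count"] == brute[row["demand"]]

    def test_by_age_excludes_unknown_and_closes(self, pipeline_result):
        _, _, result, _ = pipeline_result
        table = rm.demand_by_age(result.records)
        for col in table.columns:
            assert abs(table[col].sum() - 100.0) <= 0.2

    def test_by_severity_closes(self, pipeline_result):
        _, _, result, _ = pipeline_result
        table = rm.demand_by_severity(result.records)
        for col in table.columns:
            assert abs(table[col].sum() - 100.0) <= 0.2

    def test_all_under_split_yields_one_column(self):
        records = [
            PatientRecord(post_id=f"p{i}", age_years=30, demand="medication",
                          demand_group="drug_intervention")
            for i in range(4)
        ]
        table = rm.demand_by_age(records)
        assert list(table.columns) == ["under_50"]


class TestResponseTables:
    def test_response_rates_single(self, post_factory):
        posts = [post_factory(post_id=f"p{i}", responses=["ok"]) for i in range(5)]
        assert rm.response_rates(posts) == {"qa_search": 1.0}

    def test_response_rates_brute(self, pipeline_result):
        posts, _, _, _ = pipeline_result
        rates = rm.response_rates(posts)
        for ptype, rate in rates.items():
            sub = [p for p in posts if p.platform.platform_type.value == ptype]
            expected = sum(len(p.responses) for p in sub) / len(sub)
            assert abs(rate - expected) <= 0.005

    def test_medication_rate_extremes(self, pipeline_result, post_factory):
        from tglisten.extraction import ResponseContent

        posts = [post_factory(post_id="p0", responses=["take simvastatin"])]
        records = [PatientRecord(post_id="p0", tg_mmol_per_l=[6.0], severity="severe",
                                 htg_type="tg_only")]
        contents = [ResponseContent(response_id="p0r0", drugs_recommended=["statin"])]
        frame = rm.responses_frame(posts, contents, records)
        table = rm.medication_rate_by_severity(frame)
        severe = table[table["severity"] == "severe"].iloc[0]
        assert severe["medication_rate"] == 1.0

    def test_orphan_response_raises(self, post_factory):
        from tglisten.extraction import ResponseContent

        posts = [post_factory(post_id="p0")]
        contents = [ResponseContent(response_id="ghost")]
        with pytest.raises(KeyError):
            rm.responses_frame(posts, contents)

    def test_lifestyle_frequencies_multi_select(self, pipeline_result):
        _, _, _, frame = pipeline_result
        table = rm.lifestyle_suggestion_frequencies(frame)
        assert table.attrs["multi_select"]
        assert (table.values >= 0).all() and (table.values <= 100).all()


class TestAnnualVolume:
    def test_empty_is_17_zeros(self):
        table = rm.annual_volume([])
        assert len(table) == 17
        assert int(table["total"].sum()) == 0

    def test_conservation_and_histogram_oracle(self, pipeline_result):
        posts, _, _, _ = pipeline_result
        table = rm.annual_volume(posts)
        assert int(table["total"].sum()) == len(posts)
        brute = Counter(p.year for p in posts)
        for year in range(2004, 2021):
            assert int(table.loc[year, "total"]) == brute.get(year, 0)


class TestKeywordFrequency:
    def test_repeated_term_ranks_first(self, lexicon):
        texts = ["diet diet diet", "diet and tg"]
        ranked = rm.keyword_frequency(texts, lexicon)
        assert ranked[0][0] == "diet"

    def test_counting_oracle(self, lexicon, pipeline_result):
        posts, _, _, _ = pipeline_result
        texts = [p.query_text for p in posts[:100]]
        ranked = dict(rm.keyword_frequency(texts, lexicon))
        from tglisten.corpus_model import normalize_text

        for term in ("triglyceride", "diet", "fenofibrate"):
            brute = sum(normalize_text(t).count(term) for t in texts)
            assert ranked[term] == brute

    def test_stoplist_monotone(self, lexicon):
        texts = ["diet and tg and food"]
        full = dict(rm.keyword_frequency(texts, lexicon))
        stopped = dict(rm.keyword_frequency(texts, lexicon, stoplist=["diet"]))
        assert "diet" not in stopped
        assert all(stopped[t] == full[t] for t in stopped)


class TestConsistencyChecks:
    def test_bundled_all_pass(self):
        results = rm.run_consistency_checks()
        assert len(results) == 12
        assert all(r.passed for r in results)

    def test_perturbed_count_fails(self, tmp_path):
        with open(rm.published_counts_path()) as fh:
            spec = json.load(fh)
        t5 = next(c for c in spec["checks"] if c["id"] == "t5")
        t5["terms"][0] += 1
        path = tmp_path / "counts.json"
        path.write_text(json.dumps(spec))
        results = rm.run_consistency_checks(path)
        assert not next(r for r in results if r.check_id == "t5").passed

    def test_empty_check_file(self, tmp_path):
        path = tmp_path / "counts.json"
        path.write_text(json.dumps({"checks": []}))
        assert rm.run_consistency_checks(path) == []

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            rm.run_consistency_checks(tmp_path / "nope.json")
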