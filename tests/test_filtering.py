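import pytest
from hypothesis import given, strategies as st

from tglisten.filtering import (
    FilterRule,
    Verdict,
    apply_filters,
    classify,
    drop_duplicates,
    is_advertisement,
    is_non_topic,
    is_popular_science,
    train_stand_in_classifier,
)
from tglisten.synthgen import GeneratorConfig, generate

# Hand-labeled fixture: (text, is_advertisement, is_popular_science).
# Labels were written against the rule definitions (marker present AND no
# personal-condition evidence), not against the implementation.
LABELED_POSTS = [
    ("click http://miracle-lipid.example for a miracle lipid cure", True, False),
    ("our clinic treats high tg, order now at www.lipid-shop.example", True, False),
    ("special offer on triglyceride capsules, visit www.deal.example", True, False),
    ("free trial of our product for thick blood lipids, add the group now", True, False),
    ("discount on lipid tests this week, click the link to book", True, False),
    ("join us: https://lipidclass.example teaches about triglycerides", True, False),
    ("our product balances blood lipid levels, order now", True, False),
    ("tg management program, scan the code to enroll today", True, False),
    ("best fenofibrate prices, www.pharmacy-deal.example", True, False),
    ("special offer: fish oil bundles at http://o3.example", True, False),
    ("lipid panel discount for members, click the link", True, False),
    ("add the group for daily diet plans against high tg", True, False),
    ("our clinic now offers online tg consults, free trial available", True, False),
    ("order now: lipanthyl substitutes at https://sub.example", True, False),
    # marker present but condition evidence present -> not an advertisement
    ("my tg is 3.1 mmol/l, see http://report-link.example", False, False),
    ("my father has high tg, someone sent www.cure.example, is it real?", False, False),
    # popular science: definitional phrasing, no personal condition
    ("triglycerides are a type of blood fat found in the body", False, True),
    ("hypertriglyceridemia refers to elevated triglycerides in plasma", False, True),
    ("this article reviews diet advice for high tg", False, True),
    ("health knowledge: triglyceride is a kind of stored energy", False, True),
    ("encyclopedia entry: mixed hyperlipidemia and its diagnosis", False, True),
    ("fenofibrate is a kind of fibrate used to lower triglycerides", False, True),
    ("blood lipid basics, in this popular science post we cover tg", False, True),
    ("let us explain what triacylglycerol does in the body", False, True),
    ("this article compares statins for dyslipidemia", False, True),
    ("tg metabolism refers to how the body processes dietary fat", False, True),
    ("health knowledge: thick blood lipids explained for beginners", False, True),
    ("diet and triglycerides, this article lists common food myths", False, True),
    ("hyperlipidemia refers to several distinct lipid disorders", False, True),
    # science phrasing defeated by personal condition evidence
    ("triglycerides are a type of blood fat; my level is 2.8 mmol/l", False, False),
    ("this article helped, but my tg is still 4.2, what now?", False, False),
    # ordinary consultations: neither rule fires
    ("my tg was 2.9 mmol/l last week, how to treat this?", False, False),
    ("i am a 40 year old man, triglyceride 6.1 mmol/l, need medication?", False, False),
    ("my mother has dizziness and her tg is 3.3, what should we do?", False, False),
    ("tg 1.9 and cholesterol high, what can i not eat?", False, False),
    ("doctor said mixed hyperlipidemia, my tg is 5.8, is that severe?", False, False),
    ("triglyceride 2.2 mmol/l while 12 weeks pregnant, is it risky?", False, False),
    ("after my myocardial infarction my tg stays at 2.6", False, False),
    ("i have chest tightness and a tg of 7.4 mmol/l", False, False),
    ("my wife is 55 years old, her triglyceride is 3.0, which drug is best?", False, False),
]
assert len(LABELED_POSTS) == 40


class TestDropDuplicates:
    def test_first_in_wins(self, post_factory):
        posts = [post_factory(post_id=i, text=i) for i in ["a", "b", "a", "c", "b"]]
        kept, decisions = drop_duplicates(posts)
        assert [p.post_id for p in kept] == ["a", "b", "c"]
        assert sum(d.verdict is Verdict.drop for d in decisions) == 2
        assert all(
            d.rule_fired is FilterRule.duplicate
            for d in decisions
            if d.verdict is Verdict.drop
        )

    def test_all_unique(self, post_factory):
        posts = [post_factory(post_id=f"p{i}") for i in range(10)]
        kept, decisions = drop_duplicates(posts)
        assert len(kept) == 10
        assert all(d.verdict is Verdict.keep for d in decisions)

    @given(ids=st.lists(st.sampled_from("abcdefgh"), max_size=60))
    def test_set_oracle(self, ids):
        from tglisten.corpus_model import Platform, PlatformType, RawPost

        posts = [
            RawPost(
                post_id=i,
                platform=Platform(name="t", platform_type=PlatformType.qa_search),
                year=2015,
                query_text="",
            )
            for i in ids
        ]
        kept, decisions = drop_duplicates(posts)
        seen, expected = set(), []
        for i in ids:
            if i not in seen:
                seen.add(i)
                expected.append(i)
        assert [p.post_id for p in kept] == expected
        assert len(decisions) == len(ids)


class TestRulePredicates:
    @pytest.mark.parametrize("text,is_ad,is_sci", LABELED_POSTS)
    def test_labeled_fixture(self, text, is_ad, is_sci, lexicon, post_factory):
        post = post_factory(text=text)
        assert is_advertisement(post, lexicon) == is_ad
        assert is_popular_science(post, lexicon=lexicon) == is_sci

    def test_non_topic_all_below_threshold(self, lexicon, post_factory):
        assert is_non_topic(post_factory(text="tg 1.5 mmol/l, is this fine?"), lexicon)

    def test_non_topic_any_above_keeps(self, lexicon, post_factory):
        post = post_factory(text="tg was 1.5 last year, now 2.4")
        assert not is_non_topic(post, lexicon)

    def test_non_topic_needs_a_value(self, lexicon, post_factory):
        assert not is_non_topic(post_factory(text="my tg is high"), lexicon)

    def test_exactly_low_tg_contaminants_flagged(self, lexicon, mixed_corpus):
        posts, truth, _ = mixed_corpus
        low_ids = {
            r.post_id for r in truth.contaminants if r.contaminant_kind == "non_topic"
        }
        flagged = {p.post_id for p in posts if is_non_topic(p, lexicon)}
        assert flagged == low_ids


class TestApplyFilters:
    def test_clean_corpus_all_kept(self, lexicon, clean_corpus):
        posts, _, _ = clean_corpus
        kept, decisions = apply_filters(posts, lexicon)
        assert len(kept) == len(posts)
        assert all(d.verdict is Verdict.keep for d in decisions)

    def test_decision_completeness(self, lexicon, mixed_corpus):
        posts, _, _ = mixed_corpus
        kept, decisions = apply_filters(posts, lexicon)
        assert len(decisions) == len(posts)
        n_drop = sum(d.verdict is Verdict.drop for d in decisions)
        assert len(kept) + n_drop == len(posts)

    def test_idempotent_on_kept(self, lexicon, mixed_corpus):
        posts, _, _ = mixed_corpus
        kept, _ = apply_filters(posts, lexicon)
        kept2, decisions2 = apply_filters(kept, lexicon)
        assert kept2 == kept
        assert all(d.verdict is Verdict.keep for d in decisions2)

    def test_order_invariance_of_verdicts(self, lexicon, mixed_corpus):
        posts, _, _ = mixed_corpus
        _, d1 = apply_filters(posts, lexicon)
        _, d2 = apply_filters(list(reversed(posts)), lexicon)

        def non_dup_verdicts(ds):
            return {
                d.post_id: d.rule_fired
                for d in ds
                if d.rule_fired is not FilterRule.duplicate and d.verdict is Verdict.drop
            }

        assert non_dup_verdicts(d1) == non_dup_verdicts(d2)


class TestStandInClassifier:
    @staticmethod
    def _labeled(n, seed):
        posts, truth = generate(
            GeneratorConfig(
                n_posts=n,
                seed=seed,
                contamination={"duplicate_rate": 0, "ad_rate": 1.0,
                               "science_rate": 0, "low_tg_rate": 0},
            )
        )
        ads = {r.post_id for r in truth.contaminants}
        return [
            (p.query_text, "ad" if p.post_id in ads else "consultation") for p in posts
        ]

    def test_holdout_accuracy(self):
        train = self._labeled(100, seed=5)   # ~200 posts: 100 clean + ~100 ads
        test = self._labeled(50, seed=6)
        clf = train_stand_in_classifier(train)
        accuracy = sum(classify(clf, t) == lab for t, lab in test) / len(test)
        assert accuracy >= 0.9

    def test_reproduces_training_labels(self):
        train = self._labeled(40, seed=7)
        clf = train_stand_in_classifier(train)
        assert all(classify(clf, t) == lab for t, lab in train)

    def test_deterministic_retrain(self):
        train = self._labeled(40, seed=8)
        c1, c2 = train_stand_in_classifier(train), train_stand_in_classifier(train)
        probe = [t for t, _ in self._labeled(20, seed=9)]
        assert [classify(c1, t) for t in probe] == [classify(c2, t) for t in probe]

    def test_single_label_raises(self):
        with pytest.raises(ValueError):
            train_stand_in_classifier([("a", "x"), ("b", "x")])
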