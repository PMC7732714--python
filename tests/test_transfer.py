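import itertools

import numpy as np
import pytest

from opirisk.corpus_io import Post, PredictionRecord
from opirisk.classifiers import ModelFamily, ModelSpec, SplitSpec
from opirisk.features import FeatureCombination
from opirisk.synthetic import GeneratorConfig, generate_corpus
from opirisk.transfer import (
    C1_KEYWORDS,
    C2_KEYWORDS,
    CaseConfig,
    SampleSpec,
    contains_keyword,
    heuristic_labels,
    keyword_sample,
    majority_label,
    ratio_curve,
    run_case,
    stratified_accuracy,
)


def _post(body, pid="p0", title=""):
    return Post(id=pid, community="opiates", title=title, body=body)


class TestContainsKeyword:
    def test_phrase_match(self):
        assert contains_keyword(_post("i want to die tonight"), C1_KEYWORDS)

    def test_single_token_and_boundary_rule(self):
        assert contains_keyword(_post("my suicidality is worse"), C1_KEYWORDS)
        # "suicidal thoughts" contains the token "suicidal" but not "suicide"
        assert contains_keyword(_post("having suicidal thoughts"), ["suicidal"])
        assert not contains_keyword(_post("having suicidal thoughts"), ["suicide"])

    def test_drug_slang_in_c2_list(self):
        assert contains_keyword(_post("took some hydros last night"), C2_KEYWORDS)

    def test_case_insensitive_and_title(self):
        assert contains_keyword(_post("nothing here", title="About Fentanyl"),
                                C2_KEYWORDS)

    def test_empty_keyword_list_never_matches(self):
        assert not contains_keyword(_post("commit suicide"), [])

    def test_phrase_must_be_contiguous(self):
        assert not contains_keyword(_post("want you to die"), ["want to die"])


class TestKeywordSample:
    @staticmethod
    def _pool(n_kw, n_plain, words=60, seed=0):
        rng = np.random.default_rng(seed)
        posts = []
        filler = ["filler"] * (words - 1)
        for i in range(n_kw):
            body = " ".join(filler[: words - 3] + ["want", "to", "die"])
            posts.append(Post(id=f"k{i}", community="opiates", title="t", body=body))
        for i in range(n_plain):
            posts.append(Post(id=f"n{i}", community="opiates", title="t",
                              body=" ".join(filler)))
        return posts

    def test_cap_binds_with_abundant_keyword_posts(self):
        pool = self._pool(1200, 1200)
        sample = keyword_sample(pool, SampleSpec(seed=1), C1_KEYWORDS)
        kw_flags = [contains_keyword(p, C1_KEYWORDS) for p in sample]
        assert len(sample) == 500
        assert sum(kw_flags) == 250

    def test_cap_not_binding_includes_all_keyword_posts(self):
        pool = self._pool(100, 1000)
        sample = keyword_sample(pool, SampleSpec(seed=1), C1_KEYWORDS)
        kw_flags = [contains_keyword(p, C1_KEYWORDS) for p in sample]
        assert len(sample) == 500
        assert sum(kw_flags) == 100

    def test_word_window_enforced(self):
        long_body = " ".join(["w"] * 800)
        short_body = "tiny"
        pool = self._pool(300, 600)
        pool.append(Post(id="long", community="x", title="", body=long_body))
        pool.append(Post(id="short", community="x", title="", body=short_body))
        sample = keyword_sample(pool, SampleSpec(seed=2), C1_KEYWORDS)
        ids = {p.id for p in sample}
        assert "long" not in ids and "short" not in ids
        from opirisk.preprocessing import word_count
        assert all(30 <= word_count(p) <= 500 for p in sample)

    def test_reproducible_given_seed(self):
        pool = self._pool(600, 600)
        s1 = keyword_sample(pool, SampleSpec(seed=9), C1_KEYWORDS)
        s2 = keyword_sample(pool, SampleSpec(seed=9), C1_KEYWORDS)
        assert [p.id for p in s1] == [p.id for p in s2]

    def test_short_pool_raises_with_shortfall(self):
        pool = self._pool(10, 10)
        with pytest.raises(ValueError, match="20"):
            keyword_sample(pool, SampleSpec(seed=1), C1_KEYWORDS)


class TestMajority:
    def test_all_triples_by_exhaustive_enumeration(self):
        for votes in itertools.product([0, 1], repeat=3):
            assert majority_label(votes) == int(sum(votes) >= 2)
            for perm in itertools.permutations(votes):
                assert majority_label(perm) == majority_label(votes)

    def test_even_vote_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            majority_label([0, 1])

    def test_single_vote_is_identity(self):
        assert majority_label([1]) == 1 and majority_label([0]) == 0


class TestHeuristicLabels:
    def test_drug_keyword_flags_post(self):
        posts = [_post("got fentanyl", pid="a"), _post("feeling sad", pid="b")]
        assert heuristic_labels(posts, C2_KEYWORDS).tolist() == [1, 0]

    def test_agrees_with_latent_truth_at_full_inclusion(self):
        """With keyword inclusion 1.0 and full separability, the keyword
        heuristic recovers the latent opioid flag exactly."""
        posts, truths = generate_corpus(GeneratorConfig(
            seed=5, keyword_inclusion_rate=1.0, separability=1.0,
            n_posts_per_group={"suicidewatch": 150, "depression": 150,
                               "control": 150, "opiates": 150}))
        labels = heuristic_labels(posts, C2_KEYWORDS)
        flags = np.asarray([t.is_opioid for t in truths], dtype=int)
        assert (labels == flags).all()


class TestStratifiedAccuracy:
    @staticmethod
    def _records(scores, ids=None):
        return [PredictionRecord(id=ids[i] if ids else f"p{i}", score=s)
                for i, s in enumerate(scores)]

    def test_perfect_predictor(self):
        recs = self._records([0.1, 0.9, 0.2, 0.8])
        out = stratified_accuracy(recs, [1, 0, 1, 0])
        assert (out.all_data, out.positive_only, out.negative_only) == (1, 1, 1)
        assert out.predicted_positive_count == 2

    def test_always_negative_on_120_of_500_positives(self):
        recs = self._records([0.9] * 500)
        labels = [1] * 120 + [0] * 380
        out = stratified_accuracy(recs, labels)
        assert out.all_data == pytest.approx(0.76)
        assert out.positive_only == 0.0
        assert out.negative_only == 1.0
        assert out.predicted_positive_count == 0

    def test_all_data_is_prevalence_weighted_mean(self, rng):
        scores = rng.random(400)
        labels = rng.integers(0, 2, size=400)
        out = stratified_accuracy(self._records(scores), labels)
        prev = labels.mean()
        combined = prev * out.positive_only + (1 - prev) * out.negative_only
        assert abs(out.all_data - combined) < 1e-12

    def test_empty_stratum_reported_missing(self):
        out = stratified_accuracy(self._records([0.4, 0.3]), [1, 1])
        assert out.negative_only is None


class TestRatioCurve:
    @staticmethod
    def _known_accuracy_records(a_pos, a_neg, n=400, seed=0):
        """Predictor correct on a fraction a± of each stratum, exactly."""
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        scores = np.empty(n)
        k = int(a_pos * (n // 2))
        scores[: n // 2] = [0.1] * k + [0.9] * (n // 2 - k)
        k = int(a_neg * (n // 2))
        scores[n // 2:] = [0.9] * k + [0.1] * (n // 2 - k)
        recs = [PredictionRecord(id=f"p{i}", score=float(s))
                for i, s in enumerate(scores)]
        return recs, labels

    def test_expectation_identity_within_3_se(self):
        a_pos, a_neg = 1.0, 0.0
        recs, labels = self._known_accuracy_records(a_pos, a_neg)
        curve = ratio_curve(recs, labels, n_rows=500, n_reps=200, seed=3)
        for r, acc in curve.items():
            expect = r * a_pos + (1 - r) * a_neg
            se = np.sqrt(max(expect * (1 - expect), 1e-6) / (500 * 200))
            assert abs(acc - expect) < max(3 * se, 5e-3)

    def test_symmetric_predictor_flat_at_half(self):
        recs, labels = self._known_accuracy_records(0.8, 0.8)
        curve = ratio_curve(recs, labels, ratios=[0.5], n_rows=500, n_reps=50,
                            seed=1)
        assert curve[0.5] == pytest.approx(0.8, abs=0.02)

    def test_monotone_when_positive_accuracy_dominates(self):
        recs, labels = self._known_accuracy_records(0.9, 0.3)
        curve = ratio_curve(recs, labels, n_rows=500, n_reps=200, seed=2)
        values = [curve[r] for r in sorted(curve)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_single_class_pool_rejected(self):
        recs, _ = self._known_accuracy_records(1, 1, n=10)
        with pytest.raises(ValueError):
            ratio_curve(recs, [1] * 10)


class TestRunCase:
    @pytest.fixture(scope="class")
    @staticmethod
    def corpus():
        return generate_corpus(GeneratorConfig(
            seed=23, separability=0.95,
            n_posts_per_group={"suicidewatch": 150, "depression": 150,
                               "control": 150, "opiates": 150},
            length_distribution=(30, 400, 120.0, 0.6)))

    def test_c1_scores_only_opiates_posts_in_window(self, corpus):
        posts, _ = corpus
        spec = ModelSpec(family=ModelFamily.LR,
                         combination=FeatureCombination.TFIDF, seed=0)
        result = run_case(CaseConfig.c1(), posts, [spec], SplitSpec(seed=0))
        target_ids = {p.id for p in posts if p.group == "opiates"}
        (label, records), = result.predictions.items()
        assert {r.id for r in records} <= target_ids
        assert result.in_sample_reports[label].f1 > 0.9

    def test_suicidal_opiates_posts_score_lower(self, corpus):
        """Latently suicidal opioid posts receive lower (riskier) scores on
        average than non-suicidal ones under the transferred model."""
        posts, truths = corpus
        spec = ModelSpec(family=ModelFamily.LR,
                         combination=FeatureCombination.TFIDF, seed=0)
        result = run_case(CaseConfig.c1(), posts, [spec], SplitSpec(seed=0))
        (_, records), = result.predictions.items()
        flag = {t.post_id: t.is_suicidal for t in truths}
        risky = [r.score for r in records if flag[r.id]]
        calm = [r.score for r in records if not flag[r.id]]
        assert np.mean(risky) < np.mean(calm)

    def test_c2_is_c1_with_groups_swapped(self, corpus):
        posts, _ = corpus
        spec = ModelSpec(family=ModelFamily.LR,
                         combination=FeatureCombination.TFIDF, seed=0)
        result = run_case(CaseConfig.c2(), posts, [spec], SplitSpec(seed=0))
        target_ids = {p.id for p in posts if p.group == "suicidewatch"}
        (_, records), = result.predictions.items()
        assert {r.id for r in records} <= target_ids

    def test_empty_target_group_rejected(self, corpus):
        posts, _ = corpus
        no_target = [p for p in posts if p.group != "opiates"]
        spec = ModelSpec(family=ModelFamily.LR,
                         combination=FeatureCombination.TFIDF, seed=0)
        with pytest.raises(ValueError, match="target group"):
            run_case(CaseConfig.c1(), no_target, [spec])


def test_majority_labels_equal_truth_with_perfect_annotators():
    from opirisk.synthetic import AnnotatorConfig, simulate_annotations

    posts, truths = generate_corpus(GeneratorConfig(
        seed=31, n_posts_per_group={"suicidewatch": 80, "depression": 0,
                                    "control": 80, "opiates": 0}))
    votes = simulate_annotations(posts, truths,
                                 AnnotatorConfig(sensitivity=1.0, specificity=1.0))
    flags = np.asarray([t.is_suicidal for t in truths], dtype=int)
    majorities = np.asarray([majority_label(v) for v in votes])
    assert (majorities == flags).all()
    # stratified accuracy against majority labels equals that against truth
    rng = np.random.default_rng(0)
    recs = [PredictionRecord(id=p.id, score=float(s))
            for p, s in zip(posts, rng.random(len(posts)))]
    a = stratified_accuracy(recs, flags)
    b = stratified_accuracy(recs, majorities)
    assert a == b
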