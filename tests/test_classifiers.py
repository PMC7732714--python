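import numpy as np
import pytest

from opirisk.classifiers import (
    EvalReport,
    ModelFamily,
    ModelSpec,
    SplitSpec,
    evaluate,
    grid_run,
    split,
    train,
)
from opirisk.corpus_io import PredictionRecord
from opirisk.features import FeatureCombination
from opirisk.preprocessing import TokenizedDocument


class TestSplit:
    def test_balanced_100_gives_64_16_20(self):
        docs = [TokenizedDocument(f"d{i}", ["x"]) for i in range(100)]
        y = [i % 2 for i in range(100)]
        tr, ytr, va, yva, te, yte = split(docs, y, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (64, 16, 20)
        assert sum(ytr) == 32 and sum(yva) == 8 and sum(yte) == 10

    def test_same_seed_same_partition(self):
        docs = [TokenizedDocument(f"d{i}", ["x"]) for i in range(50)]
        y = [i % 2 for i in range(50)]
        a = split(docs, y, SplitSpec(seed=4))
        b = split(docs, y, SplitSpec(seed=4))
        assert [d.post_id for d in a[0]] == [d.post_id for d in b[0]]
        assert [d.post_id for d in a[4]] == [d.post_id for d in b[4]]

    def test_partitions_disjoint_exhaustive_and_stratified(self, rng):
        n = 1000
        docs = [TokenizedDocument(f"d{i}", ["x"]) for i in range(n)]
        y = list((rng.random(n) < 0.3).astype(int))
        tr, ytr, va, yva, te, yte = split(docs, y, SplitSpec(seed=2))
        ids = [d.post_id for part in (tr, va, te) for d in part]
        assert sorted(ids) == sorted(d.post_id for d in docs)
        for part, ypart, frac in ((tr, ytr, 0.64), (va, yva, 0.16), (te, yte, 0.20)):
            assert abs(len(part) - frac * n) <= 1
            assert abs(sum(ypart) - frac * sum(y)) <= 2

    def test_scarce_label_rejected(self):
        docs = [TokenizedDocument(f"d{i}", ["x"]) for i in range(20)]
        y = [0] * 16 + [1] * 4
        with pytest.raises(ValueError, match="at least 5"):
            split(docs, y)


class TestEvaluate:
    @staticmethod
    def _records_from_confusion(tp, fp, fn, tn):
        """Perfectly confident predictions realizing a confusion table."""
        y, p = [], []
        y += [1] * tp; p += [1.0] * tp
        y += [0] * fp; p += [1.0] * fp
        y += [1] * fn; p += [0.0] * fn
        y += [0] * tn; p += [0.0] * tn
        return np.asarray(y), np.asarray(p)

    def test_confusion_counts_give_expected_metrics(self):
        y, p = self._records_from_confusion(tp=8, fp=2, fn=2, tn=8)

        class Fake:
            def positive_probability(self, docs):
                return p

        rep = evaluate(Fake(), [None] * len(y), y)
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.8)
        # F1 is the harmonic mean of the reported precision and recall
        hm = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
        assert abs(rep.f1 - hm) < 1e-9

    def test_perfect_predictions_score_one(self):
        y = np.array([0, 1, 0, 1])

        class Fake:
            def positive_probability(self, docs):
                return y.astype(float)

        rep = evaluate(Fake(), [None] * 4, y)
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1, rep.auc) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_single_class_auc_is_missing(self):
        class Fake:
            def positive_probability(self, docs):
                return np.array([0.2, 0.7])

        rep = evaluate(Fake(), [None, None], np.array([1, 1]))
        assert rep.auc is None

    def test_auc_matches_pairwise_oracle(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        scores = rng.random(50)

        class Fake:
            def positive_probability(self, docs):
                return scores

        rep = evaluate(Fake(), [None] * 50, y)
        # O(n^2) oracle: P(score_pos > score_neg) + 0.5 P(tie)
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert rep.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_label_flip_complements_auc(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        scores = rng.random(40)

        class Fake:
            def positive_probability(self, docs):
                return scores

        a = evaluate(Fake(), [None] * 40, y).auc
        b = evaluate(Fake(), [None] * 40, 1 - y).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestTrainedModels:
    def test_lr_separates_linear_clusters(self, sw_control_docs):
        docs, y = sw_control_docs
        spec = ModelSpec(family=ModelFamily.LR, combination=FeatureCombination.TFIDF,
                         seed=0)
        tr, ytr, va, yva, te, yte = split(docs, y, SplitSpec(seed=0))
        model = train(spec, tr, ytr, va, yva)
        train_rep = evaluate(model, tr, ytr)
        assert train_rep.accuracy > 0.95

    def test_records_orientation_zero_means_positive(self, sw_control_docs):
        docs, y = sw_control_docs
        spec = ModelSpec(family=ModelFamily.LR, combination=FeatureCombination.TFIDF,
                         seed=0)
        tr, ytr, va, yva, te, yte = split(docs, y, SplitSpec(seed=0))
        model = train(spec, tr, ytr)
        records = model.predict_records(te, yte)
        p = model.positive_probability(te)
        for r, pi in zip(records, p):
            assert r.score == pytest.approx(1.0 - pi, abs=1e-6)
            assert r.predicted_class == (1 if r.score < 0.5 else 0)

    def test_nn_spec_trains_and_scores(self, sw_control_docs):
        docs, y = sw_control_docs
        spec = ModelSpec(family=ModelFamily.FAST, combination=FeatureCombination.W2V,
                         seed=0, sequence_length=64, epochs=8, batch_size=64,
                         lr=5e-2)
        tr, ytr, va, yva, te, yte = split(docs, y, SplitSpec(seed=0))
        model = train(spec, tr, ytr, va, yva)
        rep = evaluate(model, te, yte)
        assert rep.f1 > 0.85


class TestGridRun:
    def test_grid_shape_row_order_and_determinism(self, sw_control_docs):
        docs, y = sw_control_docs
        fams = [ModelFamily.LR, ModelFamily.RF]
        combos = [FeatureCombination.TFIDF, FeatureCombination.W2V]
        base = ModelSpec(family=ModelFamily.LR, seed=1, w2v_epochs=1)
        g1 = grid_run(docs, y, fams, combos, SplitSpec(seed=1), base_spec=base)
        g2 = grid_run(docs, y, fams, combos, SplitSpec(seed=1), base_spec=base)
        assert len(g1) == 4
        assert list(g1["family"]) == ["LR", "LR", "RF", "RF"]
        assert list(g1["combination"]) == ["tfidf", "w2v", "tfidf", "w2v"]
        assert np.allclose(g1["f1"], g2["f1"])

    def test_pretrained_combination_skipped_without_table(self, sw_control_docs):
        docs, y = sw_control_docs
        g = grid_run(docs, y, [ModelFamily.LR],
                     [FeatureCombination.TFIDF, FeatureCombination.TFIDF_GLOVE],
                     SplitSpec(seed=1))
        assert list(g["combination"]) == ["tfidf"]


def test_eval_report_roundtrip():
    rep = EvalReport(accuracy=0.9, precision=0.8, recall=0.7, f1=0.746, auc=None)
    d = rep.as_dict()
    assert d["auc"] is None and d["f1"] == 0.746
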