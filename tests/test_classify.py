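"""Classifier protocol: up-sampling, stratification, training, metrics."""

import numpy as np
import pytest

from vigitext import classify
from vigitext.classify import (
    ClassifierMetrics,
    LabeledExample,
    cross_validate,
    evaluate,
    label_matrix,
    metrics_from_scores,
    predict_labels,
    stratified_kfold,
    train,
    upsample_training_set,
)
from vigitext.labels import SYMPTOMS, label_vector
from vigitext.synthetic import SyntheticConfig, generate_corpus


def _example(text, *positives):
    return LabeledExample(text=text, labels=label_vector(positives))


class TestUpsampling:
    def test_balanced_input_is_fixed_point(self):
        rng = np.random.default_rng(0)
        examples = [
            _example("a", "fever"),
            _example("b", "pain"),
            _example("c", "fever"),
            _example("d", "pain"),
        ]
        out = upsample_training_set(examples, rng)
        assert sorted(e.text for e in out) == ["a", "b", "c", "d"]

    def test_minority_duplicated_to_majority_count(self):
        rng = np.random.default_rng(1)
        examples = [_example(f"f{i}", "fever") for i in range(10)]
        examples += [_example(f"p{i}", "pain") for i in range(2)]
        out = upsample_training_set(examples, rng)
        Y = label_matrix(out)
        assert Y[:, SYMPTOMS.index("pain")].sum() == 10
        assert Y[:, SYMPTOMS.index("fever")].sum() == 10

    def test_empty_input(self):
        assert upsample_training_set([], np.random.default_rng(0)) == []

    def test_zero_positive_class_warned_and_skipped(self):
        rng = np.random.default_rng(2)
        examples = [_example("a", "fever"), _example("b", "fever"), _example("c")]
        with pytest.warns(UserWarning):
            out = upsample_training_set(examples, rng)
        assert label_matrix(out)[:, SYMPTOMS.index("pain")].sum() == 0

    def test_cap_limits_duplication(self):
        rng = np.random.default_rng(3)
        examples = [_example(f"f{i}", "fever") for i in range(20)]
        examples += [_example("p0", "pain")]
        out = upsample_training_set(examples, rng, cap=5)
        assert label_matrix(out)[:, SYMPTOMS.index("pain")].sum() == 5

    def test_input_not_mutated(self):
        examples = [_example("a", "fever"), _example("b", "pain"), _example("c", "pain")]
        snapshot = list(examples)
        with pytest.warns(UserWarning):  # fixture leaves most classes empty
            upsample_training_set(examples, np.random.default_rng(4))
        assert examples == snapshot


class TestStratifiedKFold:
    def test_uniform_single_label_equal_folds(self):
        examples = [_example(f"t{i}", "fever") for i in range(10)]
        folds = stratified_kfold(examples, k=5, seed=0)
        sizes = sorted(len(te) for _, te in folds)
        assert sizes == [2, 2, 2, 2, 2]

    def test_all_negative_reduces_to_plain_kfold(self):
        examples = [_example(f"t{i}") for i in range(10)]
        folds = stratified_kfold(examples, k=5, seed=0)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(10))
        assert all(len(te) == 2 for _, te in folds)

    def test_folds_partition_ids(self, labeled_corpus_5k):
        examples = labeled_corpus_5k[:200]
        folds = stratified_kfold(examples, k=5, seed=1)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(200))
        for tr, te in folds:
            assert set(tr) & set(te) == set()

    def test_per_fold_prevalence_within_rounding(self):
        """Per-class positive proportions per fold deviate from the global
        proportion by at most one positive example per fold."""
        cfg = SyntheticConfig(n_messages=100, seed=4)
        msgs, recs = generate_corpus(cfg)
        examples = classify.examples_from_corpus(msgs, recs)
        Y = label_matrix(examples)
        folds = stratified_kfold(examples, k=5, seed=4)
        global_prev = Y.mean(axis=0)
        for _, te in folds:
            dev = np.abs(Y[te].mean(axis=0) - global_prev)
            assert (dev <= 1.0 / len(te) + 1e-9).all()

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold([_example("a")], k=5)


class _FixedScoreModel:
    degenerate_classes = ()

    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=float)

    def predict_scores(self, texts):
        return np.tile(self._scores, (len(texts), 1))


class TestTrainPredict:
    def test_separable_corpus_near_perfect_ranking(self, labeled_corpus_5k):
        """Unique surface phrases per class force near-perfect held-out AUC."""
        train_part = labeled_corpus_5k[:3000]
        test_part = labeled_corpus_5k[3000:4000]
        model = train(train_part, seed=0)
        metrics = evaluate(model, test_part)
        assert metrics.micro_auc >= 0.99

    def test_single_example_training_is_valid(self):
        model = train([_example("температура и озноб", "fever", "chills")], seed=0)
        scores = model.predict_scores(["температура"])
        assert scores.shape == (1, 12)
        assert np.all(scores >= 0) and np.all(scores <= 1)
        assert set(model.degenerate_classes) == set(SYMPTOMS)

    def test_label_shuffled_corpus_gives_chance_auc(self, labeled_corpus_5k):
        """Permutation null: with labels shuffled across messages the
        per-class (macro) AUC sits at chance.  The pooled micro-AUC is not
        0.5 under this null — pooling mixes class base rates, and prevalent
        classes keep higher scores — so chance level is asserted class-wise."""
        rng = np.random.default_rng(5)
        subset = labeled_corpus_5k[:2000]
        perm = rng.permutation(len(subset))
        shuffled = [
            LabeledExample(text=subset[i].text, labels=subset[perm[i]].labels)
            for i in range(len(subset))
        ]
        model = train(shuffled[:1500], seed=0)
        metrics = evaluate(model, shuffled[1500:])
        assert abs(metrics.macro_auc - 0.5) < 0.05

    def test_threshold_semantics(self):
        scores = [0.7, 0.2, 0.5, 0.49, 0.0, 1.0, 0.3, 0.9, 0.1, 0.6, 0.5, 0.8]
        model = _FixedScoreModel(scores)
        labels = predict_labels(model, "x", threshold=0.5)
        assert labels.tolist() == [s >= 0.5 for s in scores]
        assert predict_labels(model, "x", threshold=0.0).all()
        assert not predict_labels(model, "x", threshold=1.0)[:5].any()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(6)
        model = _FixedScoreModel(rng.random(12))
        previous = 13
        for t in np.linspace(0, 1, 21):
            n_pos = predict_labels(model, "x", threshold=t).sum()
            assert n_pos <= previous
            previous = n_pos

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            predict_labels(_FixedScoreModel(np.zeros(12)), "x", threshold=1.5)

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError):
            train([], seed=0)


class TestEvaluate:
    def test_perfect_predictions_score_one(self):
        Y = np.array([label_vector(["fever"]), label_vector(["pain"])]).astype(int)
        scores = Y.astype(float)
        m = metrics_from_scores(Y, scores, Y)
        assert m.micro_precision == m.micro_f1 == 1.0
        assert m.micro_auc == 1.0

    def test_hand_built_confusion_counts(self):
        """Pooled TP=2, FP=1, FN=1 gives micro precision and F1 of 2/3."""
        # 2 classes over 4 examples; remaining cells true negatives
        Y = np.zeros((4, 12), dtype=int)
        pred = np.zeros((4, 12), dtype=int)
        Y[0, 0] = 1; pred[0, 0] = 1          # TP
        Y[1, 1] = 1; pred[1, 1] = 1          # TP
        Y[2, 0] = 1; pred[2, 0] = 0          # FN
        Y[3, 1] = 0; pred[3, 1] = 1          # FP
        scores = pred.astype(float)
        m = metrics_from_scores(Y, scores, pred)
        assert m.micro_precision == pytest.approx(2 / 3)
        # recall = 2/3 as well, so F1 = 2/3
        assert m.micro_f1 == pytest.approx(2 / 3)

    def test_constant_scores_give_chance_auc_per_class(self):
        Y = np.zeros((10, 12), dtype=int)
        Y[:5, 0] = 1
        Y[:3, 1] = 1
        scores = np.full((10, 12), 0.4)
        pred = np.zeros_like(Y)
        m = metrics_from_scores(Y, scores, pred)
        assert m.macro_auc == pytest.approx(0.5)
        assert m.n_auc_classes == 2

    def test_evaluate_invariant_to_test_order(self, labeled_corpus_5k):
        model = train(labeled_corpus_5k[:1000], seed=0)
        test_part = list(labeled_corpus_5k[1000:1300])
        m1 = evaluate(model, test_part)
        rng = np.random.default_rng(7)
        shuffled = [test_part[i] for i in rng.permutation(len(test_part))]
        m2 = evaluate(model, shuffled)
        assert m1 == m2

    def test_empty_test_set_rejected(self):
        model = _FixedScoreModel(np.zeros(12))
        with pytest.raises(ValueError):
            evaluate(model, [])


class TestCrossValidation:
    def test_upsampling_never_touches_test_partitions(self, labeled_corpus_5k):
        """Test folds keep the natural label distribution bit-identically."""
        examples = labeled_corpus_5k[:300]
        Y = label_matrix(examples)
        folds = stratified_kfold(examples, k=5, seed=2)
        rng = np.random.default_rng(2)
        for train_ids, test_ids in folds:
            before = Y[test_ids].copy()
            upsample_training_set([examples[i] for i in train_ids], rng)
            assert np.array_equal(Y[test_ids], before)

    def test_cv_result_table_layout(self, labeled_corpus_5k):
        result = cross_validate(labeled_corpus_5k[:400], k=4, seed=0)
        df = result.to_frame()
        assert list(df["fold"])[:4] == [0, 1, 2, 3]
        assert list(df["fold"])[-2:] == ["mean", "sd"]
        assert "micro_auc" in df.columns

    def test_sentence_augmentation_grows_training_only(self):
        examples = [
            _example("темп 39. озноб всю ночь.", "fever", "chills"),
            _example("слабость", "fatigue"),
        ]
        augmented = classify.augment_with_sentences(examples)
        assert len(augmented) == 4  # 2 originals + 2 sentences of the first
        assert all(
            np.array_equal(a.labels, examples[0].labels) for a in augmented[2:]
        )

    def test_model_serialization_round_trip(self, tmp_path, labeled_corpus_5k):
        model = train(labeled_corpus_5k[:500], seed=0)
        path = tmp_path / "model.bin"
        classify.save_model(model, path)
        back = classify.load_model(path)
        texts = [e.text for e in labeled_corpus_5k[500:520]]
        assert np.allclose(back.predict_scores(texts), model.predict_scores(texts))
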