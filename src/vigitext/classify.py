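"""Multilabel adverse-event classification protocol.

The protocol mirrors how multilabel symptom extraction is evaluated in
pharmacovigilance text mining: minority classes are up-sampled in the
training partition only, models are scored under stratified k-fold
cross-validation (iterative multilabel stratification), the decision rule
is a per-class sigmoid score thresholded at 0.5, and micro/macro precision,
F1 and ROC-AUC are reported per fold with mean and SD.

The text-scoring backend is pluggable behind a narrow contract
(``fit(texts, Y)`` / ``predict_scores(texts) -> (n, 12) probabilities``).
The default desk-scale backend is a one-vs-rest regularised logistic
regression over word n-gram TF-IDF features — i.e. the same sigmoid /
binary-cross-entropy decision layer a neural encoder would feed, without
the encoder.  Heavier (e.g. transformer) backends can be registered under
the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, precision_score, roc_auc_score

from .labels import N_CLASSES, SYMPTOMS, stack_labels
from .parsing import split_sentences


@dataclass(frozen=True)
class LabeledExample:
    """A text with its 12-class label vector."""

    text: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=bool)
        if labels.shape != (N_CLASSES,):
            raise ValueError("labels must have length 12")
        object.__setattr__(self, "labels", labels)


def examples_from_corpus(messages, records) -> list[LabeledExample]:
    """Pair rendered messages with their ground-truth label vectors."""
    return [
        LabeledExample(text=m.text, labels=r.true_labels)
        for m, r in zip(messages, records, strict=True)
    ]


def label_matrix(examples: Sequence[LabeledExample]) -> np.ndarray:
    return stack_labels([e.labels for e in examples])


# ---------------------------------------------------------------------------
# Up-sampling
# ---------------------------------------------------------------------------

def upsample_training_set(
    examples: Sequence[LabeledExample],
    rng: np.random.Generator,
    cap: int | None = None,
) -> list[LabeledExample]:
    """Duplicate minority-class positives until classes are balanced.

    Each class's positive count is raised (by sampling its positive
    examples with replacement) to the largest class's positive count, or to
    ``cap`` if that is smaller.  Duplicated multilabel examples also add
    positives to their other classes, which is accounted for as duplication
    proceeds.  The output order is shuffled.  Never apply this to a test
    partition.
    """
    examples = list(examples)
    if not examples:
        return []
    Y = label_matrix(examples)
    counts = Y.sum(axis=0).astype(int)
    target = int(counts.max())
    if cap is not None:
        target = min(target, cap)

    out = list(examples)
    current = counts.copy()
    # Balance the rarest classes first so their duplicates' side-effects on
    # other classes are counted before those classes are topped up.
    for j in np.argsort(counts, kind="stable"):
        if counts[j] == 0:
            if target > 0:
                warnings.warn(
                    f"class {SYMPTOMS[j]!r} has no positive examples; skipped "
                    "during up-sampling",
                    stacklevel=2,
                )
            continue
        pool = np.flatnonzero(Y[:, j])
        while current[j] < target:
            pick = examples[int(pool[rng.integers(len(pool))])]
            out.append(pick)
            current += pick.labels.astype(int)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


# ---------------------------------------------------------------------------
# Stratified k-fold (iterative multilabel stratification)
# ---------------------------------------------------------------------------

def iterative_stratification(
    Y: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign examples to k folds balancing per-class positive proportions.

    Greedy iterative stratification: repeatedly take the label with the
    fewest remaining positives and deal its remaining examples to the fold
    most in need of that label (ties broken by overall remaining capacity,
    then at random).  Examples with no labels are dealt by capacity.
    Returns an (n,) integer fold-assignment array.
    """
    Y = np.asarray(Y, dtype=bool)
    n = Y.shape[0]
    assignment = np.full(n, -1, dtype=int)
    # desired examples per fold, and desired positives per fold per label
    fold_capacity = np.full(k, n / k)
    label_desire = np.tile(Y.sum(axis=0) / k, (k, 1)).astype(float)

    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        rem_counts = Y[remaining].sum(axis=0)
        active = np.flatnonzero(rem_counts > 0)
        if active.size == 0:
            # only label-free examples left: deal by capacity
            for i in np.flatnonzero(remaining):
                f = _pick_fold(fold_capacity, rng)
                assignment[i] = f
                fold_capacity[f] -= 1
                remaining[i] = False
            break
        lbl = active[np.argmin(rem_counts[active])]
        for i in np.flatnonzero(remaining & Y[:, lbl]):
            need = label_desire[:, lbl]
            best = np.flatnonzero(need == need.max())
            if best.size > 1:
                cap = fold_capacity[best]
                best = best[cap == cap.max()]
            f = int(best[rng.integers(best.size)]) if best.size > 1 else int(best[0])
            assignment[i] = f
            fold_capacity[f] -= 1
            label_desire[f, Y[i]] -= 1
            remaining[i] = False
    return _refine_assignment(Y, assignment, k)


def _pick_fold(capacity: np.ndarray, rng: np.random.Generator) -> int:
    best = np.flatnonzero(capacity == capacity.max())
    return int(best[rng.integers(best.size)]) if best.size > 1 else int(best[0])


def _refine_assignment(
    Y: np.ndarray, assignment: np.ndarray, k: int, max_rounds: int = 300
) -> np.ndarray:
    """Greedy swap repair: push per-fold positive counts toward their
    size-proportional targets until every class is within one positive of
    target in every fold (or no swap improves further).

    Swapping two examples between folds preserves fold sizes, so only the
    label columns of the swapped pair change the balance.
    """
    assignment = assignment.copy()
    n = Y.shape[0]
    totals = Y.sum(axis=0).astype(float)
    sizes = np.bincount(assignment, minlength=k).astype(float)
    target = np.outer(sizes, totals) / n  # (k, classes)
    pos = np.zeros_like(target)
    for f in range(k):
        pos[f] = Y[assignment == f].sum(axis=0)

    for _ in range(max_rounds):
        dev = pos - target
        worst = np.abs(dev).max()
        if worst <= 1.0 + 1e-9:
            break
        f_hi, c = np.unravel_index(np.argmax(np.abs(dev)), dev.shape)
        direction = np.sign(dev[f_hi, c])
        f_lo = int(np.argmin(dev[:, c]) if direction > 0 else np.argmax(dev[:, c]))
        if f_lo == f_hi:
            break
        # swap an example carrying class c out of the overfull fold for one
        # without it from the underfull fold (roles flip if underfull)
        src, dst = (f_hi, f_lo) if direction > 0 else (f_lo, f_hi)
        givers = np.flatnonzero((assignment == src) & Y[:, c])
        takers = np.flatnonzero((assignment == dst) & ~Y[:, c])
        best_gain, best_pair = 0.0, None
        base = float((dev[src] ** 2 + dev[dst] ** 2).sum())
        for e1 in givers:
            for e2 in takers:
                delta = Y[e2].astype(float) - Y[e1].astype(float)
                new = float(
                    ((dev[src] + delta) ** 2 + (dev[dst] - delta) ** 2).sum()
                )
                gain = base - new
                if gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (int(e1), int(e2))
        if best_pair is None:
            break
        e1, e2 = best_pair
        assignment[e1], assignment[e2] = dst, src
        delta = Y[e2].astype(float) - Y[e1].astype(float)
        pos[src] += delta
        pos[dst] -= delta
    return assignment


def stratified_kfold(
    examples: Sequence[LabeledExample], k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold splits as (train_ids, test_ids) index arrays.

    Test sets are disjoint and cover all indices; per-class positive
    proportions per fold are balanced to within integer rounding.
    """
    n = len(examples)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} examples, got {n}")
    rng = np.random.default_rng(seed)
    assignment = iterative_stratification(label_matrix(examples), k, rng)
    folds = []
    all_ids = np.arange(n)
    for f in range(k):
        test = all_ids[assignment == f]
        train = all_ids[assignment != f]
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class ClassifierModel(Protocol):
    """Backend contract: deterministic per-class probabilities in [0,1]."""

    degenerate_classes: tuple[str, ...]

    def predict_scores(self, texts: Sequence[str]) -> np.ndarray:  # (n, 12)
        ...


class LinearNgramModel:
    """One-vs-rest logistic regression over word n-gram TF-IDF features.

    Classes that are all-positive or all-negative in the training data get
    a constant score (their observed rate, 0 or 1) and are flagged in
    ``degenerate_classes``.
    """

    def __init__(self, ngram_range: tuple[int, int] = (1, 2), C: float = 10.0):
        self._vectorizer = TfidfVectorizer(
            lowercase=True, ngram_range=ngram_range, token_pattern=r"(?u)\b\w+\b"
        )
        self._C = C
        self._models: list[LogisticRegression | None] = []
        self._constants: list[float] = [0.0] * N_CLASSES
        self.degenerate_classes: tuple[str, ...] = ()

    def fit(self, texts: Sequence[str], Y: np.ndarray, seed: int = 0) -> "LinearNgramModel":
        Y = np.asarray(Y, dtype=int)
        X = self._vectorizer.fit_transform(texts)
        degenerate = []
        self._models = []
        for j in range(N_CLASSES):
            y = Y[:, j]
            if y.min() == y.max():
                self._models.append(None)
                self._constants[j] = float(y[0])
                degenerate.append(SYMPTOMS[j])
                continue
            clf = LogisticRegression(C=self._C, max_iter=2000, random_state=seed)
            clf.fit(X, y)
            self._models.append(clf)
        self.degenerate_classes = tuple(degenerate)
        return self

    def predict_scores(self, texts: Sequence[str]) -> np.ndarray:
        X = self._vectorizer.transform(texts)
        scores = np.zeros((X.shape[0], N_CLASSES), dtype=float)
        for j, clf in enumerate(self._models):
            if clf is None:
                scores[:, j] = self._constants[j]
            else:
                scores[:, j] = clf.predict_proba(X)[:, 1]
        return np.clip(scores, 0.0, 1.0)


#: Registry of backend factories: name -> callable(seed) -> fittable model.
BACKENDS: dict[str, Callable[..., LinearNgramModel]] = {
    "linear": lambda **kw: LinearNgramModel(**kw),
}


def train(
    train_set: Sequence[LabeledExample],
    backend_spec: str = "linear",
    seed: int = 0,
    **backend_kwargs,
) -> ClassifierModel:
    """Fit a backend on a training partition."""
    if not train_set:
        raise ValueError("training set is empty")
    if backend_spec not in BACKENDS:
        raise KeyError(f"unknown backend {backend_spec!r}; known: {sorted(BACKENDS)}")
    model = BACKENDS[backend_spec](**backend_kwargs)
    model.fit([e.text for e in train_set], label_matrix(train_set), seed=seed)
    return model


MODEL_FORMAT_VERSION = 1


def save_model(model: ClassifierModel, path, backend_spec: str = "linear") -> None:
    """Serialize a fitted model to a single versioned file."""
    import pickle
    from pathlib import Path

    blob = {
        "format_version": MODEL_FORMAT_VERSION,
        "backend": backend_spec,
        "model": model,
    }
    Path(path).write_bytes(pickle.dumps(blob))


def load_model(path) -> ClassifierModel:
    import pickle
    from pathlib import Path

    blob = pickle.loads(Path(path).read_bytes())
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {blob.get('format_version')}")
    return blob["model"]


def predict_labels(
    model: ClassifierModel, text: str, threshold: float = 0.5
) -> np.ndarray:
    """Label vector for one text: class positive iff score >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    scores = model.predict_scores([text])[0]
    return scores >= threshold


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierMetrics:
    """Micro/macro precision, F1 and ROC-AUC on one test partition.

    Micro metrics pool all 12×n binary decisions; macro metrics are
    unweighted means over classes (classes with no true positives in the
    test partition are excluded from macro precision/F1, classes lacking
    both outcomes are excluded from AUC; exclusion counts are reported).
    """

    micro_auc: float
    macro_auc: float
    micro_precision: float
    micro_f1: float
    macro_precision: float
    macro_f1: float
    n_macro_classes: int
    n_auc_classes: int


def evaluate(
    model: ClassifierModel,
    test: Sequence[LabeledExample],
    threshold: float = 0.5,
) -> ClassifierMetrics:
    """Score a model on a test partition (never up-sampled)."""
    if not test:
        raise ValueError("test set is empty")
    Y = label_matrix(test).astype(int)
    scores = model.predict_scores([e.text for e in test])
    pred = (scores >= threshold).astype(int)
    return metrics_from_scores(Y, scores, pred)


def metrics_from_scores(
    Y: np.ndarray, scores: np.ndarray, pred: np.ndarray
) -> ClassifierMetrics:
    Y = np.asarray(Y, dtype=int)
    micro_p = precision_score(Y.ravel(), pred.ravel(), zero_division=0)
    micro_f = f1_score(Y.ravel(), pred.ravel(), zero_division=0)

    with_pos = np.flatnonzero(Y.sum(axis=0) > 0)
    per_p = [precision_score(Y[:, j], pred[:, j], zero_division=0) for j in with_pos]
    per_f = [f1_score(Y[:, j], pred[:, j], zero_division=0) for j in with_pos]
    macro_p = float(np.mean(per_p)) if per_p else float("nan")
    macro_f = float(np.mean(per_f)) if per_f else float("nan")

    pooled = Y.ravel()
    micro_auc = (
        float(roc_auc_score(pooled, scores.ravel()))
        if pooled.min() != pooled.max()
        else float("nan")
    )
    both = [j for j in range(Y.shape[1]) if Y[:, j].min() != Y[:, j].max()]
    per_auc = [roc_auc_score(Y[:, j], scores[:, j]) for j in both]
    macro_auc = float(np.mean(per_auc)) if per_auc else float("nan")

    return ClassifierMetrics(
        micro_auc=micro_auc,
        macro_auc=macro_auc,
        micro_precision=float(micro_p),
        micro_f1=float(micro_f),
        macro_precision=macro_p,
        macro_f1=macro_f,
        n_macro_classes=len(with_pos),
        n_auc_classes=len(both),
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

_METRIC_FIELDS = (
    "micro_auc",
    "macro_auc",
    "micro_precision",
    "micro_f1",
    "macro_precision",
    "macro_f1",
)


@dataclass(frozen=True)
class CrossValidationResult:
    """Per-fold metrics with mean/SD summary."""

    folds: tuple[ClassifierMetrics, ...]

    def mean(self, metric: str) -> float:
        return float(np.nanmean([getattr(m, metric) for m in self.folds]))

    def sd(self, metric: str) -> float:
        return float(np.nanstd([getattr(m, metric) for m in self.folds], ddof=1))

    def to_frame(self) -> pd.DataFrame:
        """Per-fold rows plus mean and SD rows (CSV-friendly)."""
        rows = [
            {"fold": i, **{f: getattr(m, f) for f in _METRIC_FIELDS}}
            for i, m in enumerate(self.folds)
        ]
        rows.append({"fold": "mean", **{f: self.mean(f) for f in _METRIC_FIELDS}})
        rows.append({"fold": "sd", **{f: self.sd(f) for f in _METRIC_FIELDS}})
        return pd.DataFrame(rows)


def augment_with_sentences(
    examples: Sequence[LabeledExample],
) -> list[LabeledExample]:
    """Add each message's individual sentences as extra training examples.

    Sentences inherit the message's label vector.  Training-data-only
    augmentation; never apply to a test partition.
    """
    out = list(examples)
    for e in examples:
        sentences = split_sentences(e.text)
        if len(sentences) > 1:
            out.extend(LabeledExample(text=s, labels=e.labels) for s in sentences)
    return out


def cross_validate(
    examples: Sequence[LabeledExample],
    k: int = 5,
    seed: int = 0,
    backend_spec: str = "linear",
    threshold: float = 0.5,
    upsample: bool = True,
    augment_sentences: bool = False,
    upsample_cap: int | None = None,
) -> CrossValidationResult:
    """Stratified k-fold evaluation of the full training protocol.

    Up-sampling (and optional sentence augmentation) are applied to the
    training partition of each fold only; test partitions keep their
    natural label distribution.
    """
    folds = stratified_kfold(examples, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    results = []
    for train_ids, test_ids in folds:
        train_part = [examples[i] for i in train_ids]
        test_part = [examples[i] for i in test_ids]
        if augment_sentences:
            train_part = augment_with_sentences(train_part)
        if upsample:
            train_part = upsample_training_set(train_part, rng, cap=upsample_cap)
        model = train(train_part, backend_spec=backend_spec, seed=seed)
        results.append(evaluate(model, test_part, threshold=threshold))
    return CrossValidationResult(folds=tuple(results))
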