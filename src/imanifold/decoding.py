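"""Linear-SVM decoding of brain states on manifold coordinates.

Classification is deliberately linear (SVM with a linear kernel, default
C = 1): any nonlinearity should already be captured by the manifold
embedding, so decoding accuracy measures how linearly separable the
stages are *on the manifold*. Three schemes are provided:

* pairwise 1-vs-1 with per-stage stratified 10-fold cross-validation,
* multiclass 1-vs-all with Platt-calibrated posteriors (argmax wins),
* leave-one-subject-out (LOSO) over a group-aligned embedding.

Accuracy is always the number of correctly predicted timepoints divided
by the number of tested timepoints (trace over total of the confusion
matrix in the multiclass case).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .datatypes import ManifoldEmbedding, StageLabels

logger = logging.getLogger(__name__)


@dataclass
class DecodingResult:
    """Cross-validated decoding outcome.

    ``confusion`` rows are true stages, columns predicted, in the order of
    ``stage_order``; ``accuracy`` is trace/total.
    """

    accuracy: float
    per_fold: np.ndarray
    confusion: np.ndarray
    stage_order: list[str]
    scheme: str
    combined_uncertainty: float | None = None
    skipped_rounds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.per_fold = np.asarray(self.per_fold, dtype=float)
        self.confusion = np.asarray(self.confusion, dtype=np.int64)
        total = self.confusion.sum()
        if total:
            trace_acc = np.trace(self.confusion) / total
            if abs(trace_acc - self.accuracy) > 1e-9:
                raise ValueError("accuracy does not equal confusion trace/total")

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "accuracy": float(self.accuracy),
            "per_fold": self.per_fold.tolist(),
            "confusion": self.confusion.tolist(),
            "stage_order": list(self.stage_order),
            "combined_uncertainty": self.combined_uncertainty,
            "skipped_rounds": list(self.skipped_rounds),
        }


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVC:
    """Fit a linear-kernel SVM; errors out on single-class input."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if C <= 0:
        raise ValueError("C must be positive")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return clf


def stratified_folds(
    labels: np.ndarray,
    stages: list[str],
    n_folds: int,
    seed: int,
    scheme: str = "random",
) -> list[np.ndarray]:
    """Per-stage fold assignment: each stage's TRs are split into
    ``n_folds`` parts and fold f pools part f of every stage.

    ``scheme="random"`` permutes each stage's indices with the seeded RNG
    before splitting (the default: filtering-induced autocorrelation makes
    contiguous blocks pessimistic); ``"contiguous"`` keeps temporal order.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for stage in stages:
        idx = np.flatnonzero(labels == stage)
        if idx.size < n_folds:
            raise ValueError(
                f"stage {stage!r} has {idx.size} timepoints; "
                f"need at least {n_folds} for {n_folds}-fold CV"
            )
        if scheme == "random":
            idx = rng.permutation(idx)
        elif scheme != "contiguous":
            raise ValueError(f"unknown fold scheme {scheme!r}")
        for f, part in enumerate(np.array_split(idx, n_folds)):
            folds[f].extend(part.tolist())
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


def _confusion(
    y_true: np.ndarray, y_pred: np.ndarray, stage_order: list[str]
) -> np.ndarray:
    K = len(stage_order)
    pos = {s: k for k, s in enumerate(stage_order)}
    out = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        out[pos[t], pos[p]] += 1
    return out


def crossval_1v1(
    embedding: ManifoldEmbedding | np.ndarray,
    labels: StageLabels | np.ndarray,
    stage_a: str,
    stage_b: str,
    n_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    fold_scheme: str = "random",
) -> DecodingResult:
    """Pairwise stage decoding with per-stage stratified k-fold CV."""
    coords = embedding.coords if isinstance(embedding, ManifoldEmbedding) else np.asarray(embedding)
    labs = labels.labels if isinstance(labels, StageLabels) else np.asarray(labels, dtype=object)
    mask = (labs == stage_a) | (labs == stage_b)
    X, y = coords[mask], labs[mask]
    folds = stratified_folds(y, [stage_a, stage_b], n_folds, seed, fold_scheme)
    per_fold = np.empty(n_folds)
    conf = np.zeros((2, 2), dtype=np.int64)
    all_idx = np.arange(len(y))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        clf = train_linear_svm(X[train_idx], y[train_idx], C=C)
        pred = clf.predict(X[test_idx])
        per_fold[f] = np.mean(pred == y[test_idx])
        conf += _confusion(y[test_idx], pred, [stage_a, stage_b])
    accuracy = np.trace(conf) / conf.sum()
    return DecodingResult(
        accuracy=float(accuracy),
        per_fold=per_fold,
        confusion=conf,
        stage_order=[stage_a, stage_b],
        scheme="tenfold_1v1" if n_folds == 10 else f"{n_folds}fold_1v1",
    )


class OneVsAllPosteriorClassifier:
    """K one-vs-all linear SVMs with Platt-calibrated score posteriors.

    For each stage a binary SVM is trained, a sigmoid is fitted to its
    training decision scores (Platt calibration), and test samples are
    assigned to the stage with the highest posterior probability.
    """

    def __init__(self, stages: list[str], C: float = 1.0):
        self.stages = list(stages)
        self.C = C
        self._svms: dict[str, SVC] = {}
        self._calibrators: dict[str, LogisticRegression] = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsAllPosteriorClassifier":
        for stage in self.stages:
            target = (np.asarray(y, dtype=object) == stage).astype(int)
            if target.min() == target.max():
                raise ValueError(
                    f"training part is missing class {stage!r}; re-stratify folds"
                )
            svm = SVC(kernel="linear", C=self.C)
            svm.fit(X, target)
            scores = svm.decision_function(X).reshape(-1, 1)
            cal = LogisticRegression(C=1e6, max_iter=1000)
            cal.fit(scores, target)
            self._svms[stage] = svm
            self._calibrators[stage] = cal
        return self

    def posterior(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for stage in self.stages:
            scores = self._svms[stage].decision_function(X).reshape(-1, 1)
            cols.append(self._calibrators[stage].predict_proba(scores)[:, 1])
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        post = self.posterior(X)
        return np.asarray(self.stages, dtype=object)[np.argmax(post, axis=1)]


def crossval_1vall_multiclass(
    embedding: ManifoldEmbedding | np.ndarray,
    labels: StageLabels | np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    fold_scheme: str = "random",
) -> DecodingResult:
    """Multiclass decoding by argmax over calibrated 1-vs-all posteriors."""
    coords = embedding.coords if isinstance(embedding, ManifoldEmbedding) else np.asarray(embedding)
    if isinstance(labels, StageLabels):
        mask = labels.scored_mask
        labs = labels.labels[mask]
        coords = coords[mask]
        stages = labels.stages
    else:
        labs = np.asarray(labels, dtype=object)
        stages = sorted(set(labs))
    if len(stages) < 2:
        raise ValueError("need at least 2 stages for multiclass decoding")
    folds = stratified_folds(labs, stages, n_folds, seed, fold_scheme)
    per_fold = np.empty(n_folds)
    conf = np.zeros((len(stages), len(stages)), dtype=np.int64)
    all_idx = np.arange(len(labs))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        clf = OneVsAllPosteriorClassifier(stages, C=C).fit(
            coords[train_idx], labs[train_idx]
        )
        pred = clf.predict(coords[test_idx])
        per_fold[f] = np.mean(pred == labs[test_idx])
        conf += _confusion(labs[test_idx], pred, stages)
    accuracy = np.trace(conf) / conf.sum()
    return DecodingResult(
        accuracy=float(accuracy),
        per_fold=per_fold,
        confusion=conf,
        stage_order=stages,
        scheme="tenfold_1vall" if n_folds == 10 else f"{n_folds}fold_1vall",
    )


def leave_one_subject_out(
    embeddings: list[ManifoldEmbedding],
    labels_list: list[StageLabels],
    C: float = 1.0,
    mode: str = "1vall",
    stage_a: str | None = None,
    stage_b: str | None = None,
) -> DecodingResult:
    """LOSO decoding on a group-aligned embedding.

    One round per subject: train on every other subject's (aligned)
    coordinates, test on the held-out subject. In ``mode="1vall"`` a test
    stage absent from training counts its rows as errors; in
    ``mode="1v1"`` a round whose held-out subject lacks one of the two
    stages is skipped with a warning.
    """
    if len(embeddings) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if mode == "1v1" and (stage_a is None or stage_b is None):
        raise ValueError("1v1 mode requires stage_a and stage_b")
    coords = [e.coords for e in embeddings]
    labs = [l.labels[l.scored_mask] for l in labels_list]
    coords = [c[l.scored_mask] for c, l in zip(coords, labels_list)]
    stages = sorted({s for l in labs for s in l})
    if mode == "1v1":
        stages = [stage_a, stage_b]
    per_round: list[float] = []
    conf = np.zeros((len(stages), len(stages)), dtype=np.int64)
    skipped: list[str] = []
    for held in range(len(embeddings)):
        X_test, y_test = coords[held], labs[held]
        X_train = np.vstack([c for s, c in enumerate(coords) if s != held])
        y_train = np.concatenate([l for s, l in enumerate(labs) if s != held])
        if mode == "1v1":
            tr_mask = (y_train == stage_a) | (y_train == stage_b)
            te_mask = (y_test == stage_a) | (y_test == stage_b)
            if not ((y_test == stage_a).any() and (y_test == stage_b).any()):
                sid = labels_list[held].subject_id
                skipped.append(sid)
                logger.warning("LOSO 1v1 round skipped: %s lacks a stage", sid)
                continue
            clf = train_linear_svm(X_train[tr_mask], y_train[tr_mask], C=C)
            pred = clf.predict(X_test[te_mask])
            truth = y_test[te_mask]
        else:
            clf = OneVsAllPosteriorClassifier(
                sorted(set(y_train)), C=C
            ).fit(X_train, y_train)
            pred = clf.predict(X_test)
            truth = y_test
        per_round.append(float(np.mean(pred == truth)))
        conf += _confusion(truth, pred, stages)
    if not per_round:
        raise ValueError("all LOSO rounds were skipped")
    accuracy = np.trace(conf) / conf.sum()
    return DecodingResult(
        accuracy=float(accuracy),
        per_fold=np.asarray(per_round),
        confusion=conf,
        stage_order=stages,
        scheme="loso",
        skipped_rounds=skipped,
    )


def combined_uncertainty(errors: list[float] | np.ndarray) -> float:
    """Pooled accuracy uncertainty over m pairwise comparisons:
    (1/m) * sqrt(sum of squared per-comparison SDs)."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error list")
    if np.any(e < 0):
        raise ValueError("uncertainties must be non-negative")
    return float(np.sqrt(np.sum(e**2)) / e.size)
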