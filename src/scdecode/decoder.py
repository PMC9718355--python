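"""Pseudolinear discriminant decoding with one-vs-one output codes.

The base learner is a two-class linear discriminant with pooled
within-class covariance whose inverse is replaced by the Moore-Penrose
pseudoinverse ("pseudolinear" LDA).  This keeps fitting well defined
when a feature has zero variance — the typical situation for a channel
with no spikes in a short window — by assigning such directions zero
discriminant weight instead of failing.

Eight target classes are handled by error-correcting output codes over
all K(K-1)/2 = 28 class pairs: each binary learner votes for one of its
two classes and the predicted class is the vote argmax, with ties broken
by summed signed discriminant margins and then by the lowest class
index.  Performance is the per-class F1 score averaged over repeated
random 70/30 train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "BinaryLDAModel",
    "EcocModel",
    "PerformanceScore",
    "fit_binary_lda",
    "fit_ecoc",
    "predict_ecoc",
    "per_class_f1",
    "confusion_matrix",
    "evaluate_window",
]

N_CLASSES = 8


@dataclass
class BinaryLDAModel:
    """Two-class pooled-covariance discriminant with pseudoinverse.

    The decision function is affine: ``margin(x) = x @ w + b`` with
    ``w = pinv(S) (mu1 - mu0)`` and
    ``b = -(mu1 + mu0) @ w / 2 + log(pi1/pi0)``;
    positive margin predicts ``classes[1]``, negative ``classes[0]``,
    and an exact tie the lower class label.
    """

    classes: tuple[int, int]
    means: np.ndarray  # (2, d)
    pooled_cov: np.ndarray  # (d, d)
    cov_pinv: np.ndarray  # (d, d)
    log_priors: np.ndarray  # (2,)
    w: np.ndarray  # (d,)
    b: float

    def margin(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        m = self.margin(X)
        # tie (margin == 0) goes to the lower class label
        return np.where(m > 0, self.classes[1], np.where(m < 0, self.classes[0], min(self.classes)))


def _class_stats(X: np.ndarray, y: np.ndarray) -> dict[int, tuple[int, np.ndarray, np.ndarray]]:
    """Per-class count, mean and centered scatter matrix."""
    stats = {}
    for c in np.unique(y):
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        D = Xc - mu
        stats[int(c)] = (len(Xc), mu, D.T @ D)
    return stats


def _binary_from_stats(
    a: int,
    b: int,
    stats: dict[int, tuple[int, np.ndarray, np.ndarray]],
    pinv_rcond: float = 1e-10,
) -> BinaryLDAModel:
    na, mua, Sa = stats[a]
    nb, mub, Sb = stats[b]
    dof = max(na + nb - 2, 1)
    cov = (Sa + Sb) / dof
    cov_pinv = np.linalg.pinv(cov, rcond=pinv_rcond, hermitian=True)
    log_priors = np.log(np.array([na, nb]) / (na + nb))
    w = cov_pinv @ (mub - mua)
    bias = -0.5 * (mub + mua) @ w + (log_priors[1] - log_priors[0])
    return BinaryLDAModel(
        classes=(a, b),
        means=np.stack([mua, mub]),
        pooled_cov=cov,
        cov_pinv=cov_pinv,
        log_priors=log_priors,
        w=w,
        b=float(bias),
    )


def fit_binary_lda(X: np.ndarray, y: np.ndarray) -> BinaryLDAModel:
    """Fit the two-class pseudolinear discriminant.

    Class priors are the empirical training frequencies.  Requires at
    least one observation of each of exactly two classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("fit_binary_lda requires exactly two classes in y")
    stats = _class_stats(X, y)
    return _binary_from_stats(int(classes[0]), int(classes[1]), stats)


@dataclass
class EcocModel:
    """One-vs-one composition of binary pseudolinear discriminants."""

    classes: np.ndarray
    learners: list[BinaryLDAModel]

    def __post_init__(self) -> None:
        n_pairs = len(self.classes) * (len(self.classes) - 1) // 2
        if len(self.learners) != n_pairs:
            raise ValueError("expected one learner per unordered class pair")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_ecoc(self, X)


def fit_ecoc(X: np.ndarray, y: np.ndarray) -> EcocModel:
    """Fit one binary discriminant per unordered class pair, each on the
    trials of its two classes only (28 learners for 8 classes).

    Per-class means and scatters are computed once and shared across
    pairs; the 28 pair covariances are pseudoinverted in one batched
    call.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    stats = _class_stats(X, y)
    pairs = list(combinations([int(c) for c in classes], 2))
    covs = np.stack(
        [(stats[a][2] + stats[b][2]) / max(stats[a][0] + stats[b][0] - 2, 1) for a, b in pairs]
    )
    pinvs = np.linalg.pinv(covs, rcond=1e-10, hermitian=True)
    learners = []
    for (a, b), cov, cov_pinv in zip(pairs, covs, pinvs):
        na, mua, _ = stats[a]
        nb, mub, _ = stats[b]
        log_priors = np.log(np.array([na, nb]) / (na + nb))
        w = cov_pinv @ (mub - mua)
        bias = -0.5 * (mub + mua) @ w + (log_priors[1] - log_priors[0])
        learners.append(
            BinaryLDAModel(
                classes=(a, b),
                means=np.stack([mua, mub]),
                pooled_cov=cov,
                cov_pinv=cov_pinv,
                log_priors=log_priors,
                w=w,
                b=float(bias),
            )
        )
    return EcocModel(classes=classes, learners=learners)


def predict_ecoc(model: EcocModel, X: np.ndarray) -> np.ndarray:
    """Vote-based decoding: each pairwise learner votes for one of its
    classes; argmax of votes wins, ties broken by summed signed margins,
    remaining ties by the lowest class label."""
    X = np.asarray(X, dtype=float)
    classes = model.classes
    idx = {int(c): i for i, c in enumerate(classes)}
    n, k = X.shape[0], len(classes)
    # one affine map for all pairwise margins
    W = np.stack([learner.w for learner in model.learners], axis=1)
    bvec = np.array([learner.b for learner in model.learners])
    M = X @ W + bvec  # (n, n_pairs)
    ia = np.array([idx[l.classes[0]] for l in model.learners])
    ib = np.array([idx[l.classes[1]] for l in model.learners])
    n_pairs = len(model.learners)
    onehot_a = np.zeros((n_pairs, k))
    onehot_b = np.zeros((n_pairs, k))
    onehot_a[np.arange(n_pairs), ia] = 1.0
    onehot_b[np.arange(n_pairs), ib] = 1.0
    win_b = M > 0
    votes = win_b @ onehot_b + (~win_b) @ onehot_a
    margins = M @ (onehot_b - onehot_a)
    # argmax votes; ties broken by summed signed margin, then lowest label
    score = margins.copy()
    score[votes < votes.max(axis=1, keepdims=True)] = -np.inf
    best = np.argmax(score, axis=1)  # np.argmax returns the first (lowest-label) max
    ambiguous = np.flatnonzero((score == score[np.arange(n), best][:, None]).sum(axis=1) > 1)
    for i in ambiguous:
        order = np.lexsort((classes, -margins[i], -votes[i]))
        best[i] = order[0]
    return classes[best]


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_CLASSES
) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class (1-based labels)."""
    t = np.asarray(y_true, dtype=int) - 1
    p = np.asarray(y_pred, dtype=int) - 1
    flat = np.bincount(t * n_classes + p, minlength=n_classes * n_classes)
    return flat.reshape(n_classes, n_classes)


def per_class_f1(confusion: np.ndarray) -> np.ndarray:
    """Per-class F1 from a confusion matrix (rows true, cols predicted).

    F1_c = 2 P R / (P + R) with P = TP/(TP+FP) and R = TP/(TP+FN); any
    undefined precision, recall or F1 (class never predicted and/or never
    present) is scored 0 by convention.
    """
    cm = np.asarray(confusion, dtype=float)
    if np.any(cm < 0):
        raise ValueError("confusion counts must be nonnegative")
    tp = np.diag(cm)
    denom = 2 * tp + (cm.sum(axis=0) - tp) + (cm.sum(axis=1) - tp)  # 2TP + FP + FN
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return f1


@dataclass
class PerformanceScore:
    """Iteration-averaged per-class F1 with the pooled confusion matrix."""

    f1: np.ndarray  # (n_classes,)
    confusion: np.ndarray  # (n_classes, n_classes), summed over iterations
    n_test: int


def _split_indices(
    n: int,
    y: np.ndarray,
    train_frac: float,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Unstratified random split, resampled (bounded) until every class
    present overall appears in the training set."""
    present = np.unique(y)
    n_train = int(round(train_frac * n))
    for _ in range(max_retries + 1):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if np.isin(present, y[train]).all():
            return train, test
    raise RuntimeError("could not draw a split containing every class in training")


def evaluate_window(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    train_frac: float = 0.7,
    n_iter: int = 10,
    shuffle: bool = False,
    n_classes: int = N_CLASSES,
    learner=fit_ecoc,
) -> PerformanceScore:
    """Score one window by repeated random 70/30 splits.

    Each iteration draws an unstratified split pooled across targets,
    fits the one-vs-one model on the training 70% and computes per-class
    F1 on the held-out 30%; the returned F1 is the mean over iterations.
    With ``shuffle=True`` the target labels are independently permuted
    before each iteration's split, giving the empirical chance level.
    ``learner`` is pluggable: any callable ``(X, y) -> model`` whose
    result has a ``predict`` method (e.g. an SVM wrapper) may substitute
    for the default discriminant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < n_classes:
        raise ValueError("too few trials to evaluate")
    f1_sum = np.zeros(n_classes)
    cm_total = np.zeros((n_classes, n_classes), dtype=int)
    n_test_total = 0
    n_done = 0
    for _ in range(n_iter):
        labels = rng.permutation(y) if shuffle else y
        try:
            train, test = _split_indices(n, labels, train_frac, rng)
        except RuntimeError:
            continue  # degenerate labels; skip iteration (logged by caller)
        model = learner(X[train], labels[train])
        pred = model.predict(X[test])
        cm = confusion_matrix(labels[test], pred, n_classes)
        f1_sum += per_class_f1(cm)
        cm_total += cm
        n_test_total += len(test)
        n_done += 1
    if n_done == 0:
        raise RuntimeError("no evaluation iteration succeeded")
    return PerformanceScore(f1=f1_sum / n_done, confusion=cm_total, n_test=n_test_total)
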