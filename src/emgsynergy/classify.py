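"""Shrinkage LDA over window features: split, cross-validate, fit, evaluate.

The classifier is the Gaussian equal-covariance Bayes rule: each task's
features are modelled as N(mu_j, Sigma) with a pooled within-class covariance,
and a window is assigned the class maximising the posterior p(y_j | x).  The
pooled covariance is shrunk toward a scaled identity, (1-a) S + a tr(S)/p I,
with the shrinkage intensity picked by k-fold cross-validation at repetition
granularity.  Train/test splits are likewise made over whole repetitions:
adjacent 50%-overlapping windows are strongly dependent, and splitting them
across sides would leak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.metrics import confusion_matrix

from .features import WindowFeatureSet
from .io import TASKS

__all__ = [
    "LDAModel",
    "EvalReport",
    "lda_fit",
    "lda_predict",
    "split_train_test",
    "cross_validate",
    "evaluate",
    "DEFAULT_SHRINKAGE_GRID",
]

DEFAULT_SHRINKAGE_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)


def _canonical_order(labels: Sequence[str]) -> list[str]:
    present = list(dict.fromkeys(labels))
    known = [t for t in TASKS if t in present]
    return known + sorted(set(present) - set(known))


@dataclass
class LDAModel:
    """Gaussian equal-covariance classifier parameters."""

    classes: list[str]
    means: np.ndarray          # (m, p)
    covariance: np.ndarray     # (p, p), after shrinkage
    priors: np.ndarray         # (m,)
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")


@dataclass
class EvalReport:
    """Confusion matrix (rows true, cols predicted) and accuracies in percent.

    The overall accuracy is the unweighted mean of the per-task accuracies,
    so no task dominates through window count.
    """

    classes: list[str]
    confusion: np.ndarray
    per_task_accuracy: dict[str, float]
    overall_accuracy: float


def lda_fit(train: WindowFeatureSet | None = None, shrinkage: float = 1e-3,
            X: np.ndarray | None = None, y: np.ndarray | None = None) -> LDAModel:
    """Fit class means, pooled shrunk covariance and empirical priors."""
    if train is not None:
        X, y = train.X, train.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = _canonical_order(list(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit LDA")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")
    p = X.shape[1]
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    priors = np.array([np.mean(y == c) for c in classes])
    n, m = len(y), len(classes)
    pooled = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = X[y == c] - mu
        pooled += d.T @ d
    pooled /= max(n - m, 1)
    cov = (1 - shrinkage) * pooled + shrinkage * (np.trace(pooled) / p) * np.eye(p)
    try:
        linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        raise ValueError(
            "pooled covariance is singular; refit with a nonzero shrinkage"
        ) from None
    return LDAModel(classes=classes, means=means, covariance=cov,
                    priors=priors, shrinkage=shrinkage)


def lda_predict(model: LDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class posteriors (rows sum to 1) for each feature row.

    Ties in the posterior break toward the earlier class in ``model.classes``
    (canonical task order), deterministically.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = model.means.shape[1]
    if X.shape[1] != p:
        raise ValueError(f"feature dimension {X.shape[1]} does not match model ({p})")
    cho = linalg.cho_factor(model.covariance, lower=True)
    loglik = np.empty((X.shape[0], len(model.classes)))
    for j, mu in enumerate(model.means):
        d = X - mu
        z = linalg.cho_solve(cho, d.T)
        loglik[:, j] = -0.5 * np.einsum("ij,ji->i", d, z) + np.log(model.priors[j])
    loglik -= loglik.max(axis=1, keepdims=True)
    post = np.exp(loglik)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.array([model.classes[j] for j in np.argmax(post, axis=1)], dtype=object)
    return labels, post


# ---------------------------------------------------------------------------
# splitting and model selection at repetition granularity
# ---------------------------------------------------------------------------

def _reps_by_task(fset: WindowFeatureSet) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for task, _loading, rep in fset.groups:
        out.setdefault(task, [])
        if rep not in out[task]:
            out[task].append(rep)
    return out


def split_train_test(fset: WindowFeatureSet, train_frac: float = 0.75,
                     seed: int = 0) -> tuple[WindowFeatureSet, WindowFeatureSet]:
    """Stratified split assigning whole repetitions to one side.

    With 12 repetitions per task and the default 75/25 split, each task
    contributes 9 training and 3 testing repetitions.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 555)))
    train_reps: set[tuple[str, int]] = set()
    for task, reps in sorted(_reps_by_task(fset).items()):
        reps = sorted(reps)
        if len(reps) < 2:
            raise ValueError(f"task {task!r} has fewer than 2 repetitions; cannot split")
        k = max(1, min(len(reps) - 1, int(np.floor(train_frac * len(reps)))))
        perm = rng.permutation(len(reps))
        train_reps.update((task, reps[i]) for i in perm[:k])
    idx_train = np.array([i for i, (t, _l, r) in enumerate(fset.groups)
                          if (t, r) in train_reps])
    idx_test = np.array([i for i in range(fset.n_windows) if i not in set(idx_train)])
    return fset.subset(idx_train), fset.subset(idx_test)


def cross_validate(train: WindowFeatureSet, k: int = 10,
                   shrinkage_grid: Sequence[float] = DEFAULT_SHRINKAGE_GRID,
                   seed: int = 0) -> tuple[float, float]:
    """Pick the shrinkage with the best mean fold accuracy; ties -> smallest.

    Folds are stratified partitions of the repetitions of each task, so every
    fold holds out whole trials.  Returns (best_shrinkage, cv_accuracy).
    """
    reps = _reps_by_task(train)
    min_reps = min(len(r) for r in reps.values())
    if k > min_reps:
        raise ValueError(f"k={k} folds exceed the smallest class repetition count {min_reps}")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 556)))
    fold_of: dict[tuple[str, int], int] = {}
    for task, task_reps in sorted(reps.items()):
        order = rng.permutation(sorted(task_reps))
        for i, rep in enumerate(order):
            fold_of[(task, int(rep))] = i % k
    fold_idx = np.array([fold_of[(t, r)] for t, _l, r in train.groups])
    best = (None, -1.0)
    for lam in shrinkage_grid:
        accs = []
        try:
            for f in range(k):
                tr, te = train.subset(np.where(fold_idx != f)[0]), train.subset(np.where(fold_idx == f)[0])
                model = lda_fit(tr, shrinkage=lam)
                labels, _ = lda_predict(model, te.X)
                accs.append(float(np.mean(labels == te.y)))
        except ValueError:
            continue  # singular covariance at this shrinkage
        mean_acc = float(np.mean(accs))
        if mean_acc > best[1] + 1e-12:
            best = (lam, mean_acc)
    if best[0] is None:
        raise ValueError("no shrinkage value in the grid produced a valid fit")
    return float(best[0]), best[1]


def evaluate(model: LDAModel, test: WindowFeatureSet) -> EvalReport:
    """Confusion matrix and per-task / overall accuracy on held-out windows."""
    labels, _ = lda_predict(model, test.X)
    classes = model.classes
    for c in classes:
        if not np.any(test.y == c):
            raise ValueError(f"test set has no windows of class {c!r}")
    conf = confusion_matrix(test.y, labels, labels=classes)
    per_task = {
        c: 100.0 * conf[i, i] / conf[i].sum() for i, c in enumerate(classes)
    }
    return EvalReport(
        classes=list(classes),
        confusion=conf,
        per_task_accuracy=per_task,
        overall_accuracy=float(np.mean(list(per_task.values()))),
    )
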