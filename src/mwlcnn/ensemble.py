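"""Ensembles of base classifiers: rank-weighted averaging, voting, stacking.

Base members are diversified by bootstrap resampling (80% of the training
indices, without replacement, per member) and by varying the architecture
and optimizer.  Three aggregation rules are provided:

* **weighted averaging** — the combined posterior is sum_j alpha_j y_j(i);
  by default the weights derive from the accuracy ranking of the members,
  alpha_j = R(A_j) / sum_k R(A_k) with R = K for the most accurate member;
* **majority voting** — modal predicted label, ties broken by the vote of
  the most accurate member;
* **stacking** — a two-layer scheme: out-of-fold member predictions from a
  k-fold split form an n x K meta-table on which a multinomial logistic
  meta-classifier is trained.

Member selection from a scored (architecture x optimizer) grid supports
four strategies: the best model per architecture family, the best and worst
per family, the top half overall, or all models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Protocol, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

__all__ = [
    "ModelScore",
    "Member",
    "SELECTION_STRATEGIES",
    "bootstrap_train_sets",
    "rank_weights",
    "combine_posteriors",
    "weighted_average_predict",
    "majority_vote",
    "StackingEnsemble",
    "fit_stacking",
    "select_members",
]

SELECTION_STRATEGIES = ("best-per-family", "best-and-worst-per-family", "top-half", "all")


class Member(Protocol):
    """Anything that can be refitted and emit class posteriors.

    ``fit`` must return a *new* fitted member, leaving the receiver
    untouched, so the same template can be refitted per fold.
    """

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "Member": ...

    def predict_proba(self, features: np.ndarray) -> np.ndarray: ...


@dataclass
class ModelScore:
    """A candidate member with its validation accuracy and grid tags."""

    model: Any
    accuracy: float
    arch_id: str = ""
    optimizer: str = ""


def bootstrap_train_sets(
    train_indices: np.ndarray, fraction: float = 0.8, K: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """K index subsets of size floor(fraction * n), without replacement.

    Each member draws with its own seed stream, so subsets differ between
    members but the whole collection is reproducible from ``seed``.
    With ``fraction=1`` every subset is a permutation of all indices.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    idx = np.asarray(train_indices)
    size = int(np.floor(fraction * len(idx)))
    return [
        np.random.default_rng([seed, j]).choice(idx, size=size, replace=False)
        for j in range(K)
    ]


def rank_weights(scores: Sequence[ModelScore] | Sequence[float] | np.ndarray) -> np.ndarray:
    """Accuracy-rank weights alpha_j = R(A_j) / sum_k R(A_k).

    The most accurate of K members gets rank K, the least accurate rank 1;
    ties receive average ranks, which keeps the weights order-independent
    and summing to 1.
    """
    if len(scores) == 0:
        raise ValueError("no members to weight")
    acc = np.asarray(
        [s.accuracy if isinstance(s, ModelScore) else float(s) for s in scores]
    )
    ranks = rankdata(acc, method="average")
    return ranks / ranks.sum()


def combine_posteriors(posteriors: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted member posteriors, shape (n, c): S'(i) = sum_j alpha_j y_j(i)."""
    post = np.asarray(posteriors, dtype=float)
    w = np.asarray(weights, dtype=float)
    if post.ndim != 3:
        raise ValueError("posteriors must be (K, n_epochs, n_classes)")
    if w.shape != (post.shape[0],):
        raise ValueError(
            f"{post.shape[0]} members but {w.shape} weights"
        )
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    return np.tensordot(w, post, axes=1)


def weighted_average_predict(posteriors: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Class label per epoch from the weighted-average posterior."""
    return combine_posteriors(posteriors, weights).argmax(axis=1)


def majority_vote(votes: np.ndarray, accuracies: Sequence[float] | None = None) -> np.ndarray:
    """Modal label per epoch over K member votes.

    When several labels tie for the highest count, the vote cast by the
    most accurate member (among the tied labels) wins; without accuracies
    the lowest tied label wins.
    """
    votes = np.asarray(votes, dtype=int)
    if votes.ndim != 2 or votes.shape[0] == 0:
        raise ValueError("votes must be a non-empty (K, n_epochs) array")
    K, n = votes.shape
    acc = np.asarray(accuracies, dtype=float) if accuracies is not None else None
    if acc is not None and acc.shape != (K,):
        raise ValueError("one accuracy per member required")
    n_labels = votes.max() + 1
    out = np.empty(n, dtype=int)
    by_acc = np.argsort(-acc, kind="stable") if acc is not None else None
    for i in range(n):
        counts = np.bincount(votes[:, i], minlength=n_labels)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1 or by_acc is None:
            out[i] = tied[0]
        else:
            tied_set = set(tied.tolist())
            out[i] = next(votes[j, i] for j in by_acc if votes[j, i] in tied_set)
    return out


def _one_hot(table: np.ndarray, n_classes: int) -> np.ndarray:
    n, K = table.shape
    flat = np.zeros((n, K, n_classes))
    flat[np.arange(n)[:, None], np.arange(K)[None, :], table] = 1.0
    return flat.reshape(n, K * n_classes)


@dataclass
class StackingEnsemble:
    """Two-layer ensemble: refitted members plus a fitted meta-classifier."""

    members: list[Member]
    meta_model: LogisticRegression
    n_classes: int
    meta_table: np.ndarray  # (n, K) out-of-fold member labels

    def member_labels(self, features: np.ndarray) -> np.ndarray:
        return np.stack(
            [m.predict_proba(features).argmax(axis=1) for m in self.members], axis=1
        )

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.meta_model.predict(_one_hot(self.member_labels(features), self.n_classes))


def fit_stacking(
    members: Sequence[Member],
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> StackingEnsemble:
    """Fit a stacked ensemble by k-fold out-of-fold prediction.

    Each member template is refitted on every training fold and predicts
    the held-out fold, producing an n x K table of out-of-fold labels.
    The meta-classifier (multinomial logistic regression on the one-hot
    encoding of that table) learns to map member outputs to the target;
    finally every member is refitted on the full training set.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if folds > n:
        raise ValueError(f"{folds} folds but only {n} samples")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    K = len(members)
    n_classes = int(y.max()) + 1
    table = np.empty((n, K), dtype=int)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(features):
        for j, member in enumerate(members):
            fitted = member.fit(features[train_idx], y[train_idx])
            table[test_idx, j] = fitted.predict_proba(features[test_idx]).argmax(axis=1)
    meta = LogisticRegression(max_iter=1000, C=1e3)
    meta.fit(_one_hot(table, n_classes), y)
    refitted = [member.fit(features, y) for member in members]
    return StackingEnsemble(
        members=refitted, meta_model=meta, n_classes=n_classes, meta_table=table
    )


def select_members(scored: Sequence[ModelScore], strategy: str) -> list[ModelScore]:
    """Pick ensemble members from a scored (architecture x optimizer) grid.

    * ``best-per-family`` — the most accurate model of each architecture;
    * ``best-and-worst-per-family`` — both extremes of each architecture;
    * ``top-half`` — the floor(n/2) most accurate models overall;
    * ``all`` — every candidate.
    """
    if strategy not in SELECTION_STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {SELECTION_STRATEGIES}"
        )
    scored = list(scored)
    if not scored:
        raise ValueError("no scored models")
    if strategy == "all":
        return scored
    if strategy == "top-half":
        order = sorted(scored, key=lambda s: -s.accuracy)
        return order[: len(scored) // 2]
    families: dict[str, list[ModelScore]] = {}
    for s in scored:
        families.setdefault(s.arch_id, []).append(s)
    picked: list[ModelScore] = []
    for arch in sorted(families):
        fam = sorted(families[arch], key=lambda s: -s.accuracy)
        picked.append(fam[0])
        if strategy == "best-and-worst-per-family" and len(fam) > 1:
            picked.append(fam[-1])
    return picked
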