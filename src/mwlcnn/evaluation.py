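"""Multiclass evaluation: confusion matrices, metrics, repeated-split runs.

Conventions.  Confusion-matrix rows are target classes, columns estimated
classes.  With N the total count, tr_i the diagonal entries, n_i the row
sums and tp_i the column sums:

* accuracy            = tr / N  (tr = sum of the diagonal)
* precision (macro)   = (1/c) * sum_i tr_i / tp_i
* recall_i            = tr_i / n_i
* F-measure (macro)   = (2/c) * sum_i P_i R_i / (P_i + R_i)
* G-mean              = (prod_i recall_i) ** (1/c), zero if any class has
                        an empty diagonal
* per-class accuracy  = tr_i / tp_i — the precision-like column convention
                        used in the reference confusion tables.

Zero denominators yield 0 for the affected class term.  The repeated-split
protocol draws unstratified 50/50 train/test splits, trains every
(architecture, optimizer) combination per run, and reports per-run metrics
plus mean +/- std, ranked by mean accuracy (ties by precision, then F).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .models import ArchitectureSpec, OptimizerConfig, build_architecture

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_matrix",
    "metrics",
    "train_test_split_indices",
    "repeated_split_evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """c x c counts; rows = target class, columns = estimated class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        cm = np.asarray(self.counts)
        if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (cm < 0).any() or not np.issubdtype(cm.dtype, np.integer):
            raise ValueError("confusion matrix must hold nonnegative integers")
        object.__setattr__(self, "counts", cm)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def tr(self) -> int:
        return int(np.trace(self.counts))

    @property
    def tr_i(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def n_i(self) -> np.ndarray:
        """Per-class target counts (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def tp_i(self) -> np.ndarray:
        """Per-class predicted counts (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self, class_names: Sequence[str] | None = None) -> pd.DataFrame:
        names = list(class_names) if class_names else list(range(self.n_classes))
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_matrix(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> ConfusionMatrix:
    """Count matrix cell[t, e] = #epochs with target t estimated as e."""
    t = np.asarray(true_labels, dtype=int)
    e = np.asarray(predicted_labels, dtype=int)
    if t.shape != e.shape:
        raise ValueError("label vectors differ in length")
    for name, v in (("true", t), ("predicted", e)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    counts = np.bincount(t * n_classes + e, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


@dataclass(frozen=True)
class MetricReport:
    """The four summary metrics plus the per-class accuracy vector.

    All values are fractions in [0, 1]; multiply by 100 for percent.
    """

    accuracy: float
    precision: float
    f_measure: float
    g_mean: float
    per_class_accuracy: np.ndarray  # tr_i / tp_i, the column convention
    recall: np.ndarray

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {
            "accuracy": self.accuracy * scale,
            "precision": self.precision * scale,
            "f_measure": self.f_measure * scale,
            "g_mean": self.g_mean * scale,
        }


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    den = np.asarray(den, dtype=float)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, macro precision, macro F, G-mean and per-class accuracy.

    A class never predicted (tp_i = 0) contributes precision 0; a class
    with no correct prediction zeroes the G-mean.
    """
    if cm.N == 0:
        raise ValueError("empty confusion matrix")
    c = cm.n_classes
    tr_i = cm.tr_i.astype(float)
    precision_i = _safe_div(tr_i, cm.tp_i)
    recall_i = _safe_div(tr_i, cm.n_i)
    pr_sum = precision_i + recall_i
    f_terms = _safe_div(2.0 * precision_i * recall_i, pr_sum)
    g_mean = float(np.prod(recall_i) ** (1.0 / c))
    return MetricReport(
        accuracy=cm.tr / cm.N,
        precision=float(precision_i.mean()),
        f_measure=float(f_terms.mean()),
        g_mean=g_mean,
        per_class_accuracy=precision_i,
        recall=recall_i,
    )


def train_test_split_indices(
    n: int, split: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Unstratified uniform split: floor(split * n) training indices."""
    if not 0 < split < 1:
        raise ValueError("split must lie in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(split * n))
    return perm[:n_train], perm[n_train:]


def repeated_split_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    combos: Sequence[tuple[str, str]],
    n_runs: int = 5,
    split: float = 0.5,
    seeds: Sequence[int] | None = None,
    epochs_n: int = 100,
    batch_size: int = 32,
    filter_counts: tuple[int, int, int] = _models.DEFAULT_FILTER_COUNTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The repeated random-split protocol over an (arch, optimizer) grid.

    For each of ``n_runs`` seeded 50/50 splits, every combination is
    trained on the training half and scored on the held-out half.  Returns
    ``(runs, summary)``: per-run metric rows, and mean +/- std per combo
    with a rank column (1 = best mean accuracy; ties broken by precision,
    then F-measure).  Deterministic given the seed list.
    """
    if not combos:
        raise ValueError("empty combination list")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError(f"{n_runs} runs need {n_runs} seeds, got {len(seeds)}")
    y = np.asarray(labels, dtype=int)
    n_classes = int(y.max()) + 1
    input_shape = tuple(np.asarray(features).shape[1:])
    rows = []
    for run, seed in enumerate(seeds):
        train_idx, test_idx = train_test_split_indices(len(y), split, seed)
        for arch_id, opt_name in combos:
            spec = build_architecture(
                arch_id, n_classes, input_shape=input_shape, filter_counts=filter_counts
            )
            model = _models.train(
                spec,
                features[train_idx],
                y[train_idx],
                optimizer=OptimizerConfig(algorithm=opt_name),
                epochs_n=epochs_n,
                batch_size=batch_size,
                seed=seed,
            )
            cm = confusion_matrix(
                y[test_idx], _models.predict(model, features[test_idx]), n_classes
            )
            rows.append(
                {
                    "arch": arch_id,
                    "optimizer": opt_name,
                    "run": run,
                    "seed": seed,
                    **metrics(cm).as_dict(),
                }
            )
    runs = pd.DataFrame(rows)
    agg = runs.groupby(["arch", "optimizer"], sort=True).agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_std=("accuracy", "std"),
        precision_mean=("precision", "mean"),
        precision_std=("precision", "std"),
        f_measure_mean=("f_measure", "mean"),
        f_measure_std=("f_measure", "std"),
        g_mean_mean=("g_mean", "mean"),
        g_mean_std=("g_mean", "std"),
    )
    summary = agg.fillna(0.0).reset_index()
    order = summary.sort_values(
        ["accuracy_mean", "precision_mean", "f_measure_mean"],
        ascending=False,
        kind="stable",
    ).index
    summary["rank"] = 0
    summary.loc[order, "rank"] = np.arange(1, len(summary) + 1)
    return runs, summary
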