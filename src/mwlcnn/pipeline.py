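"""End-to-end orchestration: simulate -> features -> labels -> grid -> ensemble.

``run_pipeline`` executes the whole classification framework on synthetic
(or previously saved) data: every (architecture, optimizer) combination is
trained as a base classifier on its own bootstrap resample of the training
half, scored on a validation split, aggregated into weighted / voting /
stacking ensembles under a member-selection strategy, and everything is
evaluated on the held-out test half.  All artifacts (features, labels,
model checkpoints, metric tables, a config echo) land in the output
directory, and the run is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import models as _models
from .ensemble import (
    ModelScore,
    SELECTION_STRATEGIES,
    bootstrap_train_sets,
    fit_stacking,
    majority_vote,
    rank_weights,
    select_members,
    weighted_average_predict,
)
from .evaluation import confusion_matrix, metrics, train_test_split_indices
from .features import STFTConfig
from .models import ARCH_IDS, OPTIMIZER_IDS, OptimizerConfig, build_architecture
from .synthetic import SimulationConfig, simulate_feature_dataset

__all__ = ["PipelineConfig", "CNNMember", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full pipeline run depends on.

    Defaults reproduce the study conditions: two full ten-condition
    sessions, the complete 5 x 4 (architecture x optimizer) grid, 80%
    bootstrap resampling of the training half, 50/50 train/test split.
    Smaller values of ``condition_duration_s``, ``epochs_n`` or the grid
    lists give proportionally cheaper runs.
    """

    case: int = 4
    n_sessions: int = 2
    seed: int = 0
    split: float = 0.5
    archs: tuple[str, ...] = ARCH_IDS
    optimizers: tuple[str, ...] = OPTIMIZER_IDS
    strategies: tuple[str, ...] = ("best-per-family", "top-half", "all")
    bootstrap_fraction: float = 0.8
    validation_fraction: float = 0.2
    epochs_n: int = 100
    batch_size: int = 32
    stacking_folds: int = 5
    filter_counts: tuple[int, int, int] = _models.DEFAULT_FILTER_COUNTS
    condition_duration_s: float = 300.0
    amplitude_gap: float = 3.0

    def __post_init__(self) -> None:
        for arch in self.archs:
            if arch not in ARCH_IDS:
                raise ValueError(f"unknown architecture {arch!r} in config")
        for opt in self.optimizers:
            if opt not in OPTIMIZER_IDS:
                raise ValueError(f"unknown optimizer {opt!r} in config")
        for s in self.strategies:
            if s not in SELECTION_STRATEGIES:
                raise ValueError(f"unknown selection strategy {s!r} in config")
        if self.case not in (4, 7):
            raise ValueError("case must be 4 or 7")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("archs", "optimizers", "strategies", "filter_counts"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class CNNMember:
    """A refittable CNN template satisfying the ensemble Member protocol."""

    arch_id: str
    n_classes: int
    optimizer: OptimizerConfig
    epochs_n: int = 100
    batch_size: int = 32
    seed: int = 0
    filter_counts: tuple[int, int, int] = _models.DEFAULT_FILTER_COUNTS
    model: _models.TrainedModel | None = None

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "CNNMember":
        spec = build_architecture(
            self.arch_id,
            self.n_classes,
            input_shape=tuple(np.asarray(features).shape[1:]),
            filter_counts=self.filter_counts,
        )
        model = _models.train(
            spec,
            features,
            labels,
            optimizer=self.optimizer,
            epochs_n=self.epochs_n,
            batch_size=self.batch_size,
            seed=self.seed,
        )
        return dataclasses.replace(self, model=model)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("member is not fitted")
        return _models.predict_proba(self.model, features)


def _metric_row(name: str, y_true: np.ndarray, y_pred: np.ndarray, c: int) -> dict:
    rep = metrics(confusion_matrix(y_true, y_pred, c))
    return {"model": name, **rep.as_dict(percent=True)}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> pd.DataFrame:
    """Execute the full framework and return the summary metric table.

    Stages: simulate sessions -> low-pass filter -> epoch -> band-power
    features -> condition labels -> train the (arch x optimizer) grid on
    bootstrap resamples -> rank on a validation split -> build ensembles
    per strategy -> evaluate everything on the test half.  The summary has
    one row per base model and per ensemble.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(
        condition_duration_s=config.condition_duration_s,
        amplitude_gap=config.amplitude_gap,
    )
    features, labels, epochs = simulate_feature_dataset(
        sim, n_sessions=config.n_sessions, case=config.case, seed=config.seed
    )
    y = labels.class_indices
    c = labels.n_classes
    labels.to_frame(epochs).to_csv(out / "labels.csv", index=False)

    train_idx, test_idx = train_test_split_indices(len(y), config.split, config.seed)
    # hold out a validation slice of the training half for accuracy ranking
    n_val = max(int(round(config.validation_fraction * len(train_idx))), 1)
    val_idx, fit_idx = train_idx[:n_val], train_idx[n_val:]

    combos = [(a, o) for a in config.archs for o in config.optimizers]
    subsets = bootstrap_train_sets(
        fit_idx, config.bootstrap_fraction, K=len(combos), seed=config.seed
    )
    scored: list[ModelScore] = []
    rows: list[dict] = []
    for j, (arch, opt) in enumerate(combos):
        member = CNNMember(
            arch_id=arch,
            n_classes=c,
            optimizer=OptimizerConfig(algorithm=opt),
            epochs_n=config.epochs_n,
            batch_size=config.batch_size,
            seed=config.seed + j,
            filter_counts=config.filter_counts,
        ).fit(features[subsets[j]], y[subsets[j]])
        val_acc = float(
            (member.predict_proba(features[val_idx]).argmax(axis=1) == y[val_idx]).mean()
        )
        scored.append(ModelScore(member, val_acc, arch_id=arch, optimizer=opt))
        rows.append(
            _metric_row(
                f"{opt}-{arch}",
                y[test_idx],
                member.predict_proba(features[test_idx]).argmax(axis=1),
                c,
            )
        )
        _models.save_model(member.model, out / f"model_{opt}_{arch}.npz")

    for strategy in config.strategies:
        members = select_members(scored, strategy)
        post = np.stack(
            [m.model.predict_proba(features[test_idx]) for m in members]
        )
        accs = [m.accuracy for m in members]
        weights = rank_weights(accs)
        rows.append(
            _metric_row(
                f"weighted[{strategy}]",
                y[test_idx],
                weighted_average_predict(post, weights),
                c,
            )
        )
        rows.append(
            _metric_row(
                f"voting[{strategy}]",
                y[test_idx],
                majority_vote(post.argmax(axis=2), accs),
                c,
            )
        )

    # stacking over the best model per family, refit by cross-validation
    stack_members = [m.model for m in select_members(scored, "best-per-family")]
    stacked = fit_stacking(
        stack_members,
        features[fit_idx],
        y[fit_idx],
        folds=config.stacking_folds,
        seed=config.seed,
    )
    rows.append(
        _metric_row("stacking", y[test_idx], stacked.predict(features[test_idx]), c)
    )

    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)
    (out / "config.json").write_text(
        json.dumps({"digest": config.digest(), **config.to_dict()}, indent=1)
    )
    return summary
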