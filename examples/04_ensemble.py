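"""Build and compare the three ensemble aggregation rules.

Trains a small grid of base CNNs on bootstrap resamples of synthetic data,
combines them by rank-weighted averaging, majority voting and stacking,
and compares against the average base member.
"""

import numpy as np

from mwlcnn import models, synthetic
from mwlcnn.ensemble import (
    ModelScore,
    bootstrap_train_sets,
    fit_stacking,
    majority_vote,
    rank_weights,
    select_members,
    weighted_average_predict,
)
from mwlcnn.evaluation import train_test_split_indices
from mwlcnn.pipeline import CNNMember

cfg = synthetic.SimulationConfig(condition_duration_s=30.0, amplitude_gap=3.0)
X, labels, _ = synthetic.simulate_feature_dataset(cfg, n_sessions=2, case=4, seed=2)
y = labels.class_indices
train_idx, test_idx = train_test_split_indices(len(y), 0.5, seed=0)
val_idx, fit_idx = train_idx[:20], train_idx[20:]

# six members: three architectures x two optimizers, each on its own
# 80% bootstrap resample of the training half
grid = [(a, o) for a in ("CNN1", "CNN2", "CNN3") for o in ("nm", "adam")]
subsets = bootstrap_train_sets(fit_idx, fraction=0.8, K=len(grid), seed=0)
scored = []
for j, (arch, opt) in enumerate(grid):
    member = CNNMember(arch, 4, models.OptimizerConfig(opt), epochs_n=80,
                       batch_size=16, seed=j).fit(X[subsets[j]], y[subsets[j]])
    val_acc = (member.predict_proba(X[val_idx]).argmax(1) == y[val_idx]).mean()
    scored.append(ModelScore(member, float(val_acc), arch, opt))
    print(f"  {opt}-{arch}: validation accuracy {100 * val_acc:.1f}%")

members = select_members(scored, "top-half")
post = np.stack([s.model.predict_proba(X[test_idx]) for s in members])
accs = [s.accuracy for s in members]
test_accs = [(p.argmax(1) == y[test_idx]).mean() for p in post]

w = rank_weights(accs)
weighted = (weighted_average_predict(post, w) == y[test_idx]).mean()
voting = (majority_vote(post.argmax(axis=2), accs) == y[test_idx]).mean()
stack = fit_stacking([s.model for s in members], X[fit_idx], y[fit_idx],
                     folds=3, seed=0)
stacked = (stack.predict(X[test_idx]) == y[test_idx]).mean()

print(f"rank weights of the top-half members: {np.round(w, 3)}")
print(f"mean member test accuracy : {100 * np.mean(test_accs):.1f}%")
print(f"weighted averaging        : {100 * weighted:.1f}%")
print(f"majority voting           : {100 * voting:.1f}%")
print(f"stacking                  : {100 * stacked:.1f}%")
print("Aggregating diverse base classifiers should match or beat the "
      "average member; weighted averaging favors the better-ranked models.")
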