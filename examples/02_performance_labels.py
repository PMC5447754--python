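"""Task-performance labels: TIR, the performance indicator and clustering.

Pools zone-flag traces from several simulated sessions, computes per-epoch
PI = 0.7*TIR + 0.3*NOS and selects the workload class count with the
average silhouette index.
"""

import numpy as np

from mwlcnn.labeling import cluster_labels, select_num_classes
from mwlcnn.signal_io import RecordingSession, segment_epochs
from mwlcnn.synthetic import SimulationConfig, pi_per_epoch, simulate_zone_flags

cfg = SimulationConfig(condition_duration_s=60.0)
schedule = cfg.schedule()

# PI needs only the flag traces; a blank session supplies the epoch grid
n = int(schedule.total_duration_s * cfg.sampling_rate_hz)
blank = RecordingSession("blank", ("c",), cfg.sampling_rate_hz,
                         np.zeros((1, n), dtype=np.float32), schedule)
epochs = segment_epochs(blank)

pis = []
for s in range(8):
    rng = np.random.default_rng([7, s])
    flags = simulate_zone_flags(cfg, schedule, rng)
    pis.append(pi_per_epoch(flags, epochs, schedule))
pi = np.concatenate(pis)
print(f"{len(pi)} per-epoch performance-indicator values, "
      f"range [{pi.min():.2f}, {pi.max():.2f}]")

best_k, curve = select_num_classes(pi, range(2, 11), seed=0)
print(curve.to_string(index=False))
print(f"silhouette-selected class count: k = {best_k} "
      "(the four task-difficulty levels NOS = 0/2/3/4)")

labels = cluster_labels(pi, best_k, seed=0)
nos = np.tile([schedule[c].nos for c in epochs.condition_ids], 8)
nos_rank = np.searchsorted(np.unique(nos), nos)  # NOS level as 0..3
agree = (labels == nos_rank).mean()
print(f"cluster labels agree with the NOS grouping on {100 * agree:.1f}% of epochs")
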