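"""Target workload labels: condition mapping and performance-based clustering.

Two labeling routes are provided.  The default maps each epoch's task-load
condition to a class directly: Case 1 uses the number of manually controlled
subsystems (NOS) alone and yields four classes (Unloaded/Low/Normal/High);
Case 2 additionally splits on actuator sensitivity (AS) and yields seven
(Unloaded/Very Low/Low/Medium/High/Very High/Overloaded).

The alternative route derives labels from task performance.  Time In Range
(TIR) is the fraction of time the four controlled subsystems (O2, pressure,
CO2, temperature) stay inside their target zones; the performance indicator
PI = 0.7*TIR + 0.3*NOS combines it with task difficulty.  k-means on the
per-epoch PI values, with the class count chosen by the average silhouette
index, recovers workload classes without using the schedule directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .signal_io import ConditionSchedule, EpochSet

__all__ = [
    "CASE1_CLASSES",
    "CASE2_CLASSES",
    "LabelSet",
    "SilhouetteResult",
    "compute_tir",
    "compute_pi",
    "silhouette",
    "select_num_classes",
    "assign_condition_labels",
    "cluster_labels",
]

CASE1_CLASSES = ("Unloaded", "Low", "Normal", "High")
CASE2_CLASSES = (
    "Unloaded",
    "Very Low",
    "Low",
    "Medium",
    "High",
    "Very High",
    "Overloaded",
)

#: NOS -> Case-1 class index (0 manual subsystems = resting baseline).
_NOS_TO_CASE1 = {0: 0, 2: 1, 3: 2, 4: 3}
#: (NOS, AS) -> Case-2 class index.
_NOSAS_TO_CASE2 = {
    (0, "none"): 0,
    (2, "low"): 1,
    (2, "high"): 2,
    (3, "low"): 3,
    (3, "high"): 4,
    (4, "low"): 5,
    (4, "high"): 6,
}


@dataclass
class LabelSet:
    """Per-epoch target class labels for one of the two cases."""

    case: int  # 4 or 7
    class_indices: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.class_indices = np.asarray(self.class_indices, dtype=int)
        if self.case not in (4, 7):
            raise ValueError("case must be 4 or 7")
        if self.class_indices.size and not (
            (self.class_indices >= 0) & (self.class_indices < self.case)
        ).all():
            raise ValueError("class index out of range")

    @property
    def n_classes(self) -> int:
        return self.case

    def names(self) -> np.ndarray:
        return np.asarray(self.class_names, dtype=object)[self.class_indices]

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.class_indices, minlength=self.case)

    def to_frame(self, epochs: EpochSet | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "epoch_index": np.arange(len(self.class_indices)),
                "case": self.case,
                "class_index": self.class_indices,
                "class_name": self.names(),
            }
        )
        if epochs is not None:
            df.insert(1, "session_id", epochs.session_ids)
            df.insert(2, "condition_id", epochs.condition_ids)
        return df


def compute_tir(flags: np.ndarray) -> float:
    """Time-in-range score of a window of zone flags.

    ``flags`` is (n_instants, 4) boolean — one column per subsystem (O2,
    pressure, CO2, temperature).  At each instant the in-range fraction is
    the mean of the four flags; TIR is the mean over instants, in [0, 1].
    """
    flags = np.asarray(flags)
    if flags.ndim != 2 or flags.shape[1] != 4:
        raise ValueError("flags must be (n_instants, 4)")
    if flags.shape[0] == 0:
        raise ValueError("empty flag window")
    return float(flags.astype(float).mean())


def compute_pi(tir: float, nos: int, c1: float = 0.7, c2: float = 0.3) -> float:
    """Performance indicator PI = c1*TIR + c2*NOS.

    The default weights 0.7/0.3 mix task performance with task difficulty;
    NOS enters on its native 0-4 scale, so PI is not bounded by 1.
    """
    if not 0.0 <= tir <= 1.0:
        raise ValueError(f"TIR must lie in [0, 1], got {tir}")
    return c1 * tir + c2 * nos


@dataclass
class SilhouetteResult:
    """Per-point silhouette scores and their average."""

    s: np.ndarray  # S(i) per point, in [-1, 1]
    a: np.ndarray  # mean within-cluster distance
    b: np.ndarray  # min over other clusters of mean distance

    @property
    def mean(self) -> float:
        return float(self.s.mean())


def silhouette(points: np.ndarray, assignment: np.ndarray) -> SilhouetteResult:
    """Silhouette index S(i) = (b(i) - a(i)) / max(a(i), b(i)).

    a(i) is the average Euclidean distance from point i to the other
    members of its own cluster; b(i) the smallest average distance to the
    points of any other cluster.  Points in singleton clusters score 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1 and points.shape[1] > 1 and np.asarray(assignment).size == points.shape[1]:
        points = points.T  # accept a 1-D series of scalars
    assignment = np.asarray(assignment)
    n = points.shape[0]
    if assignment.shape != (n,):
        raise ValueError("assignment must have one cluster id per point")
    labels, inverse = np.unique(assignment, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("silhouette requires at least two clusters")
    dist = cdist(points, points)
    # mean distance from each point to the members of every cluster
    sums = np.zeros((n, k))
    counts = np.bincount(inverse, minlength=k)
    for c in range(k):
        sums[:, c] = dist[:, inverse == c].sum(axis=1)
    own = counts[inverse]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_to = sums / counts[None, :]
        a = np.where(own > 1, sums[np.arange(n), inverse] / np.maximum(own - 1, 1), 0.0)
    mean_to[np.arange(n), inverse] = np.inf
    b = mean_to.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(own > 1, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return SilhouetteResult(s=s, a=a, b=b)


def select_num_classes(
    pi_series: np.ndarray,
    k_range: range | tuple[int, ...] = range(2, 11),
    seed: int = 0,
    n_init: int = 20,
) -> tuple[int, pd.DataFrame]:
    """Choose the class count by the average silhouette over k-means fits.

    Runs k-means (``n_init`` restarts, fixed seed) for each candidate k and
    scores the partition with the average silhouette index.  Returns the
    best k (ties toward smaller k) and the full curve as a DataFrame with
    columns ``k``, ``mean_silhouette`` and ``is_local_max``.
    """
    pts = np.asarray(pi_series, dtype=float).reshape(-1, 1)
    if np.ptp(pts) == 0:
        raise ValueError("constant series cannot be clustered")
    ks = sorted(k_range)
    if len(pts) <= max(ks):
        raise ValueError("not enough points for the largest k")
    scores = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(pts)
        scores.append(silhouette(pts, labels).mean)
    scores = np.asarray(scores)
    local_max = np.zeros(len(ks), dtype=bool)
    for i in range(len(ks)):
        left = scores[i - 1] if i > 0 else -np.inf
        right = scores[i + 1] if i + 1 < len(ks) else -np.inf
        local_max[i] = scores[i] >= left and scores[i] >= right
    best_k = ks[int(np.argmax(scores))]  # argmax takes the first (smallest) tie
    curve = pd.DataFrame({"k": ks, "mean_silhouette": scores, "is_local_max": local_max})
    return best_k, curve


def assign_condition_labels(
    schedule: ConditionSchedule, epochs: EpochSet, case: int = 4
) -> LabelSet:
    """Label every epoch from its task-load condition.

    Case 1 maps NOS 0/2/3/4 to Unloaded/Low/Normal/High; Case 2 maps the
    (NOS, AS) pair to the seven-level scale.  Two concatenated full
    sessions give class sizes 1160/580/580/580 (Case 1) or 1160 plus six
    classes of 290 (Case 2).
    """
    if case not in (4, 7):
        raise ValueError("case must be 4 or 7")
    cond_to_class: dict[int, int] = {}
    for cond in schedule:
        if case == 4:
            cond_to_class[cond.condition_id] = _NOS_TO_CASE1[cond.nos]
        else:
            key = (cond.nos, cond.actuator_sensitivity)
            if key not in _NOSAS_TO_CASE2:
                raise ValueError(f"no 7-class level for NOS={cond.nos}, AS={key[1]}")
            cond_to_class[cond.condition_id] = _NOSAS_TO_CASE2[key]
    unknown = set(np.unique(epochs.condition_ids)) - set(cond_to_class)
    if unknown:
        raise ValueError(f"epochs reference unknown condition ids {sorted(unknown)}")
    indices = np.array([cond_to_class[c] for c in epochs.condition_ids], dtype=int)
    names = CASE1_CLASSES if case == 4 else CASE2_CLASSES
    return LabelSet(case=case, class_indices=indices, class_names=names)


def cluster_labels(
    pi_series: np.ndarray, n_classes: int, seed: int = 0, n_init: int = 20
) -> np.ndarray:
    """k-means labels on per-epoch PI values, clusters ordered by center.

    Cluster ids are remapped so that class 0 has the lowest PI center;
    with PI = 0.7*TIR + 0.3*NOS higher indices then mean higher load.
    """
    pts = np.asarray(pi_series, dtype=float).reshape(-1, 1)
    km = KMeans(n_clusters=n_classes, n_init=n_init, random_state=seed)
    raw = km.fit_predict(pts)
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(n_classes, dtype=int)
    remap[order] = np.arange(n_classes)
    return remap[raw]
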