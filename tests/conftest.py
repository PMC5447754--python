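"""Shared fixtures: printed reference confusion matrices and tiny sessions."""

from __future__ import annotations

import numpy as np
import pytest

from mwlcnn.signal_io import (
    Condition,
    ConditionSchedule,
    RecordingSession,
    default_channel_labels,
    default_schedule,
)

# Published 4-class confusion matrix (rows = target, cols = estimated) of the
# best single model, and its printed per-class accuracies (percent).
TABLE_CASE1 = np.array(
    [
        [585, 10, 7, 2],
        [7, 264, 12, 1],
        [8, 7, 260, 13],
        [1, 3, 6, 264],
    ]
)
TABLE_CASE1_ACC = (97.3, 93.0, 91.2, 94.3)

# The 7-class counterpart.
TABLE_CASE2 = np.array(
    [
        [588, 1, 4, 4, 1, 1, 1],
        [4, 115, 3, 2, 0, 2, 2],
        [3, 9, 132, 2, 3, 1, 0],
        [7, 4, 8, 116, 5, 1, 4],
        [1, 0, 1, 6, 138, 3, 0],
        [0, 0, 6, 2, 5, 128, 1],
        [1, 1, 0, 4, 0, 0, 130],
    ]
)
TABLE_CASE2_ACC = (97.4, 88.5, 85.7, 85.3, 90.8, 94.1, 94.2)

# Published per-session time-in-range values for the hardest three-subsystem
# condition (condition 6), one row per session, and the printed column mean.
TIR_COND6 = [0.74, 0.68, 0.66, 0.71, 0.69, 0.73, 0.66, 0.70, 0.84, 0.84, 0.78, 0.76]
TIR_COND6_MEAN = 0.732


@pytest.fixture
def table_case1() -> np.ndarray:
    return TABLE_CASE1.copy()


@pytest.fixture
def table_case2() -> np.ndarray:
    return TABLE_CASE2.copy()


def short_schedule(duration_s: float = 14.0) -> ConditionSchedule:
    """A miniature ten-condition schedule for fast structural tests."""
    return default_schedule(duration_s)


@pytest.fixture
def tiny_session() -> RecordingSession:
    """A 17-channel random session over a miniature ten-condition schedule."""
    schedule = short_schedule(14.0)
    rate = 500.0
    n = int(schedule.total_duration_s * rate)
    rng = np.random.default_rng(7)
    return RecordingSession(
        session_id="tiny",
        channel_labels=default_channel_labels(),
        sampling_rate_hz=rate,
        samples=rng.standard_normal((17, n)),
        schedule=schedule,
    )


@pytest.fixture
def two_condition_session() -> RecordingSession:
    """Two manual-free conditions, 20 s each, 3 channels at 100 Hz."""
    schedule = ConditionSchedule(
        (
            Condition(1, "auto", 0, "none", 20.0),
            Condition(2, "mixed", 2, "low", 20.0),
        )
    )
    rate = 100.0
    rng = np.random.default_rng(3)
    return RecordingSession(
        session_id="two",
        channel_labels=("a", "b", "c"),
        sampling_rate_hz=rate,
        samples=rng.standard_normal((3, int(40.0 * rate))),
        schedule=schedule,
    )
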