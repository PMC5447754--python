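"""Loading, filtering and epoching of multichannel physiological recordings.

A recording session is a channels x time array sampled at a fixed rate,
accompanied by a schedule of task-load conditions.  Each condition is defined
by the number of subsystems under manual control (NOS: 0, 2, 3 or 4) and the
actuator sensitivity (AS: none for automatic conditions, otherwise low/high).
The default schedule is the ten-condition session used throughout the
package: four automatic baseline conditions interleaved with six manual
conditions, each lasting 300 s.

Sessions round-trip through CSV (one column per channel plus ``time_s``, with
the schedule in a sidecar JSON file) or a single HDF5 file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Condition",
    "ConditionSchedule",
    "RecordingSession",
    "EpochSet",
    "default_schedule",
    "default_channel_labels",
    "load_recording",
    "write_recording",
    "lowpass_filter",
    "segment_epochs",
]

DEFAULT_SAMPLING_RATE_HZ = 500.0
DEFAULT_N_CHANNELS = 17

_CONTROL_MODES = ("auto", "manual", "mixed")
_AS_LEVELS = ("none", "low", "high")


@dataclass(frozen=True)
class Condition:
    """One task-load condition: control mode, NOS, AS and duration."""

    condition_id: int
    control_mode: str
    nos: int
    actuator_sensitivity: str
    duration_s: float = 300.0

    def __post_init__(self) -> None:
        if self.control_mode not in _CONTROL_MODES:
            raise ValueError(f"unknown control mode {self.control_mode!r}")
        if self.actuator_sensitivity not in _AS_LEVELS:
            raise ValueError(f"unknown AS level {self.actuator_sensitivity!r}")
        if self.nos not in (0, 2, 3, 4):
            raise ValueError(f"NOS must be one of 0, 2, 3, 4; got {self.nos}")
        if (self.nos == 0) != (self.control_mode == "auto"):
            raise ValueError("NOS=0 exactly for automatic conditions")
        if (self.actuator_sensitivity == "none") != (self.nos == 0):
            raise ValueError("AS='none' exactly for automatic (NOS=0) conditions")
        if self.duration_s <= 0:
            raise ValueError("condition duration must be positive")


@dataclass(frozen=True)
class ConditionSchedule:
    """Ordered task-load conditions of a session.

    Condition ids must be unique and contiguous from 1, in order.
    """

    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        ids = [c.condition_id for c in self.conditions]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("condition ids must be contiguous from 1 and ordered")

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def __getitem__(self, condition_id: int) -> Condition:
        for cond in self.conditions:
            if cond.condition_id == condition_id:
                return cond
        raise KeyError(f"no condition with id {condition_id}")

    @property
    def total_duration_s(self) -> float:
        return float(sum(c.duration_s for c in self.conditions))

    def start_times(self) -> dict[int, float]:
        """Start time (s from session start) of each condition."""
        starts, t = {}, 0.0
        for cond in self.conditions:
            starts[cond.condition_id] = t
            t += cond.duration_s
        return starts

    def to_records(self) -> list[dict]:
        return [
            {
                "condition_id": c.condition_id,
                "control_mode": c.control_mode,
                "nos": c.nos,
                "actuator_sensitivity": c.actuator_sensitivity,
                "duration_s": c.duration_s,
            }
            for c in self.conditions
        ]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "ConditionSchedule":
        try:
            conds = tuple(
                Condition(
                    condition_id=int(r["condition_id"]),
                    control_mode=str(r["control_mode"]),
                    nos=int(r["nos"]),
                    actuator_sensitivity=str(r["actuator_sensitivity"]),
                    duration_s=float(r["duration_s"]),
                )
                for r in records
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"unparseable schedule: {exc}") from exc
        return cls(conds)


def default_schedule(duration_s: float = 300.0) -> ConditionSchedule:
    """The standard ten-condition session.

    Conditions 1, 4, 7 and 10 are automatic baselines (NOS=0).  Conditions
    2/3 put two subsystems under manual control (AS low/high), 5/6 three
    subsystems, and 8/9 all four.
    """
    spec = [
        (1, "auto", 0, "none"),
        (2, "mixed", 2, "low"),
        (3, "mixed", 2, "high"),
        (4, "auto", 0, "none"),
        (5, "mixed", 3, "low"),
        (6, "mixed", 3, "high"),
        (7, "auto", 0, "none"),
        (8, "manual", 4, "low"),
        (9, "manual", 4, "high"),
        (10, "auto", 0, "none"),
    ]
    return ConditionSchedule(
        tuple(Condition(i, mode, nos, a, duration_s) for i, mode, nos, a in spec)
    )


def default_channel_labels(n_channels: int = DEFAULT_N_CHANNELS) -> tuple[str, ...]:
    return tuple(f"ch{i + 1:02d}" for i in range(n_channels))


@dataclass
class RecordingSession:
    """A multichannel recording plus its condition schedule.

    ``samples`` is a (channels, time) array.  The total length is validated
    against the schedule at epoching time, not at load time.
    """

    session_id: str
    channel_labels: tuple[str, ...]
    sampling_rate_hz: float
    samples: np.ndarray
    schedule: ConditionSchedule

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class EpochSet:
    """Fixed-length, non-overlapping epochs cut from one or more sessions.

    ``data`` is (n_epochs, channels, samples); ``condition_ids``,
    ``start_times_s`` and ``session_ids`` are per-epoch parallel arrays.
    """

    data: np.ndarray
    condition_ids: np.ndarray
    start_times_s: np.ndarray
    session_ids: np.ndarray
    window_s: float
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.data)
        for name in ("condition_ids", "start_times_s", "session_ids"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_epochs {n}")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.data)

    @staticmethod
    def concatenate(epoch_sets: Sequence["EpochSet"]) -> "EpochSet":
        first = epoch_sets[0]
        for es in epoch_sets[1:]:
            if es.window_s != first.window_s or es.sampling_rate_hz != first.sampling_rate_hz:
                raise ValueError("epoch sets have incompatible window or rate")
        return EpochSet(
            data=np.concatenate([es.data for es in epoch_sets]),
            condition_ids=np.concatenate([es.condition_ids for es in epoch_sets]),
            start_times_s=np.concatenate([es.start_times_s for es in epoch_sets]),
            session_ids=np.concatenate([es.session_ids for es in epoch_sets]),
            window_s=first.window_s,
            sampling_rate_hz=first.sampling_rate_hz,
        )


class SchemaError(ValueError):
    """The file does not match the declared channel layout."""


def _schedule_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".schedule.json")


def write_recording(session: RecordingSession, path: str | Path, format: str | None = None) -> Path:
    """Write a session to CSV (+ sidecar schedule JSON) or HDF5.

    The format is inferred from the extension when not given.  HDF5
    round-trips are bit-exact; CSV stores samples in decimal text with
    full float64 precision (17 significant digits).
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        t = np.arange(session.n_samples) / session.sampling_rate_hz
        df = pd.DataFrame(session.samples.T, columns=list(session.channel_labels))
        df.insert(0, "time_s", t)
        df.to_csv(path, index=False, float_format="%.17g")
        meta = {
            "session_id": session.session_id,
            "sampling_rate_hz": session.sampling_rate_hz,
            "schedule": session.schedule.to_records(),
        }
        _schedule_sidecar(path).write_text(json.dumps(meta, indent=1))
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=session.samples)
            f.attrs["session_id"] = session.session_id
            f.attrs["sampling_rate_hz"] = session.sampling_rate_hz
            f.attrs["channel_labels"] = list(session.channel_labels)
            f.create_dataset(
                "schedule", data=json.dumps(session.schedule.to_records())
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def load_recording(
    path: str | Path,
    format: str | None = None,
    expected_channels: int = DEFAULT_N_CHANNELS,
) -> RecordingSession:
    """Load a session written by :func:`write_recording`.

    Raises :class:`SchemaError` when the channel count differs from
    ``expected_channels`` (pass ``None`` to accept any count) and
    ``ValueError`` when the schedule block cannot be parsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if "time_s" not in df.columns:
            raise SchemaError("CSV is missing the time_s column")
        labels = tuple(c for c in df.columns if c != "time_s")
        sidecar = _schedule_sidecar(path)
        if not sidecar.exists():
            raise ValueError(f"missing schedule sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        schedule = ConditionSchedule.from_records(meta["schedule"])
        session = RecordingSession(
            session_id=str(meta.get("session_id", path.stem)),
            channel_labels=labels,
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            samples=df[list(labels)].to_numpy().T,
            schedule=schedule,
        )
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            labels = tuple(
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f.attrs["channel_labels"]
            )
            schedule = ConditionSchedule.from_records(
                json.loads(f["schedule"][()].decode())
            )
            session = RecordingSession(
                session_id=str(f.attrs["session_id"]),
                channel_labels=labels,
                sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
                samples=f["signals"][()],
                schedule=schedule,
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if expected_channels is not None and session.n_channels != expected_channels:
        raise SchemaError(
            f"expected {expected_channels} channels, file has {session.n_channels}"
        )
    return session


def lowpass_filter(
    session: RecordingSession, cutoff_hz: float = 40.0, order: int = 4
) -> RecordingSession:
    """Zero-phase Butterworth low-pass filter applied to every channel.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    passband is phase-preserving and the effective attenuation is twice the
    single-pass magnitude response.  The default 40 Hz cutoff keeps the six
    rhythm bands (1-40 Hz) and removes higher-frequency noise.
    """
    nyquist = session.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=session.sampling_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, session.samples, axis=1)
    return replace(session, samples=filtered)


def segment_epochs(
    session: RecordingSession,
    window_s: float = 2.0,
    trim_s: float = 5.0,
    strict: bool = True,
) -> EpochSet:
    """Cut non-overlapping epochs from each condition of a session.

    The first and last ``trim_s`` seconds of every condition are discarded
    and the remainder is tiled with left-aligned ``window_s`` windows, so a
    condition of duration ``d`` yields ``floor((d - 2*trim)/window)`` epochs.
    With the 300 s / 5 s / 2 s defaults that is 145 per condition and 1450
    for a full ten-condition session.

    With ``strict`` (default) a condition too short for a single window
    raises; otherwise it silently contributes no epochs.
    """
    rate = session.sampling_rate_hz
    win = int(round(window_s * rate))
    total_needed = int(round(session.schedule.total_duration_s * rate))
    if session.n_samples < total_needed:
        raise ValueError(
            f"session has {session.n_samples} samples but the schedule "
            f"requires {total_needed}"
        )
    data, cond_ids, starts = [], [], []
    t0 = 0.0
    for cond in session.schedule:
        usable = cond.duration_s - 2.0 * trim_s
        n_windows = int(np.floor(usable / window_s)) if usable > 0 else 0
        if n_windows < 1 and strict:
            raise ValueError(
                f"condition {cond.condition_id} ({cond.duration_s} s) is too "
                f"short for trim {trim_s} s and window {window_s} s"
            )
        for k in range(n_windows):
            start_t = t0 + trim_s + k * window_s
            i0 = int(round(start_t * rate))
            data.append(session.samples[:, i0 : i0 + win])
            cond_ids.append(cond.condition_id)
            starts.append(start_t)
        t0 += cond.duration_s
    n = len(data)
    return EpochSet(
        data=np.stack(data) if n else np.empty((0, session.n_channels, win)),
        condition_ids=np.array(cond_ids, dtype=int),
        start_times_s=np.array(starts, dtype=float),
        session_ids=np.array([session.session_id] * n, dtype=object),
        window_s=window_s,
        sampling_rate_hz=rate,
    )
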