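"""Synthetic multichannel sessions with workload-dependent band structure.

The generator emulates the statistical skeleton of an operator-workload
experiment on a process-control simulator: a ten-condition schedule (four
automatic baselines, six manual conditions of increasing difficulty),
17-channel oscillatory signals whose six rhythm-band amplitudes depend on
the workload class, broadband white + 1/f background noise, and per-instant
zone flags for the four controlled subsystems whose condition means match
the published average time-in-range values (about 0.96 for the easiest
manual condition down to 0.57 for the hardest).

Band oscillations are realized as band-pass-filtered Gaussian noise rather
than pure tones, so class separation rests on band *power*, not on spectral
lines.  With increasing load the theta and alpha amplitudes rise and the
beta amplitudes fall; the size of that modulation is the ``amplitude_gap``
parameter (ratio at the highest load relative to baseline, interpolated
linearly across the four load levels).  The gap is a free effect-size knob
of the simulation, not a physiological estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .features import DEFAULT_BANDS, STFTConfig, BandDefinition, extract_features
from .labeling import _NOS_TO_CASE1, LabelSet, assign_condition_labels, compute_tir
from .signal_io import (
    ConditionSchedule,
    EpochSet,
    RecordingSession,
    default_channel_labels,
    default_schedule,
    lowpass_filter,
    segment_epochs,
)

__all__ = [
    "SimulationConfig",
    "DEFAULT_TIR_MEANS",
    "class_band_multipliers",
    "simulate_session",
    "simulate_zone_flags",
    "tir_per_epoch",
    "pi_per_epoch",
    "simulated_tir_check",
    "simulate_feature_dataset",
]

#: Published per-condition average time-in-range values, keyed by (NOS, AS).
#: Automatic baselines have no published value; near-ceiling performance of
#: the automatic controllers is assumed.
DEFAULT_TIR_MEANS: Mapping[tuple[int, str], float] = {
    (0, "none"): 0.98,
    (2, "low"): 0.959,
    (2, "high"): 0.795,
    (3, "low"): 0.945,
    (3, "high"): 0.732,
    (4, "low"): 0.863,
    (4, "high"): 0.571,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the session generator.

    ``base_band_amplitudes`` are the baseline (unloaded) standard
    deviations of the six band oscillations in signal units, ordered as
    delta/theta/alpha/lower-beta/higher-beta/gamma.  ``amplitude_gap``
    scales theta/alpha up and the beta bands down with load (see module
    docstring).  ``tir_concentration`` controls the session-to-session
    dispersion of the zone-flag probability (Beta concentration; larger is
    tighter).
    """

    n_channels: int = 17
    sampling_rate_hz: float = 500.0
    condition_duration_s: float = 300.0
    base_band_amplitudes: tuple[float, ...] = (4.0, 8.0, 10.0, 5.0, 4.0, 2.0)
    amplitude_gap: float = 3.0
    white_noise_sigma: float = 2.0
    pink_noise_sigma: float = 4.0
    tir_means: Mapping[tuple[int, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TIR_MEANS)
    )
    tir_concentration: float = 100.0
    flag_interval_s: float = 0.25
    bands: BandDefinition = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if len(self.base_band_amplitudes) != len(self.bands):
            raise ValueError("need one base amplitude per band")
        if any(a < 0 for a in self.base_band_amplitudes):
            raise ValueError("band amplitudes must be nonnegative")
        if self.amplitude_gap <= 0:
            raise ValueError("amplitude_gap must be positive")
        for key, m in self.tir_means.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"TIR mean {m} for {key} outside [0, 1]")

    def schedule(self) -> ConditionSchedule:
        return default_schedule(self.condition_duration_s)


def class_band_multipliers(config: SimulationConfig, n_classes: int = 4) -> np.ndarray:
    """(n_classes, n_bands) amplitude multipliers, load increasing by row.

    At load level l in [0, 1] (class index / (n_classes - 1)) the theta and
    alpha amplitudes are multiplied by 1 + (gap - 1) * l and the two beta
    bands divided by the same factor; delta and gamma stay flat.
    """
    g = config.amplitude_gap
    names = config.bands.names
    mult = np.ones((n_classes, len(names)))
    for cls in range(n_classes):
        load = cls / (n_classes - 1)
        factor = 1.0 + (g - 1.0) * load
        for b, name in enumerate(names):
            if name in ("theta", "alpha"):
                mult[cls, b] = factor
            elif name in ("lower_beta", "higher_beta"):
                mult[cls, b] = 1.0 / factor
    return mult


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = 1.0 / np.sqrt(np.maximum(freqs, freqs[1]))
    scale[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    return pink / np.where(sd > 0, sd, 1.0)


def _band_sos(lo: float, hi: float, fs: float):
    return sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")


def simulate_session(
    config: SimulationConfig, session_id: str, seed: int = 0
) -> tuple[RecordingSession, pd.DataFrame]:
    """One synthetic session: signals plus the zone-flag trace.

    Per condition, each channel is the sum of six band-limited noise
    oscillations (standard deviation = base amplitude x class multiplier,
    with a fixed per-channel gain drawn once per session) plus white and
    pink noise.  Zone flags are drawn by :func:`simulate_zone_flags` with
    the same generator.  Bit-identical output for identical seeds.
    """
    rng = np.random.default_rng([int(seed), 0x5E55])
    schedule = config.schedule()
    fs = config.sampling_rate_hz
    n_ch = config.n_channels
    mult = class_band_multipliers(config)
    # per-channel gain heterogeneity, fixed for the session
    channel_gain = rng.uniform(0.8, 1.2, size=(n_ch, 1))
    sos_bands = [_band_sos(lo, hi, fs) for _, lo, hi in config.bands.bands]

    chunks = []
    for cond in schedule:
        n = int(round(cond.duration_s * fs))
        cls = _NOS_TO_CASE1[cond.nos]
        x = config.white_noise_sigma * rng.standard_normal((n_ch, n))
        x += config.pink_noise_sigma * _pink_noise(rng, (n_ch, n))
        for b, sos in enumerate(sos_bands):
            target_sd = config.base_band_amplitudes[b] * mult[cls, b]
            if target_sd == 0:
                continue
            osc = sps.sosfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
            sd = osc.std(axis=1, keepdims=True)
            x += osc / np.where(sd > 0, sd, 1.0) * target_sd
        chunks.append(x * channel_gain)
    samples = np.concatenate(chunks, axis=1)
    session = RecordingSession(
        session_id=session_id,
        channel_labels=default_channel_labels(n_ch),
        sampling_rate_hz=fs,
        samples=samples,
        schedule=schedule,
    )
    flags = simulate_zone_flags(config, schedule, rng)
    return session, flags


def simulate_zone_flags(
    config: SimulationConfig,
    schedule: ConditionSchedule,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-instant boolean zone flags for the four subsystems.

    For each condition the in-zone probability is drawn once from a Beta
    distribution centered on the configured mean (concentration
    ``tir_concentration``), then flags are i.i.d. Bernoulli per instant and
    subsystem.  Columns: time_s, condition_id, r_o2, r_p, r_co2, r_t.
    The default 0.25 s instant spacing keeps per-epoch TIR values from
    collapsing onto a handful of lattice points (the controlled system's
    zone membership is effectively continuous in time).
    """
    rows_t, rows_c, flag_blocks = [], [], []
    t0 = 0.0
    kappa = config.tir_concentration
    for cond in schedule:
        m = config.tir_means[(cond.nos, cond.actuator_sensitivity)]
        if 0.0 < m < 1.0 and kappa > 0:
            p = rng.beta(m * kappa, (1.0 - m) * kappa)
        else:
            p = m
        n_inst = int(round(cond.duration_s / config.flag_interval_s))
        times = t0 + config.flag_interval_s * np.arange(n_inst)
        flag_blocks.append(rng.random((n_inst, 4)) < p)
        rows_t.append(times)
        rows_c.append(np.full(n_inst, cond.condition_id))
        t0 += cond.duration_s
    flags = np.concatenate(flag_blocks)
    df = pd.DataFrame(
        {
            "time_s": np.concatenate(rows_t),
            "condition_id": np.concatenate(rows_c).astype(int),
            "r_o2": flags[:, 0],
            "r_p": flags[:, 1],
            "r_co2": flags[:, 2],
            "r_t": flags[:, 3],
        }
    )
    return df


_FLAG_COLS = ["r_o2", "r_p", "r_co2", "r_t"]


def tir_per_epoch(flags: pd.DataFrame, epochs: EpochSet) -> np.ndarray:
    """Time-in-range of each epoch's [start, start + window) span."""
    times = flags["time_s"].to_numpy()
    values = flags[_FLAG_COLS].to_numpy()
    out = np.empty(len(epochs))
    for i, start in enumerate(epochs.start_times_s):
        mask = (times >= start) & (times < start + epochs.window_s)
        if not mask.any():  # no instant inside: nearest preceding instant
            mask = times <= start
            sel = values[mask][-1:]
        else:
            sel = values[mask]
        out[i] = compute_tir(sel)
    return out


def pi_per_epoch(
    flags: pd.DataFrame,
    epochs: EpochSet,
    schedule: ConditionSchedule,
    c1: float = 0.7,
    c2: float = 0.3,
) -> np.ndarray:
    """Performance indicator c1*TIR + c2*NOS per epoch."""
    tir = tir_per_epoch(flags, epochs)
    nos = np.array([schedule[c].nos for c in epochs.condition_ids])
    return c1 * tir + c2 * nos


def simulated_tir_check(
    config: SimulationConfig, n_sessions: int, seed: int = 0
) -> pd.DataFrame:
    """Empirical per-condition mean TIR over simulated sessions.

    Only the zone-flag traces are generated, so this is cheap even for many
    sessions.  Returns a DataFrame with condition_id, nos,
    actuator_sensitivity, mean_tir and the configured target mean.
    """
    if n_sessions < 1:
        raise ValueError("need at least one session")
    schedule = config.schedule()
    sums = {c.condition_id: 0.0 for c in schedule}
    for s in range(n_sessions):
        rng = np.random.default_rng([seed, s, 0xF1A6])
        flags = simulate_zone_flags(config, schedule, rng)
        by_cond = flags.groupby("condition_id")[_FLAG_COLS].mean().mean(axis=1)
        for cid, v in by_cond.items():
            sums[cid] += v
    rows = [
        {
            "condition_id": c.condition_id,
            "nos": c.nos,
            "actuator_sensitivity": c.actuator_sensitivity,
            "mean_tir": sums[c.condition_id] / n_sessions,
            "target_mean": config.tir_means[(c.nos, c.actuator_sensitivity)],
        }
        for c in schedule
    ]
    return pd.DataFrame(rows)


def simulate_feature_dataset(
    config: SimulationConfig,
    n_sessions: int = 2,
    case: int = 4,
    seed: int = 0,
    stft: STFTConfig = STFTConfig(),
    lowpass_cutoff_hz: float = 40.0,
    trim_s: float = 5.0,
    window_s: float = 2.0,
) -> tuple[np.ndarray, LabelSet, EpochSet]:
    """End-to-end synthetic dataset: features, labels and the epoch table.

    Runs simulate -> low-pass filter -> epoch -> band-power features ->
    condition labels for ``n_sessions`` sessions and concatenates them.
    """
    epoch_sets, schedule = [], config.schedule()
    for s in range(n_sessions):
        session, _ = simulate_session(config, session_id=f"S{s + 1}", seed=seed + s)
        session = lowpass_filter(session, cutoff_hz=lowpass_cutoff_hz)
        epoch_sets.append(segment_epochs(session, window_s=window_s, trim_s=trim_s))
    epochs = EpochSet.concatenate(epoch_sets)
    features = extract_features(
        epochs.data, stft, config.bands, sampling_rate_hz=config.sampling_rate_hz
    )
    labels = assign_condition_labels(schedule, epochs, case=case)
    return features, labels, epochs
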