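"""STFT band-power features and assembly of the CNN input matrix.

Each 2-s epoch of a channel is split into tapered frames; the squared
magnitude of the frame Fourier transform gives a frames x frequency power
spectrogram.  Averaging power over the bins of the six rhythm bands (delta
1-4, theta 5-8, alpha 9-13, lower beta 14-16, higher beta 17-30, gamma
31-40 Hz) yields a 6 x n_frames block per channel; stacking the 17 channel
blocks row-wise gives the 102 x 10 matrix fed to the networks.

The default layout cuts a 1000-sample epoch into ten overlapping 550-sample
Hann frames (hop 50), giving ~0.91 Hz bin spacing at 500 Hz: every band —
including the narrow 1-4 Hz delta band — contains bins, and a pure tone
concentrates >90% of its 1-40 Hz power inside its own band.  Band
membership is by bin-center inclusion in the closed interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import get_window

__all__ = [
    "STFTConfig",
    "BandDefinition",
    "DEFAULT_BANDS",
    "Spectrogram",
    "stft_power",
    "band_power",
    "build_feature_matrix",
    "extract_features",
    "write_features",
    "load_features",
]


@dataclass(frozen=True)
class STFTConfig:
    """Frame layout and taper of the short-time Fourier transform.

    Defaults cover a 1000-sample (2 s at 500 Hz) epoch with ten
    overlapping 550-sample Hann-tapered frames at hop 50, satisfying
    ``(epoch_len - frame_length) / hop + 1 == n_frames``.  ``n_fft`` may
    exceed ``frame_length`` for zero-padded finer bin spacing.
    """

    frame_length: int = 550
    hop: int = 50
    window: str = "hann"
    n_frames: int = 10
    n_fft: int = 550

    def __post_init__(self) -> None:
        if self.frame_length <= 0 or self.hop <= 0:
            raise ValueError("frame_length and hop must be positive")
        if self.n_fft < self.frame_length:
            raise ValueError("n_fft must be >= frame_length")

    def validate_length(self, n_samples: int) -> None:
        if self.frame_length > n_samples:
            raise ValueError("frame longer than the epoch")
        implied = (n_samples - self.frame_length) // self.hop + 1
        if implied != self.n_frames:
            raise ValueError(
                f"epoch of {n_samples} samples yields {implied} frames, "
                f"config expects {self.n_frames}"
            )


@dataclass(frozen=True)
class BandDefinition:
    """Named non-overlapping frequency bands within (0, 40] Hz."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        edges = sorted((lo, hi, name) for name, lo, hi in self.bands)
        for (lo, hi, name) in edges:
            if not (0 < lo <= hi):
                raise ValueError(f"band {name} has invalid edges ({lo}, {hi})")
        for (_, hi_prev, a), (lo_next, _, b) in zip(edges, edges[1:]):
            if lo_next <= hi_prev:
                raise ValueError(f"bands {a} and {b} overlap")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    def __len__(self) -> int:
        return len(self.bands)


DEFAULT_BANDS = BandDefinition(
    (
        ("delta", 1.0, 4.0),
        ("theta", 5.0, 8.0),
        ("alpha", 9.0, 13.0),
        ("lower_beta", 14.0, 16.0),
        ("higher_beta", 17.0, 30.0),
        ("gamma", 31.0, 40.0),
    )
)


@dataclass
class Spectrogram:
    """Nonnegative power values on a frames x frequency-bin grid."""

    power: np.ndarray  # (n_frames, n_bins)
    freqs_hz: np.ndarray  # (n_bins,) bin centers

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.power.ndim != 2 or self.power.shape[1] != len(self.freqs_hz):
            raise ValueError("power must be (n_frames, n_bins)")


def stft_power(
    x: np.ndarray, config: STFTConfig = STFTConfig(), sampling_rate_hz: float = 500.0
) -> Spectrogram:
    """Short-time Fourier power of one epoch channel.

    The signal is cut into ``n_frames`` frames of ``frame_length`` samples
    (stride ``hop``), each multiplied by the taper and Fourier transformed;
    power is the squared magnitude.  Quadratically homogeneous: scaling the
    input by a scales every power value by a**2.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D epoch")
    config.validate_length(len(x))
    idx = np.arange(config.frame_length)[None, :] + config.hop * np.arange(config.n_frames)[:, None]
    frames = x[idx] * get_window(config.window, config.frame_length, fftbins=True)
    spec = np.fft.rfft(frames, n=config.n_fft, axis=1)
    freqs = np.fft.rfftfreq(config.n_fft, d=1.0 / sampling_rate_hz)
    return Spectrogram(power=np.abs(spec) ** 2, freqs_hz=freqs)


def band_power(spec: Spectrogram, bands: BandDefinition = DEFAULT_BANDS) -> np.ndarray:
    """Average power per band and frame, shape (n_bands, n_frames).

    A band whose interval captures no bin centers raises rather than
    silently contributing zeros; widen ``n_fft`` in that case.
    """
    out = np.empty((len(bands), spec.power.shape[0]))
    for b, (name, lo, hi) in enumerate(bands.bands):
        mask = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
        if not mask.any():
            raise ValueError(
                f"band {name} [{lo}, {hi}] Hz captures no frequency bins; "
                "increase n_fft"
            )
        out[b] = spec.power[:, mask].mean(axis=1)
    return out


def build_feature_matrix(
    epoch: np.ndarray,
    config: STFTConfig = STFTConfig(),
    bands: BandDefinition = DEFAULT_BANDS,
    sampling_rate_hz: float = 500.0,
    n_channels: int | None = 17,
) -> np.ndarray:
    """Band-power feature matrix of one multichannel epoch.

    Rows are channel-major, band-minor: row ``c * n_bands + b`` holds the
    band-``b`` power of channel ``c`` over the time frames.  With 17
    channels, six bands and ten frames the result is 102 x 10.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be (channels, samples)")
    if n_channels is not None and epoch.shape[0] != n_channels:
        raise ValueError(f"expected {n_channels} channels, got {epoch.shape[0]}")
    blocks = [
        band_power(stft_power(ch, config, sampling_rate_hz), bands) for ch in epoch
    ]
    return np.concatenate(blocks, axis=0)


def extract_features(
    epoch_data: np.ndarray,
    config: STFTConfig = STFTConfig(),
    bands: BandDefinition = DEFAULT_BANDS,
    sampling_rate_hz: float = 500.0,
) -> np.ndarray:
    """Feature matrices for a batch of epochs, shape (n, channels*bands, frames).

    Vectorized over epochs and channels; equivalent to calling
    :func:`build_feature_matrix` per epoch.
    """
    epoch_data = np.asarray(epoch_data, dtype=float)
    if epoch_data.ndim != 3:
        raise ValueError("epoch_data must be (n_epochs, channels, samples)")
    n, n_ch, n_samp = epoch_data.shape
    config.validate_length(n_samp)
    idx = np.arange(config.frame_length)[None, :] + config.hop * np.arange(config.n_frames)[:, None]
    taper = get_window(config.window, config.frame_length, fftbins=True)
    # (n, ch, frames, frame_length) -> rfft over the last axis
    frames = epoch_data[:, :, idx] * taper
    power = np.abs(np.fft.rfft(frames, n=config.n_fft, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(config.n_fft, d=1.0 / sampling_rate_hz)
    out = np.empty((n, n_ch * len(bands), config.n_frames))
    for b, (name, lo, hi) in enumerate(bands.bands):
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise ValueError(f"band {name} captures no frequency bins")
        out[:, b :: len(bands), :] = power[..., mask].mean(axis=-1)
    return out


def write_features(
    path,
    features: np.ndarray,
    labels: np.ndarray | None = None,
    condition_ids: np.ndarray | None = None,
) -> None:
    """Write an epochs x rows x frames feature tensor (plus labels) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=np.asarray(features))
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels))
        if condition_ids is not None:
            f.create_dataset("condition_id", data=np.asarray(condition_ids))


def load_features(path) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        features = f["features"][()]
        labels = f["labels"][()] if "labels" in f else None
        cond = f["condition_id"][()] if "condition_id" in f else None
    return features, labels, cond
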