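"""Raw epoch conditioning: crop, anti-alias lowpass, normalize, decimate.

The network input representation is produced by, in order,

1. cropping the analysis window (half-open sample interval, t = 0 at
   fixation onset),
2. zero-phase lowpass below 45 Hz (order-8 Butterworth applied
   forward-backward, so the 0.5 s feedback landmark is not shifted; the
   two-pass response is down ~46 dB at 62.5 Hz, the post-decimation Nyquist),
3. per-trial normalization — subtract each channel's mean, then divide by the
   single standard deviation of the centred data pooled over all channels and
   timepoints,
4. decimation to 125 Hz (keep every 8th sample from index 0).

A -0.2..0.5 s epoch recorded at 1000 Hz becomes 204 x 87 (channels x
timepoints) after this chain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import (
    DegenerateTrialError,
    InvalidFilterError,
    InvalidRateError,
    WindowError,
)

__all__ = ["EpochSet", "lowpass", "normalize_trial", "normalize_epochs", "downsample", "crop_window", "preprocess"]


@dataclass
class EpochSet:
    """Trials x channels x timepoints with timing and label metadata."""

    data: np.ndarray
    fs: float
    window: tuple[float, float]  # seconds relative to fixation onset
    labels: np.ndarray
    channel_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValueError("channel_ids length must equal channel count")
        if not np.isfinite(self.data).all():
            raise ValueError("epochs contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_times) / self.fs


def lowpass(epochs: EpochSet, cutoff: float = 45.0, order: int = 8) -> EpochSet:
    """Zero-phase Butterworth lowpass along the time axis (DC gain 1)."""
    if cutoff >= epochs.fs / 2:
        raise InvalidFilterError(f"cutoff {cutoff} Hz requires fs > {2 * cutoff} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=filtered)


def normalize_trial(epoch: np.ndarray) -> np.ndarray:
    """Centre each channel, then scale by the pooled standard deviation.

    The scale is one scalar per trial: the SD of the channel-centred values
    collapsed over all channels and timepoints.  Idempotent.
    """
    epoch = np.asarray(epoch)
    if not np.issubdtype(epoch.dtype, np.floating):
        epoch = epoch.astype(float)
    centered = epoch - epoch.mean(axis=-1, keepdims=True)
    sd = centered.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateTrialError("constant trial cannot be normalized")
    return centered / sd


def normalize_epochs(epochs: EpochSet) -> EpochSet:
    data = epochs.data
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(float)
    centered = data - data.mean(axis=-1, keepdims=True)
    sd = centered.std(axis=(1, 2), keepdims=True)
    if np.any(sd == 0) or not np.isfinite(sd).all():
        bad = np.flatnonzero((sd == 0).ravel() | ~np.isfinite(sd).ravel())
        raise DegenerateTrialError(f"constant trial(s) at index {bad.tolist()}")
    return replace(epochs, data=centered / sd)


def downsample(epochs: EpochSet, fs_out: float = 125.0) -> EpochSet:
    """Decimate by keeping every (fs/fs_out)-th sample starting at index 0.

    Output length is floor(n_in * fs_out / fs_in); assumes the anti-alias
    lowpass has already been applied.
    """
    factor = epochs.fs / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise InvalidRateError(f"fs {epochs.fs} is not an integer multiple of fs_out {fs_out}")
    factor = int(round(factor))
    n_out = int(np.floor(epochs.n_times * fs_out / epochs.fs))
    data = epochs.data[..., ::factor][..., :n_out]
    return replace(epochs, data=data, fs=fs_out)


def crop_window(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Half-open sample interval [start, end) relative to fixation onset."""
    start, end = window
    s0, _ = epochs.window
    i0 = int(round((start - s0) * epochs.fs))
    i1 = int(round((end - s0) * epochs.fs))
    if i0 < 0 or i1 > epochs.n_times or i0 >= i1:
        raise WindowError(f"window {window} outside stored {epochs.window}")
    return replace(epochs, data=epochs.data[..., i0:i1], window=(start, end))


def preprocess(
    epochs: EpochSet,
    window: tuple[float, float] = (-0.2, 0.5),
    cutoff: float = 45.0,
    fs_out: float = 125.0,
) -> EpochSet:
    """Full chain crop -> lowpass -> normalize -> downsample."""
    out = crop_window(epochs, window)
    out = lowpass(out, cutoff)
    out = normalize_epochs(out)
    return downsample(out, fs_out)
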