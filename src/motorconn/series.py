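"""Multichannel time-series container and epoching.

The pipeline's raw input is a set of M regional source series sampled at a
common rate (in the motor-network application: cM1, iM1, cpMC, ipMC, SMA at
128 Hz). Epoching splits a recording into contiguous, non-overlapping windows
that are modelled independently downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical node labels of the 5-ROI motor network: contra-/ipsi-lesional
#: primary motor cortex, contra-/ipsi-lesional premotor cortex, and the
#: supplementary motor area.
MOTOR_ROIS = ("cM1", "iM1", "cpMC", "ipMC", "SMA")


@dataclass
class MultichannelSeries:
    """An M-channel, N-sample real-valued time series.

    Parameters
    ----------
    values : ndarray, shape (M, N)
        One row per channel.
    fs : float
        Sampling rate in Hz.
    labels : tuple of str
        Unique channel names, one per row.
    """

    values: np.ndarray
    fs: float
    labels: tuple = field(default=MOTOR_ROIS)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (channels x samples) array")
        self.labels = tuple(self.labels)
        m, n = self.values.shape
        if n < 1:
            raise ValueError("series must contain at least one sample")
        if len(self.labels) != m:
            raise ValueError(
                f"{m} channels but {len(self.labels)} labels supplied"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Contiguous, non-overlapping, equal-length windows of one recording."""

    epochs: list

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("EpochSet must contain at least one epoch")
        first = self.epochs[0]
        for ep in self.epochs:
            if ep.labels != first.labels or ep.fs != first.fs:
                raise ValueError("epochs disagree on channels or sampling rate")
            if ep.n_samples != first.n_samples:
                raise ValueError("epochs have unequal length")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i):
        return self.epochs[i]

    @property
    def epoch_samples(self) -> int:
        return self.epochs[0].n_samples


def epoch_series(
    series: MultichannelSeries,
    epoch_seconds: float,
    center: bool = True,
) -> EpochSet:
    """Split a recording into consecutive windows of ``epoch_seconds``.

    A 60 s recording at 128 Hz with 10 s windows yields six epochs of 1,280
    samples. Trailing samples that do not fill a window are discarded. Each
    channel of each epoch is mean-centered (``center=False`` disables this,
    e.g. to verify lossless segmentation).
    """
    n_ep_samples = epoch_seconds * series.fs
    if abs(n_ep_samples - round(n_ep_samples)) > 1e-9:
        raise ValueError("epoch_seconds * fs must be an integer sample count")
    n_ep_samples = int(round(n_ep_samples))
    if n_ep_samples < 10 * series.n_channels:
        raise ValueError(
            f"epoch of {n_ep_samples} samples is too short for "
            f"{series.n_channels} channels (need >= {10 * series.n_channels})"
        )
    n_epochs = series.n_samples // n_ep_samples
    if n_epochs < 1:
        raise ValueError(
            f"series of {series.n_samples} samples is shorter than one "
            f"epoch of {n_ep_samples} samples"
        )
    epochs = []
    for k in range(n_epochs):
        chunk = series.values[:, k * n_ep_samples:(k + 1) * n_ep_samples]
        chunk = chunk.copy()
        if center:
            chunk -= chunk.mean(axis=1, keepdims=True)
        epochs.append(MultichannelSeries(chunk, series.fs, series.labels))
    return EpochSet(epochs)
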