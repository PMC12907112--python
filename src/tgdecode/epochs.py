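"""Epoched-EEG data model, HDF5 container I/O, and preprocessing operators.

An :class:`EpochsSet` holds one subject's condition-labelled epochs as a
``trials x channels x time`` tensor in microvolts, with a millisecond time
axis sampled uniformly at ``1000 / sfreq``.  The preprocessing operators
implemented here are the post-hoc ones a decoding pipeline needs on already
filtered, artifact-cleaned data: baseline correction, +/-threshold amplitude
rejection, common average referencing, 2:1 downsampling by pair averaging,
and restriction to a named electrode network.  All operators are pure — they
return new objects and never mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .montage import NetworkMap

FORMAT_VERSION = "1"


@dataclass
class EpochsSet:
    """Condition-labelled epoched EEG for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Signal in microvolts.
    times : ndarray, shape (n_times,)
        Sample times in milliseconds relative to stimulus onset; strictly
        increasing with uniform spacing ``1000 / sfreq``.
    sfreq : float
        Sampling rate in Hz.
    channels : tuple of str
        Electrode names, ordered as the channel axis of ``data``.
    labels : ndarray of str, shape (n_trials,)
        Per-trial condition label.
    subject : str
        Subject identifier.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channels: tuple[str, ...]
    labels: np.ndarray
    subject: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.channels = tuple(self.channels)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_trials, n_ch, n_t = self.data.shape
        if len(self.channels) != n_ch:
            raise ValueError(
                f"{len(self.channels)} channel names for {n_ch} data channels")
        if self.times.shape != (n_t,):
            raise ValueError("times length does not match data time axis")
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length does not match trial axis")
        if n_t > 1:
            dt = np.diff(self.times)
            step = 1000.0 / self.sfreq
            if np.any(dt <= 0) or not np.allclose(dt, step, rtol=0, atol=1e-6):
                raise ValueError(
                    f"times must increase uniformly at {step} ms spacing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab))
        return tuple(seen)

    def select(self, condition: str) -> np.ndarray:
        """Trial tensor of a single condition."""
        mask = np.asarray([str(l) == condition for l in self.labels])
        if not mask.any():
            raise KeyError(f"no trials with condition {condition!r}")
        return self.data[mask]

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for a closed [lo, hi] millisecond window."""
        lo, hi = window
        if hi < lo:
            raise ValueError(f"empty window {window}")
        return (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochsSet, path) -> None:
    """Write an :class:`EpochsSet` to the HDF5 container layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset(
            "labels", data=[str(l) for l in epochs.labels], dtype=str_dt)
        f.create_dataset("channels", data=list(epochs.channels), dtype=str_dt)
        f.attrs["sfreq"] = float(epochs.sfreq)
        f.attrs["subject"] = epochs.subject
        f.attrs["format_version"] = FORMAT_VERSION


def read_epochs(path) -> EpochsSet:
    """Read an :class:`EpochsSet` from the HDF5 container layout."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise IOError(
                f"unknown epochs container version {version!r} in {path}")
        for member in ("data", "times", "labels", "channels"):
            if member not in f:
                raise IOError(f"epochs container missing member /{member}")
        return EpochsSet(
            data=f["data"][()],
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            channels=tuple(c.decode() if isinstance(c, bytes) else str(c)
                           for c in f["channels"][()]),
            labels=np.array([l.decode() if isinstance(l, bytes) else str(l)
                             for l in f["labels"][()]], dtype=object),
            subject=str(f.attrs.get("subject", "")),
        )


# ---------------------------------------------------------------------------
# preprocessing operators
# ---------------------------------------------------------------------------

def baseline_correct(
    epochs: EpochsSet, window: tuple[float, float] = (-200.0, 0.0)
) -> EpochsSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - baseline)


@dataclass
class RejectionReport:
    """Outcome of amplitude-based trial rejection."""

    threshold_uv: float
    discarded: dict[str, list[int]] = field(default_factory=dict)
    n_kept: int = 0
    n_total: int = 0

    @property
    def n_discarded(self) -> int:
        return sum(len(v) for v in self.discarded.values())


def reject_amplitude(
    epochs: EpochsSet, threshold_uv: float = 100.0
) -> tuple[EpochsSet, RejectionReport]:
    """Discard trials whose absolute amplitude exceeds the threshold anywhere.

    Returns the retained epochs and a report listing discarded original trial
    indices per condition.  Raises if every trial would be rejected.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    if not keep.any():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed +/-{threshold_uv} uV")
    report = RejectionReport(threshold_uv=threshold_uv,
                             n_kept=int(keep.sum()),
                             n_total=epochs.n_trials)
    for idx in np.flatnonzero(~keep):
        report.discarded.setdefault(str(epochs.labels[idx]), []).append(int(idx))
    out = replace(epochs, data=epochs.data[keep], labels=epochs.labels[keep])
    return out, report


def common_average_reference(epochs: EpochsSet) -> EpochsSet:
    """Re-reference every sample to the instantaneous mean over channels."""
    if len(epochs.channels) < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return replace(
        epochs, data=epochs.data - epochs.data.mean(axis=1, keepdims=True))


def downsample_pairs(epochs: EpochsSet) -> EpochsSet:
    """Halve the sampling rate by averaging every two consecutive samples.

    Output sample ``i`` is the mean of input samples ``2i`` and ``2i+1`` and
    carries the mean of their time stamps; a trailing odd sample is dropped.
    """
    n_t = epochs.data.shape[2]
    if n_t < 2:
        raise ValueError("need at least 2 time samples to downsample")
    n_pairs = n_t // 2
    data = epochs.data[:, :, : 2 * n_pairs]
    data = data.reshape(*data.shape[:2], n_pairs, 2).mean(axis=3)
    times = epochs.times[: 2 * n_pairs].reshape(n_pairs, 2).mean(axis=1)
    return replace(epochs, data=data, times=times, sfreq=epochs.sfreq / 2.0)


def subset_network(
    epochs: EpochsSet, network_map: NetworkMap, network: str
) -> EpochsSet:
    """Restrict channels to one of the six networks, preserving order."""
    wanted = set(network_map.channels(network))
    idx = [i for i, ch in enumerate(epochs.channels) if ch in wanted]
    missing = wanted - set(epochs.channels)
    if missing:
        raise ValueError(
            f"network {network!r} channels missing from epochs: "
            f"{sorted(missing)}")
    return replace(
        epochs,
        data=epochs.data[:, idx, :],
        channels=tuple(epochs.channels[i] for i in idx),
    )
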