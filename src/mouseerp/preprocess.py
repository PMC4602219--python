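"""Stimulus-locked epoching, artifact rejection, block averaging, grand averages.

Epochs use a half-open sample convention [start, end): at 1 kHz a
(−500, 500) ms window yields exactly 1000 samples with t = 0 included.
Rejection follows the strict rule |value| > threshold (an epoch whose extreme
is exactly at threshold is retained). Block averages group retained epochs
into consecutive, non-overlapping blocks of k in trial order; a trailing
remainder shorter than k is discarded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from mouseerp.io import Recording

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """A stack of stimulus-locked epochs for one animal.

    data: (n_epochs, n_channels, n_times) in µV; times_ms relative to
    stimulus onset; mask marks retained epochs (rejection only ever clears
    mask bits, never sets them).
    """

    data: np.ndarray
    times_ms: np.ndarray
    channels: tuple[str, ...]
    trial_indices: np.ndarray
    mask: np.ndarray
    sampling_rate_hz: float
    animal_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        if len(self.mask) != self.n_epochs:
            raise ValueError("mask length must equal the number of epochs")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("time axis length must match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def retained(self) -> np.ndarray:
        """(n_retained, n_channels, n_times) view of the unmasked epochs."""
        return self.data[self.mask]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch set {self.channels}") from None

    # -- serialization: binary array container + JSON header -----------------
    def save(self, base: str | Path) -> None:
        base = Path(base)
        np.savez_compressed(
            base.with_suffix(".epochs.npz"),
            data=self.data.astype(np.float32),
            times_ms=self.times_ms,
            trial_indices=self.trial_indices,
            mask=self.mask,
        )
        header = {
            "channels": list(self.channels),
            "sampling_rate_hz": self.sampling_rate_hz,
            "animal_id": self.animal_id,
            "genotype": self.genotype,
        }
        base.with_suffix(".epochs.json").write_text(json.dumps(header, indent=1) + "\n")

    @classmethod
    def load(cls, base: str | Path) -> "EpochSet":
        base = Path(base)
        arrays = np.load(base.with_suffix(".epochs.npz"))
        header = json.loads(base.with_suffix(".epochs.json").read_text())
        return cls(
            data=arrays["data"].astype(float),
            times_ms=arrays["times_ms"],
            channels=tuple(header["channels"]),
            trial_indices=arrays["trial_indices"],
            mask=arrays["mask"],
            sampling_rate_hz=header["sampling_rate_hz"],
            animal_id=header["animal_id"],
            genotype=header["genotype"],
        )


def extract_epochs(
    recording: Recording,
    window_ms: tuple[float, float] = (-500.0, 500.0),
    baseline: bool = False,
) -> EpochSet:
    """Cut one epoch per stimulus event.

    Events whose full window does not fit inside the recording are dropped
    (and counted in the log). With ``baseline=True`` the mean of the
    pre-stimulus part of the window is subtracted per epoch and channel
    (off by default).
    """
    w0, w1 = window_ms
    if w0 >= w1:
        raise ValueError("window start must precede window end")
    fs = recording.sampling_rate_hz
    s0 = int(round(w0 * fs / 1000.0))
    s1 = int(round(w1 * fs / 1000.0))
    n_t = s1 - s0
    times_ms = (np.arange(s0, s1) / fs) * 1000.0

    keep, dropped = [], 0
    for i, onset in enumerate(recording.events):
        if onset + s0 < 0 or onset + s1 > recording.n_samples:
            dropped += 1
        else:
            keep.append(i)
    if dropped:
        logger.info("dropped %d event(s) with truncated windows", dropped)
    if not keep:
        logger.warning("no events with complete windows; empty epoch set")
    data = np.empty((len(keep), len(recording.channels), n_t))
    for j, i in enumerate(keep):
        onset = recording.events[i]
        data[j] = recording.data[:, onset + s0 : onset + s1]
    if baseline and len(keep):
        pre = times_ms < 0
        if pre.any():
            data -= data[:, :, pre].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        times_ms=times_ms,
        channels=tuple(recording.channels),
        trial_indices=np.asarray(keep, dtype=np.int64),
        mask=np.ones(len(keep), dtype=bool),
        sampling_rate_hz=fs,
        animal_id=recording.animal_id,
        genotype=recording.genotype,
    )


def reject_artifacts(epochs: EpochSet, threshold_uV: float = 1000.0) -> EpochSet:
    """Mask out epochs containing any sample with |value| strictly greater
    than threshold on any channel. Never unmasks."""
    if threshold_uV <= 0:
        raise ValueError("threshold_uV must be positive")
    extreme = np.abs(epochs.data).max(axis=(1, 2)) > threshold_uV
    new_mask = epochs.mask & ~extreme
    return replace(epochs, mask=new_mask)


def block_average(epochs: EpochSet, k: int) -> EpochSet:
    """Average retained epochs in consecutive non-overlapping blocks of k
    (trial order); the remainder shorter than k is discarded. k = 1 returns
    the retained epochs unchanged."""
    if k < 1:
        raise ValueError("block size k must be >= 1")
    retained = epochs.retained()
    idx = epochs.trial_indices[epochs.mask]
    n_blocks = len(retained) // k
    if n_blocks == 0:
        logger.warning(
            "block size k=%d exceeds the %d retained epochs; empty output", k, len(retained)
        )
    blocks = retained[: n_blocks * k].reshape(n_blocks, k, *retained.shape[1:]).mean(axis=1)
    return replace(
        epochs,
        data=blocks,
        trial_indices=idx[: n_blocks * k : k].copy(),
        mask=np.ones(n_blocks, dtype=bool),
    )


def grand_average(epochs: EpochSet) -> np.ndarray:
    """(n_channels, n_times) sample-wise mean over retained epochs."""
    if epochs.n_retained == 0:
        raise ValueError("cannot average an epoch set with zero retained epochs")
    return epochs.retained().mean(axis=0)
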