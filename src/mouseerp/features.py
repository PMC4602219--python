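"""ERP feature families: N1/P1/N2 peak components and waveform principal components.

Both families are built from the (0, 250) ms post-stimulus analysis window.

Peak detection: the waveform is smoothed with a 5 ms moving average, local
extrema are taken in time order, and the first three extrema of alternating
type (minimum / maximum) fill the N1, P1, N2 slots — N slots are local
minima, P slots local maxima. If the first extremum is a maximum it fills
the P1 slot and N1 stays invalid. Amplitude is the signed raw (unsmoothed)
value at the extremum sample; latency is its time in ms after stimulus
onset. A component whose raw amplitude contradicts its slot's sign (an "N"
above zero or a "P" below) is flagged invalid.

Waveform features are the per-channel (0, 250) ms traces concatenated in a
fixed declared channel order; principal components of these concatenations
serve as compressed spatio-temporal features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from mouseerp.preprocess import EpochSet

#: channels used for the multi-channel feature families
MULTI_CHANNELS = ("FL", "FR", "PR", "OL", "OR")
#: channel used for the single-channel peak family
SINGLE_CHANNEL = "FR"

ANALYSIS_WINDOW_MS = (0.0, 250.0)


@dataclass(frozen=True)
class PeakComponent:
    label: str
    latency_ms: float
    amplitude_uV: float
    valid: bool

    @classmethod
    def invalid(cls, label: str) -> "PeakComponent":
        return cls(label, np.nan, np.nan, False)


def detect_peak_components(
    waveform: np.ndarray,
    fs: float,
    smooth_ms: float = 5.0,
    t0_ms: float = 0.0,
) -> tuple[PeakComponent, PeakComponent, PeakComponent]:
    """Detect the N1, P1, N2 components of a single-channel waveform.

    ``waveform`` must cover the analysis window (time of its first sample
    given by ``t0_ms``). Returns one :class:`PeakComponent` per slot;
    components that cannot be found are flagged invalid.
    """
    waveform = np.asarray(waveform, dtype=float)
    width = max(1, int(round(smooth_ms * fs / 1000.0)))
    if len(waveform) < width:
        raise ValueError(
            f"waveform of {len(waveform)} samples is shorter than the "
            f"{width}-sample smoothing kernel"
        )
    kernel = np.ones(width) / width
    smoothed = np.convolve(waveform, kernel, mode="same")

    # only prominent deflections count as peaks: the floor is relative to the
    # waveform's own range, so detection is equivariant to amplitude scaling
    # and residual noise wiggles do not claim component slots
    prominence = 0.1 * (smoothed.max() - smoothed.min())
    if prominence <= 0:
        return tuple(PeakComponent.invalid(lab) for lab in ("N1", "P1", "N2"))
    maxima, _ = find_peaks(smoothed, prominence=prominence)
    minima, _ = find_peaks(-smoothed, prominence=prominence)
    extrema = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])

    taken: list[tuple[int, int]] = []
    for idx, pol in extrema:
        if not taken or pol == -taken[-1][1]:
            taken.append((idx, pol))
        if len(taken) == 3:
            break

    slots = {"N1": None, "P1": None, "N2": None}
    if taken:
        order = ("N1", "P1", "N2") if taken[0][1] < 0 else ("P1", "N2")
        for slot, ext in zip(order, taken):
            slots[slot] = ext

    out = []
    for label in ("N1", "P1", "N2"):
        ext = slots[label]
        if ext is None:
            out.append(PeakComponent.invalid(label))
            continue
        idx, pol = ext
        amp = float(waveform[idx])
        sign_ok = amp <= 0 if label.startswith("N") else amp >= 0
        if not sign_ok:
            out.append(PeakComponent.invalid(label))
            continue
        out.append(PeakComponent(label, t0_ms + idx / fs * 1000.0, amp, True))
    return tuple(out)


@dataclass
class FeatureMatrix:
    """Per-sample feature vectors with animal and genotype labels.

    ``descriptor`` records the feature kind (peaks_single / peaks_multi /
    waveform / pc), channel order and window, so column meaning is fully
    determined.
    """

    X: np.ndarray
    animal_ids: np.ndarray
    genotypes: np.ndarray
    descriptor: dict
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.animal_ids = np.asarray(self.animal_ids)
        self.genotypes = np.asarray(self.genotypes)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples × features)")
        if len(self.animal_ids) != len(self.X) or len(self.genotypes) != len(self.X):
            raise ValueError("per-row labels must match the number of rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X[mask], self.animal_ids[mask], self.genotypes[mask],
            dict(self.descriptor), list(self.column_names),
        )

    @classmethod
    def concat(cls, parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        return cls(
            np.vstack([p.X for p in parts]),
            np.concatenate([p.animal_ids for p in parts]),
            np.concatenate([p.genotypes for p in parts]),
            dict(parts[0].descriptor),
            list(parts[0].column_names),
        )

    def to_tsv(self, base: str | Path) -> None:
        base = Path(base)
        cols = self.column_names or [f"f{i}" for i in range(self.n_features)]
        table = pd.DataFrame(self.X, columns=cols)
        table.insert(0, "animal_id", self.animal_ids)
        table.insert(1, "genotype", self.genotypes)
        table.to_csv(base.with_suffix(".features.tsv"), sep="\t", index=False)
        base.with_suffix(".features.json").write_text(
            json.dumps(self.descriptor, indent=1) + "\n"
        )


def _resolve_channels(epochs: EpochSet, channels) -> list[str]:
    channels = list(channels)
    if not channels:
        raise ValueError("channel list must not be empty")
    for ch in channels:
        epochs.channel_index(ch)
    return channels


def build_peak_feature_matrix(
    epochs: EpochSet,
    channels=MULTI_CHANNELS,
    window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
    impute: bool = True,
) -> FeatureMatrix:
    """(latency, amplitude) of N1, P1, N2 per channel → 6 features/channel.

    Invalid components appear as NaN; with ``impute=True`` each NaN cell is
    replaced by its column's mean over valid entries (use ``impute=False``
    plus a :class:`PeakImputer` fitted on a training partition to keep
    train/test separation).
    """
    channels = _resolve_channels(epochs, channels)
    w0, w1 = window_ms
    sel = (epochs.times_ms >= w0) & (epochs.times_ms < w1)
    t0 = float(epochs.times_ms[sel][0])
    retained = epochs.retained()

    rows = np.full((len(retained), 6 * len(channels)), np.nan)
    for r, epoch in enumerate(retained):
        col = 0
        for ch in channels:
            trace = epoch[epochs.channel_index(ch), sel]
            for comp in detect_peak_components(trace, epochs.sampling_rate_hz, t0_ms=t0):
                if comp.valid:
                    rows[r, col] = comp.latency_ms
                    rows[r, col + 1] = comp.amplitude_uV
                col += 2
    if impute:
        rows = PeakImputer().fit_transform(rows)
    names = [f"{ch}:{lab}:{q}" for ch in channels for lab in ("N1", "P1", "N2") for q in ("lat", "amp")]
    kind = "peaks_single" if len(channels) == 1 else "peaks_multi"
    return FeatureMatrix(
        rows,
        np.repeat(epochs.animal_id, len(rows)),
        np.repeat(epochs.genotype, len(rows)),
        {"kind": kind, "channels": channels, "window_ms": list(window_ms)},
        names,
    )


class PeakImputer(BaseEstimator, TransformerMixin):
    """Column-mean imputation of invalid (NaN) peak features.

    The means are computed over valid entries of the partition passed to
    ``fit`` — fitted state, so cross-validation can fit on training animals
    only. A column with no valid entry imputes to 0.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(X, axis=0)
        self.statistics_ = np.where(np.isfinite(means), means, 0.0)
        return self

    def transform(self, X):
        X = np.array(X, dtype=float, copy=True)
        if X.shape[1] != len(self.statistics_):
            raise ValueError("feature dimension mismatch")
        nan = np.isnan(X)
        X[nan] = np.take(self.statistics_, np.nonzero(nan)[1])
        return X


def build_waveform_feature_matrix(
    epochs: EpochSet,
    channels=MULTI_CHANNELS,
    window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
) -> FeatureMatrix:
    """Concatenate per-channel waveforms cropped to [0, 250) ms in the
    declared channel order (5 channels at 1 kHz → 1250 columns)."""
    channels = _resolve_channels(epochs, channels)
    w0, w1 = window_ms
    if w0 < epochs.times_ms[0] or w1 > epochs.times_ms[-1] + 1000.0 / epochs.sampling_rate_hz:
        raise ValueError("analysis window exceeds the epoch extent")
    sel = (epochs.times_ms >= w0) & (epochs.times_ms < w1)
    retained = epochs.retained()
    ch_idx = [epochs.channel_index(ch) for ch in channels]
    X = retained[:, ch_idx][:, :, sel].reshape(len(retained), -1)
    return FeatureMatrix(
        X,
        np.repeat(epochs.animal_id, len(X)),
        np.repeat(epochs.genotype, len(X)),
        {"kind": "waveform", "channels": channels, "window_ms": list(window_ms)},
    )


class WaveformPCA(BaseEstimator, TransformerMixin):
    """Mean-centered PCA of waveform features with a fixed sign convention.

    Loadings (``components_``) are orthonormal rows ordered by explained
    variance (non-increasing); each loading is oriented so its
    largest-magnitude coefficient is positive. ``n_components`` bounds the
    number of components kept (None keeps all); ``random_state`` only
    matters when the randomized SVD solver is triggered on large inputs.
    """

    def __init__(self, n_components: int | None = None, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("PCA requires at least 2 samples")
        if np.allclose(X, X[0], atol=1e-12):
            raise ValueError("constant feature matrix has no variance to decompose")
        n_comp = self.n_components
        if n_comp is not None:
            n_comp = min(n_comp, X.shape[0], X.shape[1])
        pca = PCA(n_components=n_comp, random_state=self.random_state)
        pca.fit(X)
        components = pca.components_.copy()
        flip = components[np.arange(len(components)), np.abs(components).argmax(axis=1)] < 0
        components[flip] *= -1
        self.mean_ = pca.mean_
        self.components_ = components
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_components_ = components.shape[0]
        return self

    def transform(self, X, n_pcs: int | None = None):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.mean_):
            raise ValueError("feature dimension mismatch")
        n_pcs = self.n_components_ if n_pcs is None else n_pcs
        if not (1 <= n_pcs <= self.n_components_):
            raise ValueError(
                f"n_pcs must lie in [1, {self.n_components_}], got {n_pcs}"
            )
        return (X - self.mean_) @ self.components_[:n_pcs].T

    def inverse_transform(self, scores):
        scores = np.asarray(scores, dtype=float)
        return scores @ self.components_[: scores.shape[1]] + self.mean_


def fit_pca(features: FeatureMatrix, n_components: int | None = None) -> WaveformPCA:
    """Fit a :class:`WaveformPCA` on a feature matrix."""
    return WaveformPCA(n_components=n_components).fit(features.X)


def project_pca(model: WaveformPCA, features: FeatureMatrix, n_pcs: int) -> FeatureMatrix:
    """Scores of the rows on the first ``n_pcs`` principal components."""
    scores = model.transform(features.X, n_pcs=n_pcs)
    desc = dict(features.descriptor)
    desc.update(kind="pc", n_pcs=int(n_pcs))
    return FeatureMatrix(
        scores, features.animal_ids, features.genotypes, desc,
        [f"PC{i + 1}" for i in range(n_pcs)],
    )
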