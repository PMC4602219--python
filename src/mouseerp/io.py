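"""Recording input/output: EDF signals, TSV event tables, JSON montages, TSV cohort manifests.

Continuous signals travel as EDF (16-bit, the precision of the acquisition
chain). The physical range declared in the EDF header is fixed at
[-3276.8, +3276.7] µV so that one digital step is exactly 0.1 µV; a signal
exceeding the declared range raises instead of clipping silently. Event
onsets are authoritative in samples; the seconds column of the event table
is derived. All signals are µV end-to-end.

Reading EDF goes through :func:`mne.io.read_raw_edf`; writing is done by a
small built-in EDF writer (header + 16-bit little-endian data records of
1 s, the final partial record zero-padded; the true sample count lives in a
JSON metadata sidecar which is authoritative on load).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "HYPO")

#: physical range (µV) declared in the EDF header; one 16-bit step = 0.1 µV
EDF_PHYS_MIN = -3276.8
EDF_PHYS_MAX = 3276.7
EDF_STEP_UV = 0.1


@dataclass(frozen=True)
class MontageEntry:
    """One electrode: label, stereotaxic mm from bregma (AP anterior-positive,
    ML right-positive), and kind (eeg / reference / emg)."""

    label: str
    ap_mm: float
    ml_mm: float
    kind: str = "eeg"

    def __post_init__(self) -> None:
        if self.kind not in ("eeg", "reference", "emg"):
            raise ValueError(f"unknown electrode kind {self.kind!r}")


@dataclass(frozen=True)
class Montage:
    """An electrode montage with unique labels."""

    entries: tuple[MontageEntry, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")

    def __getitem__(self, label: str) -> MontageEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(e.label == label for e in self.entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)

    def eeg_labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries if e.kind == "eeg")

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"label": e.label, "ap_mm": e.ap_mm, "ml_mm": e.ml_mm, "kind": e.kind}
            for e in self.entries
        ]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        return cls(tuple(MontageEntry(**e) for e in payload))


def default_montage() -> Montage:
    """The six-electrode epidural montage plus cerebellar reference.

    Frontal ±1.0 mm ML at +1.0 mm AP, parietal ±1.5 mm ML at −1.0 mm AP,
    occipital ±2.0 mm ML at −3.5 mm AP, reference on the midline at −6.0 mm.
    """
    return Montage((
        MontageEntry("FL", 1.0, -1.0), MontageEntry("FR", 1.0, 1.0),
        MontageEntry("PL", -1.0, -1.5), MontageEntry("PR", -1.0, 1.5),
        MontageEntry("OL", -3.5, -2.0), MontageEntry("OR", -3.5, 2.0),
        MontageEntry("REF", -6.0, 0.0, kind="reference"),
    ))


@dataclass
class Recording:
    """A continuous multi-channel recording in µV with stimulus events.

    data is (n_channels, n_samples); events are onset sample indices,
    strictly increasing and within the signal bounds.
    """

    sampling_rate_hz: float
    data: np.ndarray
    channels: tuple[str, ...]
    events: np.ndarray
    animal_id: str = ""
    genotype: str = ""
    sex: str = ""
    session: str = ""
    montage: Montage = field(default_factory=default_montage)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.events = np.asarray(self.events, dtype=np.int64)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples) matching channel labels")
        if self.genotype and self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        for ch in self.channels:
            if ch not in self.montage:
                raise ValueError(f"channel {ch!r} not present in the montage")
        if len(self.events):
            if np.any(np.diff(self.events) <= 0):
                raise ValueError("event onsets must be strictly increasing")
            if self.events[0] < 0 or self.events[-1] >= self.n_samples:
                raise ValueError("event onsets must lie within the signal bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


# ----------------------------------------------------------------------------
# EDF writing (header per the EDF specification; data records of 1 s)
# ----------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _write_edf(path: Path, data_uv: np.ndarray, channels: tuple[str, ...], fs: float) -> None:
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samples = data_uv.shape
    if data_uv.size and (data_uv.max() > EDF_PHYS_MAX or data_uv.min() < EDF_PHYS_MIN):
        raise ValueError(
            f"signal exceeds the declared EDF physical range "
            f"[{EDF_PHYS_MIN}, {EDF_PHYS_MAX}] µV; refusing to clip"
        )
    n_records = int(np.ceil(n_samples / fs)) if n_samples else 0

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate 01-JAN-2020 X X X", 80),
        _edf_field("01.01.20", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (n_ch + 1), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    per = [
        [_edf_field(ch, 16) for ch in channels],
        [_edf_field("", 80)] * n_ch,
        [_edf_field("uV", 8)] * n_ch,
        [_edf_field(EDF_PHYS_MIN, 8)] * n_ch,
        [_edf_field(EDF_PHYS_MAX, 8)] * n_ch,
        [_edf_field(-32768, 8)] * n_ch,
        [_edf_field(32767, 8)] * n_ch,
        [_edf_field("HP:0.1Hz", 80)] * n_ch,
        [_edf_field(fs, 8)] * n_ch,
        [_edf_field("", 32)] * n_ch,
    ]
    header += b"".join(b"".join(block) for block in per)

    # digital value d encodes d * 0.1 µV exactly
    digital = np.round(data_uv / EDF_STEP_UV).astype(np.int16)
    padded = np.zeros((n_ch, n_records * fs), dtype=np.int16)
    padded[:, :n_samples] = digital
    # records: (record, channel, sample-in-record)
    records = padded.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(records.astype("<i2").tobytes())


def _read_edf(path: Path) -> tuple[np.ndarray, tuple[str, ...], float]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    return data_uv, tuple(raw.ch_names), float(raw.info["sfreq"])


# ----------------------------------------------------------------------------
# Recording save / load
# ----------------------------------------------------------------------------

def _paths(base: str | Path) -> dict[str, Path]:
    base = Path(base)
    return {
        "edf": base.with_suffix(".edf"),
        "events": base.with_suffix(".events.tsv"),
        "montage": base.with_suffix(".montage.json"),
        "meta": base.with_suffix(".meta.json"),
    }


def save_recording(recording: Recording, base: str | Path) -> dict[str, Path]:
    """Write a recording as EDF + events TSV + montage JSON + metadata JSON.

    ``base`` is a path prefix; files ``base.edf``, ``base.events.tsv``,
    ``base.montage.json`` and ``base.meta.json`` are produced. Returns the
    path mapping.
    """
    paths = _paths(base)
    paths["edf"].parent.mkdir(parents=True, exist_ok=True)
    _write_edf(paths["edf"], recording.data, recording.channels, recording.sampling_rate_hz)
    events = pd.DataFrame({
        "onset_sample": recording.events.astype(np.int64),
        "onset_s": recording.events / recording.sampling_rate_hz,
        "label": "click",
    })
    events.to_csv(paths["events"], sep="\t", index=False)
    recording.montage.to_json(paths["montage"])
    meta = {
        "animal_id": recording.animal_id,
        "genotype": recording.genotype,
        "sex": recording.sex,
        "session": recording.session,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "n_samples": recording.n_samples,
        "channels": list(recording.channels),
    }
    paths["meta"].write_text(json.dumps(meta, indent=1) + "\n")
    return paths


def load_recording(base: str | Path) -> Recording:
    """Load a recording written by :func:`save_recording`; validates all
    invariants (consistent channels, monotone in-bounds events)."""
    paths = _paths(base)
    for key in ("edf", "events", "montage", "meta"):
        if not paths[key].exists():
            raise FileNotFoundError(f"missing {key} file: {paths[key]}")
    meta = json.loads(paths["meta"].read_text())
    montage = Montage.from_json(paths["montage"])
    data_uv, channels, fs = _read_edf(paths["edf"])
    for ch in channels:
        if ch not in montage:
            raise ValueError(f"EDF channel {ch!r} is not defined in the montage")
    if abs(fs - meta["sampling_rate_hz"]) > 1e-6:
        raise ValueError("sampling rate mismatch between EDF and metadata")
    n = int(meta["n_samples"])
    data_uv = data_uv[:, :n]  # drop the final record's zero padding
    events = pd.read_csv(paths["events"], sep="\t")
    onsets = events["onset_sample"].to_numpy(dtype=np.int64)
    if len(onsets) and np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets in the events table are not strictly increasing")
    return Recording(
        sampling_rate_hz=fs,
        data=data_uv,
        channels=channels,
        events=onsets,
        animal_id=meta.get("animal_id", ""),
        genotype=meta.get("genotype", ""),
        sex=meta.get("sex", ""),
        session=meta.get("session", ""),
        montage=montage,
    )


# ----------------------------------------------------------------------------
# Cohort manifests
# ----------------------------------------------------------------------------

MANIFEST_COLUMNS = ("animal_id", "genotype", "sex", "edf_path", "events_path")


def save_cohort(recordings: list[Recording], outdir: str | Path) -> Path:
    """Save every recording under ``outdir`` and write ``manifest.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        base = outdir / rec.animal_id
        paths = save_recording(rec, base)
        rows.append({
            "animal_id": rec.animal_id,
            "genotype": rec.genotype,
            "sex": rec.sex,
            "edf_path": paths["edf"].name,
            "events_path": paths["events"].name,
        })
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> list[Recording]:
    """Load all recordings referenced by a cohort manifest, in manifest order."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    if table.empty:
        logger.warning("cohort manifest %s is empty", manifest_path)
        return []
    ids = table["animal_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({a for a in ids if ids.count(a) > 1})
        raise ValueError(f"duplicate animal_id in manifest: {dupes}")
    bad = set(table["genotype"]) - set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotype label(s) in manifest: {sorted(bad)}")
    recordings = []
    for _, row in table.iterrows():
        base = manifest_path.parent / Path(row["edf_path"]).with_suffix("")
        rec = load_recording(base)
        rec = replace(rec, animal_id=row["animal_id"], genotype=row["genotype"], sex=row.get("sex", rec.sex))
        recordings.append(rec)
    return recordings
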