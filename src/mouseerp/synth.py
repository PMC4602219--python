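"""Synthetic epidural EEG cohorts with a known spatio-temporal evoked structure.

Each simulated animal is a continuous multi-channel recording: every click
trial adds, per channel, a sum of three Gaussian-windowed evoked components
(N1, P1, N2), on top of 1/f^β background noise; occasional large artifact
spikes (>1 mV) are inserted so the downstream rejection rule has work to do.
A cohort carries two genotype groups; the HYPO group's templates are altered
by a configurable per-(channel, component) amplitude scaling (negative values
flip polarity) and latency shift — the planted effect every downstream stage
is validated against.

The generated signal is quantized to 0.1 µV steps, emulating 16-bit
digitization over the amplifier's physical range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from mouseerp.io import Recording, default_montage

COMPONENT_LABELS = ("N1", "P1", "N2")
GENOTYPES = ("WT", "HYPO")
EEG_CHANNELS = ("FL", "FR", "PL", "PR", "OL", "OR")

#: analysis window (ms) over which evoked templates are integrated for the
#: ground-truth effect pattern
ANALYSIS_WINDOW_MS = (0.0, 250.0)


@dataclass(frozen=True)
class ComponentTemplate:
    """One evoked component: a Gaussian bump amplitude_uV · exp(−(t−latency)²/2·width²).

    N-labelled components are negative deflections (amplitude < 0 in the
    wild-type template), P-labelled positive.
    """

    label: str
    latency_ms: float
    width_ms: float
    amplitude_uV: float

    def __post_init__(self) -> None:
        if self.label not in COMPONENT_LABELS:
            raise ValueError(f"component label must be one of {COMPONENT_LABELS}")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if not (0 <= self.latency_ms < 250):
            raise ValueError("latency_ms must lie in [0, 250) ms")

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        return self.amplitude_uV * np.exp(-((t_ms - self.latency_ms) ** 2) / (2 * self.width_ms**2))


@dataclass(frozen=True)
class GenotypeEffect:
    """Per-(channel, component) alteration of the evoked template.

    ``scales`` maps "CH:COMP" → unitless amplitude multiplier (negative flips
    polarity); ``shifts_ms`` maps "CH:COMP" → additive latency change in ms.
    Missing keys mean "unaffected". The null effect has all scales 1 and all
    shifts 0 (equivalently: empty maps).
    """

    scales: dict = field(default_factory=dict)
    shifts_ms: dict = field(default_factory=dict)

    def scale(self, channel: str, component: str) -> float:
        return float(self.scales.get(f"{channel}:{component}", 1.0))

    def shift_ms(self, channel: str, component: str) -> float:
        return float(self.shifts_ms.get(f"{channel}:{component}", 0.0))

    def is_null(self) -> bool:
        return all(v == 1.0 for v in self.scales.values()) and all(
            v == 0.0 for v in self.shifts_ms.values()
        )

    @classmethod
    def null(cls) -> "GenotypeEffect":
        return cls()


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a simulated cohort; round-trips through YAML/JSON."""

    n_per_genotype: int
    sampling_rate_hz: float
    isi_s: float
    n_trials: int
    channel_templates: dict  # channel → tuple[ComponentTemplate, ComponentTemplate, ComponentTemplate]
    effect: GenotypeEffect
    noise_sd_uV: float
    noise_exponent: float
    animal_jitter_frac: float
    artifact_prob: float
    artifact_amp_uV: float
    seed: int
    latency_jitter_ms: float = 0.0  # optional trial-to-trial latency jitter, off by default

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not (0.0 <= self.artifact_prob <= 1.0):
            raise ValueError("artifact_prob must lie in [0, 1]")
        if self.artifact_prob > 0 and self.artifact_amp_uV <= 1000:
            raise ValueError("artifact_amp_uV must exceed 1000 µV so artifacts trip rejection")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_templates"] = {
            ch: [asdict(c) for c in comps] for ch, comps in self.channel_templates.items()
        }
        d["effect"] = {"scales": dict(self.effect.scales), "shifts_ms": dict(self.effect.shifts_ms)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["channel_templates"] = {
            ch: tuple(ComponentTemplate(**c) for c in comps)
            for ch, comps in d["channel_templates"].items()
        }
        d["effect"] = GenotypeEffect(**d["effect"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SynthConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def _scaled_templates(base: tuple, amp: float, shift: float) -> tuple:
    return tuple(
        replace(c, amplitude_uV=c.amplitude_uV * amp, latency_ms=c.latency_ms + shift)
        for c in base
    )


def default_config() -> SynthConfig:
    """The reference study conditions: 18 animals (9 per genotype), 1 kHz,
    2.5 s ISI, 1100 click trials, six bilateral channels.

    Wild-type frontal template: N1 (−30 µV, 25 ms, 8 ms SD), P1 (+40 µV,
    60 ms, 15 ms), N2 (−20 µV, 120 ms, 30 ms); parietal = frontal × 0.7 with
    +5 ms latencies; occipital = frontal × 0.5 with +10 ms. The hypomorph
    effect flips occipital N1 polarity (scale −0.8), attenuates frontal P1
    (scale 0.7) and delays frontal N1 by 10 ms.
    """
    frontal = (
        ComponentTemplate("N1", 25.0, 8.0, -30.0),
        ComponentTemplate("P1", 60.0, 15.0, 40.0),
        ComponentTemplate("N2", 120.0, 30.0, -20.0),
    )
    parietal = _scaled_templates(frontal, 0.7, 5.0)
    occipital = _scaled_templates(frontal, 0.5, 10.0)
    templates = {
        "FL": frontal, "FR": frontal,
        "PL": parietal, "PR": parietal,
        "OL": occipital, "OR": occipital,
    }
    effect = GenotypeEffect(
        scales={"OL:N1": -0.8, "OR:N1": -0.8, "FL:P1": 0.7, "FR:P1": 0.7},
        shifts_ms={"FL:N1": 10.0, "FR:N1": 10.0},
    )
    return SynthConfig(
        n_per_genotype=9,
        sampling_rate_hz=1000.0,
        isi_s=2.5,
        n_trials=1100,
        channel_templates=templates,
        effect=effect,
        noise_sd_uV=20.0,
        noise_exponent=1.0,
        animal_jitter_frac=0.1,
        artifact_prob=0.02,
        artifact_amp_uV=1500.0,
        seed=0,
    )


def null_config(**overrides) -> SynthConfig:
    """Default conditions with the genotype effect removed (chance-level cohort)."""
    return replace(default_config(), effect=GenotypeEffect.null(), **overrides)


def evoked_waveform(
    config: SynthConfig, genotype: str, channel: str, t_ms: np.ndarray
) -> np.ndarray:
    """The noise-free evoked template of one channel at times t_ms (ms post-stimulus)."""
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}, got {genotype!r}")
    t_ms = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t_ms)
    for comp in config.channel_templates[channel]:
        if genotype == "HYPO":
            comp = replace(
                comp,
                amplitude_uV=comp.amplitude_uV * config.effect.scale(channel, comp.label),
                latency_ms=comp.latency_ms + config.effect.shift_ms(channel, comp.label),
            )
        out += comp.waveform(t_ms)
    return out


def _pink_noise_multi(
    rng: np.random.Generator, n_channels: int, n: int, fs: float, beta: float, sd: float
) -> np.ndarray:
    """Independent 1/f^β noise per channel by spectral shaping of white
    Gaussian noise; content below 0.1 Hz (and DC) is zeroed to emulate the
    amplifier low-cut, and each channel is rescaled to exactly ``sd``.

    Synthesis runs in single precision (the signal is later quantized to
    0.1 µV anyway); the returned array is float64.
    """
    import scipy.fft as sfft

    white = rng.standard_normal((n_channels, n), dtype=np.float32)
    spec = sfft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros(len(freqs), dtype=np.float32)
    passband = freqs >= 0.1
    shape[passband] = freqs[passband].astype(np.float32) ** np.float32(-beta / 2.0)
    shaped = sfft.irfft(spec * shape, n, axis=1).astype(np.float64)
    s = shaped.std(axis=1, keepdims=True)
    s[s == 0] = np.inf
    return shaped * (sd / s)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, beta: float, sd: float) -> np.ndarray:
    """Single-channel convenience wrapper around :func:`_pink_noise_multi`."""
    return _pink_noise_multi(rng, 1, n, fs, beta, sd)[0]


def _event_onsets(config: SynthConfig) -> tuple[np.ndarray, int]:
    fs = config.sampling_rate_hz
    onsets = (np.round((1.0 + np.arange(config.n_trials) * config.isi_s) * fs)).astype(np.int64)
    n_samples = int(np.ceil(config.n_trials * config.isi_s * fs))
    n_samples = max(n_samples, int(onsets[-1] + round(1.5 * fs)))
    return onsets, n_samples


def simulate_animal(
    config: SynthConfig, genotype: str, animal_id: str, seed: int, sex: str = ""
) -> Recording:
    """Simulate one animal's continuous session.

    Deterministic in (config, genotype, animal_id, seed). The per-animal
    amplitude jitter is drawn once; each channel gets independent 1/f^β
    noise; artifact spikes of ±artifact_amp_uV land in a random
    ``artifact_prob`` fraction of inter-stimulus windows.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}, got {genotype!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fs = config.sampling_rate_hz
    onsets, n_samples = _event_onsets(config)
    channels = tuple(config.channel_templates.keys())
    data = np.zeros((len(channels), n_samples))

    gain = 1.0 + config.animal_jitter_frac * rng.standard_normal()
    # trial-to-trial latency jitter (off by default)
    trial_shift_ms = (
        config.latency_jitter_ms * rng.standard_normal(config.n_trials)
        if config.latency_jitter_ms > 0
        else np.zeros(config.n_trials)
    )

    # evoked support: the full epoch window around each onset
    half = int(round(0.5 * fs))
    rel = np.arange(-half, half)
    t_ms = rel / fs * 1000.0
    if config.latency_jitter_ms > 0:
        for i, onset in enumerate(onsets):
            for c, ch in enumerate(channels):
                data[c, onset - half : onset + half] += gain * evoked_waveform(
                    config, genotype, ch, t_ms - trial_shift_ms[i]
                )
    else:
        template = np.stack([gain * evoked_waveform(config, genotype, ch, t_ms) for ch in channels])
        for onset in onsets:
            data[:, onset - half : onset + half] += template

    if config.noise_sd_uV > 0:
        data += _pink_noise_multi(
            rng, len(channels), n_samples, fs, config.noise_exponent, config.noise_sd_uV
        )

    if config.artifact_prob > 0:
        hit = rng.random(config.n_trials) < config.artifact_prob
        for i in np.flatnonzero(hit):
            ch = rng.integers(0, len(channels))
            offset = rng.integers(-int(0.4 * fs), int(0.4 * fs))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            center = onsets[i] + offset
            # short triangular spike peaking at ±artifact_amp_uV
            spike = sign * config.artifact_amp_uV * np.array([0.2, 0.6, 1.0, 0.6, 0.2])
            lo = center - 2
            data[ch, lo : lo + 5] += spike

    data = np.round(data, 1)  # 0.1 µV quantization, as digitized at 16 bit
    return Recording(
        sampling_rate_hz=fs,
        data=data,
        channels=channels,
        events=onsets,
        animal_id=animal_id,
        genotype=genotype,
        sex=sex,
        montage=default_montage(),
    )


def simulate_cohort(config: SynthConfig) -> list[Recording]:
    """Simulate the full two-group cohort.

    Animal ids are WT01… and HY01…; per-animal seeds derive deterministically
    from config.seed. Sex alternates F/M within each group (5 female, 4 male
    at the default group size of 9).
    """
    if config.n_per_genotype < 1:
        raise ValueError("n_per_genotype must be >= 1")
    n_total = 2 * config.n_per_genotype
    seeds = np.random.SeedSequence(config.seed).generate_state(n_total) % (2**31)
    recordings = []
    idx = 0
    for genotype, prefix in (("WT", "WT"), ("HYPO", "HY")):
        for i in range(config.n_per_genotype):
            sex = "F" if i % 2 == 0 else "M"
            rec = simulate_animal(
                config, genotype, f"{prefix}{i + 1:02d}", int(seeds[idx]), sex=sex
            )
            recordings.append(rec)
            idx += 1
    return recordings


def true_effect_pattern(config: SynthConfig, dt_ms: float = 0.05) -> dict:
    """Ground-truth per-channel effect: the signed integral over (0, 250) ms of
    (WT template − HYPO template), in µV·ms. Exactly zero at unaffected channels."""
    t = np.arange(ANALYSIS_WINDOW_MS[0], ANALYSIS_WINDOW_MS[1], dt_ms)
    pattern = {}
    for ch in config.channel_templates:
        affected = any(
            config.effect.scale(ch, lab) != 1.0 or config.effect.shift_ms(ch, lab) != 0.0
            for lab in COMPONENT_LABELS
        )
        if not affected:
            pattern[ch] = 0.0
            continue
        diff = evoked_waveform(config, "WT", ch, t) - evoked_waveform(config, "HYPO", ch, t)
        pattern[ch] = float(np.trapezoid(diff, dx=dt_ms))
    return pattern
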