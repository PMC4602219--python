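"""End-to-end orchestration: simulate/load → preprocess → classify → map.

A single :class:`RunConfig` drives the whole experiment; every random draw
derives from its one seed, so a run is reproducible bit-for-bit from its
manifest. Outputs: ``cv_report.csv`` (error grid), ``chosen_pcs.csv``
(per-fold component counts), per-animal spatial-map TSV/JSON, a projection
scatter figure, and ``run_manifest.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import mouseerp
from mouseerp.discriminant import (
    DEFAULT_K_GRID,
    DEFAULT_PC_GRID,
    FEATURE_KINDS,
    FisherLDA,
    error_vs_averaging,
)
from mouseerp.features import (
    MULTI_CHANNELS,
    SINGLE_CHANNEL,
    FeatureMatrix,
    WaveformPCA,
    build_waveform_feature_matrix,
)
from mouseerp.io import load_cohort
from mouseerp.preprocess import EpochSet, block_average, extract_epochs, grand_average, reject_artifacts
from mouseerp.spatial import channel_projection_map, extract_temporal_discriminant, spanning_plane
from mouseerp.synth import SynthConfig, default_config, simulate_animal

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one experiment run (YAML/JSON round-trippable)."""

    synth: SynthConfig | None = None
    cohort_manifest: str | None = None
    window_ms: tuple[float, float] = (-500.0, 500.0)
    reject_uV: float = 1000.0
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    kinds: tuple[str, ...] = FEATURE_KINDS
    pc_grid: tuple[int, ...] = DEFAULT_PC_GRID
    channels: tuple[str, ...] = MULTI_CHANNELS
    single_channel: str = SINGLE_CHANNEL
    map_k: int = 4
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.synth is None and self.cohort_manifest is None:
            self.synth = default_config()
        if self.cohort_manifest is not None and not Path(self.cohort_manifest).exists():
            raise FileNotFoundError(self.cohort_manifest)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"] = self.synth.to_dict() if self.synth is not None else None
        for key in ("window_ms", "k_grid", "kinds", "pc_grid", "channels"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synth") is not None:
            d["synth"] = SynthConfig.from_dict(d["synth"])
        for key in ("window_ms", "k_grid", "kinds", "pc_grid", "channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def cohort_epochs(config: RunConfig) -> list[EpochSet]:
    """Produce per-animal, artifact-rejected epoch sets for the configured
    cohort (simulated on the fly, or loaded from a manifest)."""
    epochs = []
    if config.cohort_manifest is not None:
        for rec in load_cohort(config.cohort_manifest):
            ep = extract_epochs(rec, config.window_ms)
            epochs.append(reject_artifacts(ep, config.reject_uV))
        return epochs
    synth = replace(config.synth, seed=config.seed)
    n_total = 2 * synth.n_per_genotype
    seeds = np.random.SeedSequence(synth.seed).generate_state(n_total) % (2**31)
    idx = 0
    for genotype, prefix in (("WT", "WT"), ("HYPO", "HY")):
        for i in range(synth.n_per_genotype):
            sex = "F" if i % 2 == 0 else "M"
            rec = simulate_animal(synth, genotype, f"{prefix}{i + 1:02d}", int(seeds[idx]), sex=sex)
            idx += 1
            ep = extract_epochs(rec, config.window_ms)
            epochs.append(reject_artifacts(ep, config.reject_uV))
            del rec
    return epochs


def fit_cohort_discriminant(
    epochs: list[EpochSet],
    k: int,
    n_pcs: int,
    channels=MULTI_CHANNELS,
    pc_cap: int = 100,
):
    """Fit PCA + Fisher on all animals pooled (for the map product only —
    never fed back into cross-validation). Returns (pca, classifier, feats)."""
    feats = FeatureMatrix.concat(
        [build_waveform_feature_matrix(block_average(ep, k), channels) for ep in epochs
         if block_average(ep, k).n_epochs > 0]
    )
    cap = min(pc_cap, feats.n_samples - 1, feats.n_features)
    n_pcs = min(n_pcs, cap)
    pca = WaveformPCA(n_components=cap).fit(feats.X)
    clf = FisherLDA().fit(pca.transform(feats.X)[:, :n_pcs], feats.genotypes)
    return pca, clf, feats


def animal_maps(
    epochs: list[EpochSet],
    temporal: np.ndarray,
    channels=MULTI_CHANNELS,
    window_ms=(0.0, 250.0),
):
    """Per-animal cortical maps: each animal's mean (0, 250) ms ERP per
    channel projected onto the temporal discriminant, then interpolated."""
    from mouseerp.io import default_montage

    montage = default_montage()
    maps = []
    for ep in epochs:
        ga = grand_average(ep)
        sel = (ep.times_ms >= window_ms[0]) & (ep.times_ms < window_ms[1])
        W = np.stack([ga[ep.channel_index(ch)][sel] for ch in channels])
        maps.append(
            channel_projection_map(W, tuple(channels), temporal, montage, animal_id=ep.animal_id)
        )
    return maps


from contextlib import contextmanager


@contextmanager
def _stage(name: str, outdir: Path):
    """Tag stage failures and leave an ``INCOMPLETE`` marker behind."""
    try:
        yield
    except Exception as exc:
        (outdir / "INCOMPLETE").write_text(f"failed during stage {name}: {exc}\n")
        raise RuntimeError(f"[stage {name}] {exc}") from exc


def run_experiment(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write the report bundle to ``outdir``.

    Idempotent for a fixed seed: re-running with the same config produces
    byte-identical CSV outputs. A stage failure aborts with a stage-tagged
    message and marks the partial output directory ``INCOMPLETE``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate/load: preparing cohort epochs")
    with _stage("simulate", outdir):
        epochs = cohort_epochs(config)

    logger.info("stage classify: %d kinds × %d averaging sizes", len(config.kinds), len(config.k_grid))
    with _stage("classify", outdir):
        report = error_vs_averaging(
            epochs, config.kinds, config.k_grid, config.pc_grid,
            config.channels, config.single_channel,
        )
    report.to_csv(outdir / "cv_report.csv")
    report.to_json(outdir / "cv_report.json")
    pcs_rows = [
        {"k": c.k, "animal_id": a, "n_pcs": p}
        for c in report.cells if c.kind == "pc_multi" for a, p in sorted(c.chosen_pcs.items())
    ]
    pd.DataFrame(pcs_rows, columns=["k", "animal_id", "n_pcs"]).to_csv(
        outdir / "chosen_pcs.csv", index=False
    )

    logger.info("stage map: temporal discriminant and per-animal cortical maps")
    with _stage("map", outdir):
        try:
            n_pcs = int(report.cell(config.map_k, "pc_multi").n_pcs)
        except (KeyError, ValueError):
            n_pcs = 20
        pca, clf, feats = fit_cohort_discriminant(
            epochs, config.map_k, max(n_pcs, 1), config.channels, pc_cap=int(max(config.pc_grid))
        )
        n_time = feats.n_features // len(config.channels)
        temporal, spatial_w = extract_temporal_discriminant(
            clf, pca, len(config.channels), n_time
        )
        maps = animal_maps(epochs, temporal, config.channels)
        for m in maps:
            pd.DataFrame(
                m.grid_values, index=m.grid_ap_mm, columns=m.grid_ml_mm
            ).to_csv(outdir / f"map_{m.animal_id}.tsv", sep="\t")
            (outdir / f"map_{m.animal_id}.json").write_text(
                json.dumps({"animal_id": m.animal_id, "channel_values": m.channel_values}, indent=1)
                + "\n"
            )
        _map_figure(maps, [ep.genotype for ep in epochs], outdir)

    _projection_figure(epochs, outdir)
    (outdir / "INCOMPLETE").unlink(missing_ok=True)

    manifest = {
        "package_version": mouseerp.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_animals": len(epochs),
        "temporal_discriminant_norm": float(np.linalg.norm(temporal)),
        "spatial_weights": {ch: float(v) for ch, v in zip(config.channels, spatial_w)},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return {"report": report, "maps": maps, "temporal": temporal, "outdir": outdir}


def _map_figure(maps, genotypes, outdir: Path) -> None:
    """Group-mean cortical maps and their WT − HYPO difference as one figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = {}
    for m, g in zip(maps, genotypes):
        groups.setdefault(g, []).append(m.grid_values)
    if set(groups) != {"WT", "HYPO"}:
        return
    wt = np.mean(groups["WT"], axis=0)
    hy = np.mean(groups["HYPO"], axis=0)
    panels = [("WT mean", wt), ("HYPO mean", hy), ("WT − HYPO", wt - hy)]
    extent = [maps[0].grid_ml_mm[0], maps[0].grid_ml_mm[-1],
              maps[0].grid_ap_mm[0], maps[0].grid_ap_mm[-1]]
    vmax = max(np.abs(p[1]).max() for p in panels) or 1.0
    fig, axes = plt.subplots(1, 3, figsize=(10, 4), sharey=True)
    for ax, (title, grid) in zip(axes, panels):
        im = ax.imshow(grid, origin="lower", extent=extent, aspect="equal",
                       cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_title(title)
        ax.set_xlabel("ML (mm)")
    axes[0].set_ylabel("AP (mm)")
    fig.colorbar(im, ax=axes, shrink=0.8, label="projection (µV·a.u.)")
    fig.savefig(outdir / "map_group_means.png", dpi=120)
    plt.close(fig)


def _projection_figure(epochs: list[EpochSet], outdir: Path) -> None:
    """Scatter of single-trial FR/PR/OR waveforms on the grand-average
    spanning plane (channel-cluster geometry)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    window = (0.0, 250.0)
    sel = (epochs[0].times_ms >= window[0]) & (epochs[0].times_ms < window[1])
    chans = ("FR", "PR", "OR")
    if any(ch not in epochs[0].channels for ch in chans):
        return
    pooled = {ch: [] for ch in chans}
    for ep in epochs:
        for ch in chans:
            pooled[ch].append(ep.retained()[:, ep.channel_index(ch), :][:, sel])
    stacks = {ch: np.vstack(v) for ch, v in pooled.items()}
    gas = {ch: s.mean(axis=0) for ch, s in stacks.items()}
    try:
        plane = spanning_plane(gas["FR"], gas["PR"], gas["OR"])
    except ValueError:
        return
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"FR": "tab:orange", "PR": "tab:green", "OR": "tab:purple"}
    for ch in chans:
        xy = plane.project(stacks[ch])
        ax.scatter(xy[:, 0], xy[:, 1], s=2, alpha=0.15, color=colors[ch], label=ch)
        g = plane.project(gas[ch])
        ax.scatter([g[0]], [g[1]], s=60, color="white", edgecolor=colors[ch], zorder=3)
    ax.set_xlabel("spanning waveform #1")
    ax.set_ylabel("spanning waveform #2")
    ax.legend(markerscale=5)
    fig.tight_layout()
    fig.savefig(outdir / "projection_scatter.png", dpi=120)
    plt.close(fig)
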