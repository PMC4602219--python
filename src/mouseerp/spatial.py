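"""Geometric readouts: spanning planes, covariance ellipses, the temporal
discriminant, and interpolated cortical maps.

The spanning plane is the 2-D affine subspace through three grand-average
waveforms (channels FR, PR, OR): origin at their centroid, basis by
Gram–Schmidt on the first two mean-centered waveforms. Projections of
single-trial waveforms onto this plane reproduce the channel-cluster
geometry; 1 σ covariance ellipses summarize trial scatter.

The temporal discriminant factorizes the waveform-space Fisher weights: the
PC-space weight vector is mapped back through the PCA loadings, reshaped to
channels × time, and decomposed by SVD. The leading right-singular vector
(unit norm, largest-magnitude sample positive) is the temporal discriminant;
the leading left-singular vector scaled by the leading singular value gives
per-channel spatial weights. Projecting each channel's animal-mean ERP onto
the temporal discriminant yields one scalar per electrode, interpolated over
the cortical plane by thin-plate radial basis functions (exact at the
electrodes) to produce the per-animal cortical map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator

from mouseerp.io import Montage
from mouseerp.discriminant import FisherLDA
from mouseerp.features import WaveformPCA

#: interpolation grid bounds (mm from bregma) and spacing
GRID_AP_MM = (-6.0, 3.0)
GRID_ML_MM = (-4.0, 4.0)
GRID_STEP_MM = 0.1


@dataclass
class ProjectionPlane:
    """Affine 2-D plane in waveform space: origin + two orthonormal spanning
    waveforms."""

    origin: np.ndarray
    basis: np.ndarray  # (2, n_times), orthonormal rows

    def project(self, waveforms: np.ndarray) -> np.ndarray:
        return project_onto_plane(self, waveforms)


def spanning_plane(ga_fr: np.ndarray, ga_pr: np.ndarray, ga_or: np.ndarray) -> ProjectionPlane:
    """Plane through three grand averages; spanning waveforms #1 and #2 by
    Gram–Schmidt on (ga_fr − centroid, ga_pr − centroid)."""
    ga_fr, ga_pr, ga_or = (np.asarray(g, dtype=float) for g in (ga_fr, ga_pr, ga_or))
    if not (ga_fr.shape == ga_pr.shape == ga_or.shape) or ga_fr.ndim != 1:
        raise ValueError("the three grand averages must be 1-D and equally long")
    centroid = (ga_fr + ga_pr + ga_or) / 3.0
    v1 = ga_fr - centroid
    v2 = ga_pr - centroid
    n1 = np.linalg.norm(v1)
    if n1 < 1e-12:
        raise ValueError("grand averages are collinear; plane undefined")
    e1 = v1 / n1
    u2 = v2 - (v2 @ e1) * e1
    n2 = np.linalg.norm(u2)
    if n2 < 1e-9 * max(np.linalg.norm(v2), 1e-30):
        raise ValueError("grand averages are collinear; plane undefined")
    e2 = u2 / n2
    return ProjectionPlane(origin=centroid, basis=np.vstack([e1, e2]))


def project_onto_plane(plane: ProjectionPlane, waveforms: np.ndarray) -> np.ndarray:
    """2-D in-plane coordinates: inner products with the spanning waveforms
    after centering on the plane origin."""
    W = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if W.shape[1] != len(plane.origin):
        raise ValueError("waveform length does not match the plane")
    coords = (W - plane.origin) @ plane.basis.T
    return coords[0] if np.asarray(waveforms).ndim == 1 else coords


@dataclass
class EllipseParams:
    """A covariance ellipse: the nsigma contour of a 2-D sample covariance."""

    center: np.ndarray
    semi_axes: np.ndarray  # descending
    angle_rad: float       # orientation of the major axis
    nsigma: float


def covariance_ellipse(points: np.ndarray, nsigma: float = 1.0) -> EllipseParams:
    """Center = mean; semi-axes = nsigma·sqrt(covariance eigenvalues);
    orientation from the leading eigenvector. Collinear points give a
    degenerate (zero-minor-axis) ellipse."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 2:
        raise ValueError("need at least 2 points in 2-D")
    center = points.mean(axis=0)
    cov = np.cov(points.T)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)[::-1]
    vecs = vecs[:, ::-1]
    return EllipseParams(
        center=center,
        semi_axes=nsigma * np.sqrt(vals),
        angle_rad=float(np.arctan2(vecs[1, 0], vecs[0, 0])),
        nsigma=nsigma,
    )


def cluster_separation(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Distance between two 2-D cluster means in pooled-covariance
    Mahalanobis units (a σ-style separation readout)."""
    points_a = np.asarray(points_a, float)
    points_b = np.asarray(points_b, float)
    pooled = (
        (len(points_a) - 1) * np.cov(points_a.T) + (len(points_b) - 1) * np.cov(points_b.T)
    ) / (len(points_a) + len(points_b) - 2)
    d = points_a.mean(axis=0) - points_b.mean(axis=0)
    return float(np.sqrt(d @ np.linalg.solve(pooled, d)))


def extract_temporal_discriminant(
    classifier: FisherLDA, pca: WaveformPCA, n_channels: int, n_time: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-1 space × time factorization of the discriminant weights.

    Returns (temporal vector of length n_time with unit norm, per-channel
    spatial weights of length n_channels). The temporal vector's sign is
    fixed so its largest-magnitude sample is positive; the compensating sign
    lives in the spatial weights, keeping their outer product invariant.
    """
    w_pc = np.asarray(classifier.coef_, dtype=float)
    if len(w_pc) > pca.n_components_:
        raise ValueError("classifier uses more components than the PCA provides")
    w_wave = pca.components_[: len(w_pc)].T @ w_pc
    if len(w_wave) != n_channels * n_time:
        raise ValueError(
            f"waveform dimension {len(w_wave)} != n_channels × n_time "
            f"({n_channels} × {n_time})"
        )
    W = w_wave.reshape(n_channels, n_time)
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    tau = Vt[0]
    spatial = U[:, 0] * s[0]
    if tau[np.abs(tau).argmax()] < 0:
        tau = -tau
        spatial = -spatial
    return tau, spatial


@dataclass
class SpatialMap:
    """Per-channel discriminant projection values with a thin-plate
    interpolation over the cortical plane (exact at the electrodes)."""

    channel_values: dict
    grid_ap_mm: np.ndarray
    grid_ml_mm: np.ndarray
    grid_values: np.ndarray  # (n_ap, n_ml)
    animal_id: str = ""


def channel_projection_map(
    channel_waveforms: np.ndarray,
    channels: tuple[str, ...],
    temporal: np.ndarray,
    montage: Montage,
    animal_id: str = "",
    grid_step_mm: float = GRID_STEP_MM,
) -> SpatialMap:
    """Project each channel's mean ERP onto the temporal discriminant and
    interpolate the resulting per-channel scalars over the cortical grid.

    ``channel_waveforms`` is (n_channels, n_time) over the analysis window,
    rows ordered like ``channels``.
    """
    W = np.asarray(channel_waveforms, dtype=float)
    temporal = np.asarray(temporal, dtype=float)
    if W.ndim != 2 or W.shape[0] != len(channels):
        raise ValueError("channel_waveforms must be (n_channels, n_time)")
    if W.shape[1] != len(temporal):
        raise ValueError("ERP window length does not match the temporal vector")
    coords = []
    for ch in channels:
        if ch not in montage:
            raise ValueError(f"montage is missing channel {ch!r}")
        e = montage[ch]
        coords.append((e.ap_mm, e.ml_mm))
    coords = np.asarray(coords, dtype=float)
    values = W @ temporal

    interp = RBFInterpolator(coords, values, kernel="thin_plate_spline")
    ap = np.arange(GRID_AP_MM[0], GRID_AP_MM[1] + grid_step_mm / 2, grid_step_mm)
    ml = np.arange(GRID_ML_MM[0], GRID_ML_MM[1] + grid_step_mm / 2, grid_step_mm)
    AP, ML = np.meshgrid(ap, ml, indexing="ij")
    grid = interp(np.column_stack([AP.ravel(), ML.ravel()])).reshape(AP.shape)
    return SpatialMap(
        channel_values={ch: float(v) for ch, v in zip(channels, values)},
        grid_ap_mm=ap,
        grid_ml_mm=ml,
        grid_values=grid,
        animal_id=animal_id,
    )
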