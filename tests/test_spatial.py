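"""Spanning planes, covariance ellipses, temporal discriminant, cortical maps."""

import numpy as np
import pytest

from mouseerp.discriminant import FisherLDA
from mouseerp.features import WaveformPCA
from mouseerp.io import default_montage
from mouseerp.spatial import (
    channel_projection_map,
    covariance_ellipse,
    extract_temporal_discriminant,
    project_onto_plane,
    spanning_plane,
)


@pytest.fixture
def three_waveforms(rng):
    t = np.linspace(0, 250, 250)
    ga_fr = -30 * np.exp(-((t - 25) ** 2) / 128) + 40 * np.exp(-((t - 60) ** 2) / 450)
    ga_pr = 0.7 * np.roll(ga_fr, 5)
    ga_or = 0.5 * np.roll(ga_fr, 10) + 3 * np.sin(t / 40)
    return ga_fr, ga_pr, ga_or


class TestSpanningPlane:
    def test_defining_waveforms_reconstruct_exactly(self, three_waveforms):
        plane = spanning_plane(*three_waveforms)
        for g in three_waveforms:
            xy = project_onto_plane(plane, g)
            recon = plane.origin + xy @ plane.basis
            assert np.linalg.norm(recon - g) < 1e-9 * np.linalg.norm(g)

    def test_projection_idempotent(self, three_waveforms, rng):
        plane = spanning_plane(*three_waveforms)
        w = rng.normal(size=250)
        xy1 = project_onto_plane(plane, w)
        in_plane = plane.origin + xy1 @ plane.basis
        xy2 = project_onto_plane(plane, in_plane)
        np.testing.assert_allclose(xy1, xy2, atol=1e-9)

    def test_orthogonal_waveform_projects_to_origin(self, three_waveforms, rng):
        plane = spanning_plane(*three_waveforms)
        w = rng.normal(size=250)
        # explicit orthogonal-complement construction
        w_perp = w - plane.basis.T @ (plane.basis @ w)
        xy = project_onto_plane(plane, plane.origin + w_perp)
        np.testing.assert_allclose(xy, [0.0, 0.0], atol=1e-8)

    def test_origin_and_basis_coordinates(self, three_waveforms):
        plane = spanning_plane(*three_waveforms)
        np.testing.assert_allclose(project_onto_plane(plane, plane.origin), [0, 0], atol=1e-10)
        np.testing.assert_allclose(
            project_onto_plane(plane, plane.origin + plane.basis[0]), [1, 0], atol=1e-10
        )

    def test_matches_least_squares_oracle(self, three_waveforms, rng):
        plane = spanning_plane(*three_waveforms)
        w = rng.normal(size=250)
        A = plane.basis.T
        coef, *_ = np.linalg.lstsq(A, w - plane.origin, rcond=None)
        np.testing.assert_allclose(project_onto_plane(plane, w), coef, atol=1e-9)

    def test_collinear_means_error(self):
        t = np.arange(100, dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            spanning_plane(t, 2 * t, 3 * t)

    def test_isometry_on_the_plane(self, three_waveforms, rng):
        plane = spanning_plane(*three_waveforms)
        a = plane.origin + rng.normal(size=2) @ plane.basis
        b = plane.origin + rng.normal(size=2) @ plane.basis
        d_full = np.linalg.norm(a - b)
        d_plane = np.linalg.norm(project_onto_plane(plane, a) - project_onto_plane(plane, b))
        assert d_plane == pytest.approx(d_full, rel=1e-9)


class TestCovarianceEllipse:
    def test_monte_carlo_isotropic_gaussian(self):
        pts = np.random.default_rng(42).normal(size=(10_000, 2))
        ell = covariance_ellipse(pts, nsigma=1)
        assert 0.95 <= ell.semi_axes[0] <= 1.05
        assert 0.95 <= ell.semi_axes[1] <= 1.05

    def test_nsigma_scales_axes(self, rng):
        pts = rng.normal(size=(200, 2)) @ np.array([[2.0, 0.3], [0.0, 0.5]])
        e1 = covariance_ellipse(pts, nsigma=1)
        e2 = covariance_ellipse(pts, nsigma=2)
        np.testing.assert_allclose(e2.semi_axes, 2 * e1.semi_axes, rtol=1e-12)

    def test_collinear_points_degenerate_not_failing(self):
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([t, 2 * t])
        ell = covariance_ellipse(pts)
        assert ell.semi_axes[1] == pytest.approx(0.0, abs=1e-8)
        assert ell.semi_axes[0] > 0

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            covariance_ellipse(np.array([[0.0, 0.0]]))


def _rank1_setup(rng, n_channels=5, n_time=250, n_pcs=12):
    """Plant w = s ⊗ τ in waveform space, expressed in an orthonormal loading
    basis whose span contains it (as a fitted PCA basis would when the
    discriminant direction carries class variance)."""
    tau = np.sin(np.linspace(0, 3 * np.pi, n_time))
    tau /= np.linalg.norm(tau)
    s = np.array([1.5, -0.7, 0.4, 2.0, -1.1])[:n_channels]
    w_wave = np.outer(s, tau).ravel()
    d = n_channels * n_time
    M = np.column_stack([w_wave, rng.normal(size=(d, n_pcs - 1))])
    Q, _ = np.linalg.qr(M)
    pca = WaveformPCA()
    pca.mean_ = np.zeros(d)
    pca.components_ = Q.T
    pca.n_components_ = n_pcs
    w_pc = pca.components_ @ w_wave
    clf = FisherLDA._from_solution(np.array(["HYPO", "WT"]), w_pc, 0.0, 0.0, 0.0)
    return tau, s, pca, clf


class TestTemporalDiscriminant:
    def test_recovers_planted_rank1_pattern(self, rng):
        tau, s, pca, clf = _rank1_setup(rng)
        t_hat, s_hat = extract_temporal_discriminant(clf, pca, 5, 250)
        assert abs(t_hat @ tau) >= 0.999
        scale = s_hat @ s / (s @ s)
        np.testing.assert_allclose(s_hat, scale * s, atol=1e-8)

    def test_exact_recovery_when_weights_exact(self):
        # bypass PCA truncation: identity loadings
        n_ch, n_t = 4, 50
        tau = np.cos(np.linspace(0, 2 * np.pi, n_t))
        tau /= np.linalg.norm(tau)
        s = np.array([2.0, -1.0, 0.5, 1.5])
        pca = WaveformPCA()
        pca.mean_ = np.zeros(n_ch * n_t)
        pca.components_ = np.eye(n_ch * n_t)
        pca.n_components_ = n_ch * n_t
        clf = FisherLDA._from_solution(
            np.array(["HYPO", "WT"]), np.outer(s, tau).ravel(), 0.0, 0.0, 0.0
        )
        t_hat, s_hat = extract_temporal_discriminant(clf, pca, n_ch, n_t)
        assert abs(t_hat @ tau) >= 0.999
        assert np.linalg.norm(t_hat) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(np.outer(s_hat, t_hat), np.outer(s, tau), atol=1e-9)

    def test_sign_convention_fixed(self):
        n_ch, n_t = 3, 40
        tau = np.sin(np.linspace(0, np.pi, n_t))
        tau /= np.linalg.norm(tau)
        s = np.array([1.0, 2.0, -0.5])
        pca = WaveformPCA()
        pca.mean_ = np.zeros(n_ch * n_t)
        pca.components_ = np.eye(n_ch * n_t)
        pca.n_components_ = n_ch * n_t
        mk = lambda w: FisherLDA._from_solution(np.array(["HYPO", "WT"]), w, 0.0, 0.0, 0.0)
        t1, s1 = extract_temporal_discriminant(mk(np.outer(s, tau).ravel()), pca, n_ch, n_t)
        t2, s2 = extract_temporal_discriminant(mk(np.outer(s, -tau).ravel()), pca, n_ch, n_t)
        np.testing.assert_allclose(t1, t2, atol=1e-9)
        assert t1[np.abs(t1).argmax()] > 0

    def test_dimension_mismatch_errors(self, rng):
        tau, s, pca, clf = _rank1_setup(rng)
        with pytest.raises(ValueError):
            extract_temporal_discriminant(clf, pca, 7, 250)


class TestNullCohortMaps:
    def test_no_false_spatial_signature_without_effect(self):
        """On zero-effect cohorts the WT−HYPO difference of group-mean channel
        projections stays within 4 SE of its across-animal variability at
        every channel, allowing the expected false-positive share of
        cohorts (≤ 2 of 5 at the 5% + 4 SD allowance)."""
        from dataclasses import replace
        from mouseerp.features import MULTI_CHANNELS
        from mouseerp.pipeline import RunConfig, cohort_epochs, fit_cohort_discriminant
        from mouseerp.preprocess import grand_average
        from mouseerp.synth import null_config

        violating = 0
        for seed in range(5):
            cfg = RunConfig(
                synth=replace(null_config(), n_per_genotype=3, n_trials=96), seed=seed
            )
            eps = cohort_epochs(cfg)
            pca, clf, feats = fit_cohort_discriminant(eps, 4, 10)
            n_time = feats.n_features // len(MULTI_CHANNELS)
            tau, _ = extract_temporal_discriminant(clf, pca, len(MULTI_CHANNELS), n_time)
            proj = {"WT": [], "HYPO": []}
            for ep in eps:
                ga = grand_average(ep)
                sel = (ep.times_ms >= 0) & (ep.times_ms < 250)
                W = np.stack([ga[ep.channel_index(c)][sel] for c in MULTI_CHANNELS])
                proj[ep.genotype].append(W @ tau)
            a, b = np.array(proj["WT"]), np.array(proj["HYPO"])
            diff = a.mean(0) - b.mean(0)
            se = np.sqrt(a.var(0, ddof=1) / len(a) + b.var(0, ddof=1) / len(b))
            violating += bool((np.abs(diff) / se > 4).any())
        assert violating <= 2


class TestChannelProjectionMap:
    CHANNELS = ("FL", "FR", "PR", "OL", "OR")

    def test_constant_values_interpolate_to_constant(self):
        tau = np.ones(10) / np.sqrt(10)
        W = np.tile(tau * 0.7, (5, 1))  # every row ⋅ τ = 0.7
        m = channel_projection_map(W, self.CHANNELS, tau, default_montage())
        assert np.allclose(list(m.channel_values.values()), 0.7)
        assert np.abs(m.grid_values - 0.7).max() < 1e-6

    def test_surface_exact_at_electrodes(self, rng):
        tau = rng.normal(size=50)
        tau /= np.linalg.norm(tau)
        W = rng.normal(size=(5, 50))
        montage = default_montage()
        m = channel_projection_map(W, self.CHANNELS, tau, montage, grid_step_mm=0.5)
        for ch, val in m.channel_values.items():
            e = montage[ch]
            i = np.argmin(np.abs(m.grid_ap_mm - e.ap_mm))
            j = np.argmin(np.abs(m.grid_ml_mm - e.ml_mm))
            # grid nodes land exactly on electrode coordinates (0.5 mm grid)
            assert m.grid_values[i, j] == pytest.approx(val, abs=1e-8)

    def test_linearity_in_the_erp(self, rng):
        tau = rng.normal(size=30)
        tau /= np.linalg.norm(tau)
        W = rng.normal(size=(5, 30))
        m1 = channel_projection_map(W, self.CHANNELS, tau, default_montage(), grid_step_mm=1.0)
        m2 = channel_projection_map(2 * W, self.CHANNELS, tau, default_montage(), grid_step_mm=1.0)
        np.testing.assert_allclose(m2.grid_values, 2 * m1.grid_values, atol=1e-8)

    def test_missing_montage_channel_errors(self, rng):
        from mouseerp.io import Montage, MontageEntry

        montage = Montage((MontageEntry("FL", 1.0, -1.0),))
        with pytest.raises(ValueError, match="FR"):
            channel_projection_map(
                np.zeros((2, 10)), ("FL", "FR"), np.ones(10), montage
            )

    def test_window_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            channel_projection_map(
                np.zeros((5, 20)), self.CHANNELS, np.ones(10), default_montage()
            )
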