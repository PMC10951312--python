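"""Image-quality metrics: mutual information, SNR/CNR, FFT noise, layer counts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from octcycle import (
    LayerDetectParams,
    PhantomConfig,
    ResolutionEllipse,
    RoiStats,
    cnr_db,
    count_retinal_layers,
    fft_noise_beyond_resolution,
    make_clean_frame,
    mmi,
    roi_stats,
    sclera_uniformity,
    snr_db,
    vitreous_stats,
)
from octcycle.errors import MaskError, NoOutsideRegionError, UndefinedMetricError
from octcycle.types import RoiMaskSet


def brute_force_mi(x, y, bins):
    """Independent oracle: explicit double sum over joint histogram cells."""
    x, y = np.ravel(x).astype(float), np.ravel(y).astype(float)
    lo, hi = min(x.min(), y.min()), max(x.max(), y.max())
    edges = np.linspace(lo, hi, bins + 1)
    total = 0.0
    n = x.size
    joint = np.zeros((bins, bins))
    for xi, yi in zip(x, y):
        i = min(np.searchsorted(edges, xi, side="right") - 1, bins - 1)
        j = min(np.searchsorted(edges, yi, side="right") - 1, bins - 1)
        joint[i, j] += 1.0 / n
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    for i in range(bins):
        for j in range(bins):
            if joint[i, j] > 0:
                total += joint[i, j] * math.log(joint[i, j] / (px[i] * py[j]))
    return total


class TestMMI:
    @pytest.mark.parametrize(
        "x,y",
        [
            ([[0.0, 1.0], [1.0, 0.0]], [[1.0, 0.0], [0.0, 1.0]]),
            ([[0.0, 1.0], [1.0, 1.0]], [[0.0, 0.0], [1.0, 1.0]]),
            ([[0.2, 0.8], [0.8, 0.2]], [[0.2, 0.8], [0.8, 0.2]]),
        ],
    )
    def test_two_by_two_matches_brute_force(self, x, y):
        """2x2 images with 2-bin histograms against the hand-evaluated sum."""
        x, y = np.asarray(x), np.asarray(y)
        assert mmi(x, y, 2) == pytest.approx(brute_force_mi(x, y, 2), abs=1e-12)

    def test_self_information_is_histogram_entropy(self, rng):
        x = rng.random((64, 64))
        hist, _ = np.histogram(x, bins=64)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mmi(x, x, 64) == pytest.approx(entropy, rel=1e-10)

    def test_independent_images_near_zero(self, rng):
        """MI of independent noise stays within the permutation-null spread."""
        x, y = rng.random((128, 128)), rng.random((128, 128))
        null = [
            mmi(x, rng.permutation(y.ravel()).reshape(y.shape), 16) for _ in range(20)
        ]
        assert mmi(x, y, 16) < np.mean(null) + 3 * np.std(null) + 1e-9

    def test_constant_pair_returns_zero(self):
        assert mmi(np.ones((8, 8)), np.ones((8, 8))) == 0.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        data=hnp.arrays(
            np.float64,
            (2, 6, 6),
            elements=st.floats(0, 1, allow_nan=False, width=32),
        )
    )
    def test_symmetry_nonnegativity_and_self_dominance(self, data):
        x, y = data[0], data[1]
        m_xy, m_yx = mmi(x, y, 8), mmi(y, x, 8)
        assert m_xy == pytest.approx(m_yx, abs=1e-12)
        assert m_xy >= -1e-12
        # data-processing inequality, evaluated under the same binning
        pooled = (float(min(x.min(), y.min())), float(max(x.max(), y.max())))
        assert mmi(x, x, 8, pooled) >= mmi(x, y, 8, pooled) - 1e-12


class TestSnrCnr:
    def test_closed_forms(self):
        assert snr_db(RoiStats(100.0, 0.0, 0.0, 10.0)) == pytest.approx(20.0)
        assert cnr_db(RoiStats(110.0, 0.0, 10.0, 10.0)) == pytest.approx(20.0)
        assert snr_db(RoiStats(10.0, 0.0, 0.0, 10.0)) == pytest.approx(0.0)

    def test_zero_background_sd_undefined(self):
        with pytest.raises(UndefinedMetricError):
            snr_db(RoiStats(1.0, 0.0, 0.0, 0.0))

    def test_equal_means_give_minus_infinity_cnr(self):
        assert cnr_db(RoiStats(5.0, 0.0, 5.0, 1.0)) == float("-inf")

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        mu_i=st.floats(0.1, 1e3),
        mu_b=st.floats(0.0, 1e3),
        sigma_b=st.floats(1e-3, 1e3),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, mu_i, mu_b, sigma_b, c):
        """Multiplying a frame by c > 0 scales all ROI moments by c and leaves
        SNR and CNR unchanged."""
        a = RoiStats(mu_i, 0.0, mu_b, sigma_b)
        b = RoiStats(c * mu_i, 0.0, c * mu_b, c * sigma_b)
        assert snr_db(a) == pytest.approx(snr_db(b), rel=1e-9, abs=1e-9)
        assert cnr_db(a) == pytest.approx(cnr_db(b), rel=1e-9, abs=1e-9) or (
            cnr_db(a) == cnr_db(b)
        )


class TestFftNoise:
    def test_default_geometry_semi_axes(self):
        """k_cut = N * px / res for the instrument geometry."""
        ell = ResolutionEllipse.from_geometry(1536, 1024)
        assert ell.semi_axis_axial == pytest.approx(1536 * 1.95 / 6.3)
        assert ell.semi_axis_transverse == pytest.approx(1024 * 5.9 / 20.0)
        assert ell.semi_axis_axial == pytest.approx(475.43, abs=0.01)
        assert ell.semi_axis_transverse == pytest.approx(302.08, abs=0.01)

    def test_undersampled_geometry_rejected(self):
        with pytest.raises(UndefinedMetricError):
            ResolutionEllipse.from_geometry(256, 256, 3.9, 5.9)

    def test_constant_image_scores_zero(self):
        ell = ResolutionEllipse(10.0, 10.0)
        assert fft_noise_beyond_resolution(np.full((64, 64), 3.0), ell) == pytest.approx(0.0)

    def test_noise_scores_above_its_smoothed_version(self, rng):
        from scipy import ndimage

        x = rng.random((128, 128))
        sm = ndimage.gaussian_filter(x, 4.0)
        ell = ResolutionEllipse(20.0, 20.0)
        assert fft_noise_beyond_resolution(x, ell) > fft_noise_beyond_resolution(sm, ell)

    def test_translation_invariance(self, rng):
        x = rng.random((64, 64))
        ell = ResolutionEllipse(12.0, 12.0)
        rolled = np.roll(np.roll(x, 7, axis=0), -11, axis=1)
        assert fft_noise_beyond_resolution(x, ell) == pytest.approx(
            fft_noise_beyond_resolution(rolled, ell), rel=1e-9
        )

    def test_ellipse_covering_spectrum_rejected(self):
        with pytest.raises(NoOutsideRegionError):
            fft_noise_beyond_resolution(np.ones((8, 8)), ResolutionEllipse(100.0, 100.0))


class TestRegionStats:
    def test_constant_sclera_has_zero_sd(self):
        labels = np.full((10, 10), 6, dtype=np.uint8)
        masks = RoiMaskSet(labels, {"sclera": 6})
        assert sclera_uniformity(np.full((10, 10), 0.5), masks) == 0.0

    def test_empty_vitreous_scores_zero_mean_and_sd(self):
        labels = np.full((10, 10), 1, dtype=np.uint8)
        masks = RoiMaskSet(labels, {"vitreous": 1})
        assert vitreous_stats(np.zeros((10, 10)), masks) == (0.0, 0.0)

    def test_missing_region_raises(self):
        masks = RoiMaskSet(np.ones((4, 4), dtype=np.uint8), {"sclera": 1})
        with pytest.raises(MaskError):
            vitreous_stats(np.zeros((4, 4)), masks)

    def test_roi_stats_against_numpy_moments(self, clean_frame_full):
        _, frame, masks = clean_frame_full
        stats = roi_stats(frame, masks, "rpe")
        rpe = frame[masks.region("rpe")]
        assert stats.mu_i == pytest.approx(rpe.mean())
        assert stats.sigma_i == pytest.approx(rpe.std())


class TestLayerCounting:
    def test_default_phantom_counts_eleven_interfaces(self, clean_frame_full):
        """Noise-free default anatomy: the counter finds all 11 interfaces."""
        cfg, frame, masks = clean_frame_full
        res = count_retinal_layers(frame, masks, cfg.axial_px_um)
        assert res.median_interfaces == 11
        assert res.n_interfaces == pytest.approx(11.0, abs=0.2)

    def test_default_phantom_mean_thickness_near_fifty_um(self, clean_frame_full):
        """Mean inter-interface spacing ~50 um within one axial pixel."""
        cfg, frame, masks = clean_frame_full
        res = count_retinal_layers(frame, masks, cfg.axial_px_um)
        assert res.mean_thickness_um == pytest.approx(50.0, abs=cfg.axial_px_um)

    @pytest.mark.parametrize("thickness", [30.0, 50.0, 80.0])
    def test_thickness_sweep_recovers_configured_spacing(self, thickness):
        cfg = PhantomConfig(rng_seed=2, layer_thickness_um=thickness)
        frame, masks = make_clean_frame(cfg)
        res = count_retinal_layers(frame, masks, cfg.axial_px_um)
        assert res.median_interfaces == cfg.n_interfaces
        assert res.mean_thickness_um == pytest.approx(thickness, abs=cfg.axial_px_um)

    def test_flat_region_counts_zero(self):
        labels = np.zeros((64, 32), dtype=np.uint8)
        labels[16:48] = 3
        masks = RoiMaskSet(labels, {"retina": 3})
        res = count_retinal_layers(np.full((64, 32), 0.5), masks, 1.95)
        assert res.n_interfaces == 0.0
        assert res.mean_thickness_um is None
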