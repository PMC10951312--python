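"""Two-step registration: translation, A-scan tilt, outlier rejection."""

import numpy as np
import pytest
from scipy import ndimage

from octcycle import (
    PhantomConfig,
    apply_tilt,
    detect_outliers,
    fit_ascan_tilt,
    make_phantom,
    register_translation,
)
from octcycle.errors import DegenerateInputError, FitError
from octcycle.phantom import make_clean_frame
from octcycle.registration import otsu_split


@pytest.fixture(scope="module")
def clean():
    cfg = PhantomConfig.desk(rng_seed=1, frame_height=192, frame_width=128,
                             n_interfaces=6, layer_thickness_um=60.0)
    frame, masks = make_clean_frame(cfg)
    return frame.astype(float), masks


class TestTranslation:
    def test_identity(self, clean):
        frame, _ = clean
        shift, reg = register_translation(frame, frame)
        assert shift.as_tuple() == (0, 0)
        assert np.allclose(reg, frame)

    def test_constructed_translation_recovered(self, clean):
        frame, _ = clean
        moved = ndimage.shift(frame, (5, 3), order=1, cval=0.0)
        shift, reg = register_translation(moved, frame)
        assert shift.as_tuple() == (5, 3)
        interior = (slice(10, -10), slice(10, -10))
        assert np.abs(reg[interior] - frame[interior]).mean() < 0.01 * np.ptp(frame)

    def test_constant_image_raises(self, clean):
        frame, _ = clean
        with pytest.raises(DegenerateInputError):
            register_translation(np.ones_like(frame), frame)

    def test_seeded_jitter_recovered_within_one_pixel(self):
        """Median |error| of recovered shifts over 50 speckled frames <= 1 px
        for eye-motion jitter up to ~10 px."""
        cfg = PhantomConfig.desk(
            rng_seed=32, frame_height=192, frame_width=128, duration_s=0.5,
            n_interfaces=6, layer_thickness_um=60.0,
            pulsation_amp_px=0.0, jitter_sd_px=3.0, tilt_drift_px_per_frame=0.0,
        )
        out = make_phantom(cfg)
        errs = []
        for i in range(50):
            s, _ = register_translation(out.video.frames[i], out.base_frame)
            errs.append(
                np.hypot(
                    s.axial_shift - out.true_global_shifts[i, 0],
                    s.transverse_shift - out.true_global_shifts[i, 1],
                )
            )
        assert np.median(errs) <= 1.0

    def test_idempotence(self, clean):
        frame, _ = clean
        moved = ndimage.shift(frame, (4, -2), order=1, cval=0.0)
        _, reg = register_translation(moved, frame)
        shift2, _ = register_translation(reg, frame)
        assert abs(shift2.axial_shift) <= 1 and abs(shift2.transverse_shift) <= 1


class TestAscanTilt:
    def test_identity_gives_zero_fit(self, clean):
        frame, _ = clean
        fit = fit_ascan_tilt(frame, frame)
        assert fit.slope == 0.0 and fit.intercept == 0.0

    @pytest.mark.parametrize("true_slope", [0.02, -0.03, 0.05])
    def test_constructed_linear_tilt_recovered(self, clean, true_slope):
        """Slope recovered within the integer-lag quantization of the fit.

        Oracle: OLS over the per-column rounded shifts, which is what integer
        lags can represent at best.
        """
        frame, _ = clean
        h, w = frame.shape
        zz, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
        tilted = ndimage.map_coordinates(frame, [zz - true_slope * xx, xx], order=1, cval=0.0)
        fit = fit_ascan_tilt(tilted, frame, stride=10)
        cols = np.arange(0, w, 10, dtype=float)
        oracle_slope = np.polyfit(cols, np.round(true_slope * cols), 1)[0]
        quant = 2.0 / w  # worst-case slope error from +-0.5 px lag rounding
        assert fit.slope == pytest.approx(oracle_slope, abs=quant)
        assert abs(fit.intercept) < 1.0

    def test_pure_axial_offset_fits_intercept(self, clean):
        frame, _ = clean
        moved = ndimage.shift(frame, (4, 0), order=1, cval=0.0)
        fit = fit_ascan_tilt(moved, frame)
        assert fit.slope == pytest.approx(0.0, abs=1e-6)
        assert fit.intercept == pytest.approx(4.0, abs=0.5)

    def test_tilt_roundtrip_restores_frame(self, clean):
        frame, _ = clean
        h, w = frame.shape
        zz, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
        tilted = ndimage.map_coordinates(frame, [zz - 0.02 * xx, xx], order=1, cval=0.0)
        fit = fit_ascan_tilt(tilted, frame, stride=10)
        restored = apply_tilt(tilted, fit)
        assert np.abs(restored - frame).mean() < 0.01 * np.ptp(frame)

    def test_apply_zero_fit_is_identity(self, clean):
        frame, _ = clean
        fit = fit_ascan_tilt(frame, frame)
        assert np.array_equal(apply_tilt(frame, fit), frame)

    def test_constant_columns_unchanged_by_shift(self):
        """Columns that are constant in depth are invariant under axial shift
        (up to edge fill) and carry no correlation signal for the fit."""
        frame = np.tile(np.linspace(0.1, 1, 64), (128, 1))
        with pytest.raises(FitError):
            fit_ascan_tilt(frame, frame)  # zero-variance columns unusable
        from octcycle.registration import TiltFit

        fit = TiltFit(0.01, 2.0, np.arange(0, 64, 20), np.zeros(4))
        shifted = apply_tilt(frame, fit)
        assert np.allclose(shifted[5:-5, :], frame[5:-5, :])

    def test_tilt_recovery_across_seeded_trials(self, clean):
        """Fitted slope stays within quantization of truth over 20 seeded trials."""
        frame, _ = clean
        h, w = frame.shape
        zz, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
        r = np.random.default_rng(77)
        quant = 2.0 / w
        for _ in range(20):
            s = r.uniform(-0.06, 0.06)
            tilted = ndimage.map_coordinates(frame, [zz - s * xx, xx], order=1, cval=0.0)
            fit = fit_ascan_tilt(tilted, frame, stride=10)
            assert abs(fit.slope - s) <= quant + 0.004


class TestOutliers:
    def test_identical_frames_all_kept(self, clean):
        frame, _ = clean
        frames = [frame.copy() for _ in range(5)]
        assert detect_outliers(frames, frames[0]).size == 5

    def test_pure_noise_frame_flagged(self, clean, rng):
        """29 mildly speckled copies + 1 structureless noise frame: only the
        noise frame is below the Otsu split and gets removed."""
        frame, _ = clean
        frames = [frame * rng.gamma(4.0, 0.25, frame.shape) for _ in range(29)]
        frames.append(rng.uniform(0, frame.max(), frame.shape))
        kept = detect_outliers(frames, frames[0])
        assert 29 not in kept
        assert kept.size == 29

    def test_tight_cluster_kept(self, clean, rng):
        """A unimodal MMI set (mild speckle variants) fails the separation
        criterion; nothing is removed."""
        frame, _ = clean
        frames = [frame * rng.gamma(8.0, 0.125, frame.shape) for _ in range(20)]
        assert detect_outliers(frames, frames[0]).size == 20

    def test_removal_capped_at_max_fraction(self, clean, rng):
        """Even when many frames sit below the split, at most the configured
        fraction of the bin is removed."""
        frame, _ = clean
        good = [frame * rng.gamma(8.0, 0.125, frame.shape) for _ in range(10)]
        bad = [rng.uniform(0, frame.max(), frame.shape) for _ in range(10)]
        kept = detect_outliers(good + bad, good[0], max_remove_frac=0.2)
        assert kept.size == 16  # floor(0.2 * 20) = 4 removed

    def test_otsu_split_decisiveness(self, rng):
        _, decisive_uni = otsu_split(rng.normal(5.0, 0.3, 40))
        _, decisive_bi = otsu_split(np.r_[rng.normal(2, 0.2, 20), rng.normal(5, 0.2, 20)])
        assert not decisive_uni
        assert decisive_bi
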