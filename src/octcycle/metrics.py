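"""Global and region-specific image-quality metrics for OCT B-scans.

Global metrics
    * mutual information between image pairs (joint intensity histogram),
    * SNR/CNR in decibels from ROI-vs-background statistics,
    * mean FFT magnitude beyond the resolution ellipse of the instrument —
      spatial frequencies beyond the optical resolution cannot carry signal,
      so their average magnitude measures the residual noise level.

Region-specific metrics exploit anatomy: the sclera is homogeneous collagen
(its intensity SD should be ~0), the vitreous humor is optically empty (mean
and SD should be ~0), and the retina is a stack of layers whose interfaces
appear as peaks of the vertical intensity gradient — a denoised scan should
show the expected interface count (11 from the inner limiting membrane to
Bruch's membrane) at ~50 um average spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .errors import MaskError, NoOutsideRegionError, UndefinedMetricError
from .types import RoiMaskSet

__all__ = [
    "mmi",
    "RoiStats",
    "roi_stats",
    "snr_db",
    "cnr_db",
    "ResolutionEllipse",
    "fft_noise_beyond_resolution",
    "sclera_uniformity",
    "vitreous_stats",
    "LayerDetectParams",
    "LayerProfileResult",
    "count_retinal_layers",
]


def mmi(
    x: np.ndarray,
    y: np.ndarray,
    n_histogram_bins: int = 64,
    intensity_range: tuple[float, float] | None = None,
) -> float:
    """Mutual information between two images from their joint histogram.

    The joint histogram uses ``n_histogram_bins`` equal-width bins per axis
    over ``intensity_range`` (default: the pooled intensity range of the
    pair), normalised to a joint probability mass function P(X,Y); the
    metric is

        sum_xy P(X,Y)(x,y) * log( P(X,Y)(x,y) / (P_X(x) * P_Y(y)) )

    in nats. A constant image pair (degenerate histogram) returns 0. Passing
    an explicit range makes values comparable across pairs (and makes the
    data-processing inequality MMI(X,X) >= MMI(X,Y) hold exactly).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise UndefinedMetricError("images must have the same number of pixels")
    if n_histogram_bins < 2:
        raise UndefinedMetricError("n_histogram_bins must be >= 2")
    if intensity_range is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
    else:
        lo, hi = intensity_range
    if hi == lo:
        return 0.0
    pxy, _, _ = np.histogram2d(
        x, y, bins=n_histogram_bins, range=[[lo, hi], [lo, hi]]
    )
    pxy /= pxy.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    denom = np.outer(px, py)[nz]
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / denom)))


@dataclass
class RoiStats:
    """First- and second-moment intensity statistics of an ROI and background."""

    mu_i: float
    sigma_i: float
    mu_b: float
    sigma_b: float


def roi_stats(
    frame: np.ndarray,
    masks: RoiMaskSet,
    roi: str,
    background: str = "background",
    erode_px: int = 0,
) -> RoiStats:
    """Mean/SD of the named ROI and the background region of a frame.

    ``erode_px`` shrinks both masks by that many pixels before measuring —
    useful on registered/averaged frames whose mask borders are contaminated
    by the zero fill of shifted source frames.
    """
    frame = np.asarray(frame, dtype=float)
    roi_mask = masks.region(roi)
    bg_mask = masks.region(background)
    if erode_px > 0:
        roi_mask = ndimage.binary_erosion(roi_mask, iterations=erode_px)
        bg_mask = ndimage.binary_erosion(bg_mask, iterations=erode_px)
        if not roi_mask.any() or not bg_mask.any():
            raise MaskError("mask empty after erosion")
    if frame.shape != masks.labels.shape:
        raise MaskError("frame and mask shapes differ")
    ri = frame[roi_mask]
    rb = frame[bg_mask]
    return RoiStats(
        mu_i=float(ri.mean()),
        sigma_i=float(ri.std()),
        mu_b=float(rb.mean()),
        sigma_b=float(rb.std()),
    )


def snr_db(stats: RoiStats) -> float:
    """Signal-to-noise ratio: ``20 * log10(mu_i / sigma_b)`` in dB."""
    if stats.sigma_b == 0:
        raise UndefinedMetricError("background SD is zero; SNR undefined")
    if stats.mu_i <= 0:
        return float("-inf")
    return 20.0 * np.log10(stats.mu_i / stats.sigma_b)


def cnr_db(stats: RoiStats) -> float:
    """Contrast-to-noise ratio: ``20 * log10(|mu_i - mu_b| / sigma_b)`` in dB.

    Returns ``-inf`` when ROI and background means coincide.
    """
    if stats.sigma_b == 0:
        raise UndefinedMetricError("background SD is zero; CNR undefined")
    contrast = abs(stats.mu_i - stats.mu_b)
    if contrast == 0:
        return float("-inf")
    return 20.0 * np.log10(contrast / stats.sigma_b)


@dataclass
class ResolutionEllipse:
    """Resolution-limit ellipse in the centred 2-D FFT plane.

    Semi-axes are expressed in FFT bins. For an image of N pixels of pitch
    ``px`` (um) along one axis and an optical resolution ``res`` (um), the
    cut-off sits at ``k_cut = N * px / res`` bins from the DC term.
    """

    semi_axis_axial: float
    semi_axis_transverse: float

    def __post_init__(self) -> None:
        if self.semi_axis_axial <= 0 or self.semi_axis_transverse <= 0:
            raise UndefinedMetricError("ellipse semi-axes must be strictly positive")

    @classmethod
    def from_geometry(
        cls,
        n_axial: int,
        n_transverse: int,
        axial_px_um: float = 1.95,
        transverse_px_um: float = 5.9,
        axial_res_um: float = 6.3,
        transverse_res_um: float = 20.0,
    ) -> "ResolutionEllipse":
        a = n_axial * axial_px_um / axial_res_um
        b = n_transverse * transverse_px_um / transverse_res_um
        if a > n_axial / 2 or b > n_transverse / 2:
            raise UndefinedMetricError(
                "resolution cut-off beyond Nyquist: the image is undersampled "
                f"(semi-axes ({a:.1f}, {b:.1f}) bins vs Nyquist "
                f"({n_axial / 2:.0f}, {n_transverse / 2:.0f}))"
            )
        return cls(semi_axis_axial=a, semi_axis_transverse=b)


def fft_noise_beyond_resolution(frame: np.ndarray, ellipse: ResolutionEllipse) -> float:
    """Mean centred-FFT magnitude strictly outside the resolution ellipse."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise UndefinedMetricError("empty frame")
    h, w = frame.shape
    spec = np.fft.fftshift(np.abs(np.fft.fft2(frame)))
    kz = np.arange(h) - h // 2
    kx = np.arange(w) - w // 2
    zz, xx = np.meshgrid(kz, kx, indexing="ij")
    outside = (zz / ellipse.semi_axis_axial) ** 2 + (
        xx / ellipse.semi_axis_transverse
    ) ** 2 > 1.0
    if not outside.any():
        raise NoOutsideRegionError("resolution ellipse covers the whole spectrum")
    return float(spec[outside].mean())


def sclera_uniformity(frame: np.ndarray, masks: RoiMaskSet) -> float:
    """Intensity SD over the sclera (homogeneous tissue; expected ~0)."""
    return float(np.asarray(frame, float)[masks.region("sclera")].std())


def vitreous_stats(frame: np.ndarray, masks: RoiMaskSet) -> tuple[float, float]:
    """(mean, SD) of intensity over the vitreous humor (expected ~(0, 0))."""
    v = np.asarray(frame, float)[masks.region("vitreous")]
    return float(v.mean()), float(v.std())


@dataclass
class LayerDetectParams:
    """Tunables of the retinal-interface counter.

    smooth_sigma_px
        Gaussian smoothing of the axial profile before differentiation.
    prominence_factor
        Peak prominence threshold as a fraction of the per-column SD of the
        gradient magnitude.
    min_separation_px
        Minimum axial distance between detected interfaces.
    column_stride
        Every k-th A-scan inside the retina mask is analysed.
    pad_px
        Rows added above/below the mask span so the boundary interfaces
        (inner limiting membrane, Bruch's membrane) fall inside the profile.
    """

    smooth_sigma_px: float = 2.0
    prominence_factor: float = 0.5
    min_separation_px: int = 5
    column_stride: int = 4
    pad_px: int = 4


@dataclass
class LayerProfileResult:
    """Interface count and spacing averaged over sampled A-scans."""

    n_interfaces: float  # mean gradient-peak count per sampled column
    median_interfaces: float  # median count (robust to stray columns)
    mean_thickness_um: float | None  # mean inter-peak spacing; None if < 2 peaks
    n_columns: int


def count_retinal_layers(
    frame: np.ndarray,
    masks: RoiMaskSet,
    axial_px_um: float,
    params: LayerDetectParams | None = None,
) -> LayerProfileResult:
    """Count retinal interfaces as peaks of the vertical intensity gradient.

    For every ``column_stride``-th A-scan crossing the retina mask, the axial
    profile (mask span padded by ``pad_px``) is Gaussian-smoothed, the
    magnitude of its vertical gradient is computed, and peaks exceeding the
    prominence threshold with the minimum separation are collected. The
    interface count and the mean inter-peak distance (converted to um via
    ``axial_px_um``) are averaged over columns.
    """
    if params is None:
        params = LayerDetectParams()
    frame = np.asarray(frame, dtype=float)
    retina = masks.region("retina")
    if frame.shape != masks.labels.shape:
        raise MaskError("frame and mask shapes differ")
    h, _ = frame.shape

    counts: list[int] = []
    spacings: list[float] = []
    col_has = retina.any(axis=0)
    for c in np.nonzero(col_has)[0][:: params.column_stride]:
        rows = np.nonzero(retina[:, c])[0]
        z_lo = max(0, rows[0] - params.pad_px)
        z_hi = min(h, rows[-1] + 1 + params.pad_px)
        profile = frame[z_lo:z_hi, c]
        if profile.size < 2 * params.min_separation_px:
            continue
        smooth = ndimage.gaussian_filter1d(profile, params.smooth_sigma_px)
        grad = np.abs(np.gradient(smooth))
        sd = grad.std()
        if sd == 0:
            counts.append(0)
            continue
        peaks, _ = find_peaks(
            grad,
            prominence=params.prominence_factor * sd,
            distance=params.min_separation_px,
        )
        counts.append(int(peaks.size))
        if peaks.size >= 2:
            spacings.append(float(np.mean(np.diff(peaks))) * axial_px_um)

    if not counts:
        return LayerProfileResult(0.0, 0.0, None, 0)
    return LayerProfileResult(
        n_interfaces=float(np.mean(counts)),
        median_interfaces=float(np.median(counts)),
        mean_thickness_um=float(np.mean(spacings)) if spacings else None,
        n_columns=len(counts),
    )
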