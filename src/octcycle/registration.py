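"""Two-step B-scan registration and MMI-based outlier rejection.

Step 1 is a global rigid translation of the moving frame onto a reference
frame, estimated by FFT cross-correlation (integer-pixel by default,
subpixel refinement behind a flag). Step 2 corrects the progressive A-scan
tilt — an axial shift that varies linearly across columns, caused by slow
rotational drift during acquisition: the axial lag maximising the normalised
cross-correlation between reference and moving A-scans is measured every
``stride`` columns, a least-squares line is fitted over (column, lag), and
the fitted per-column shift is subtracted.

Outlier frames within a cardiac-phase bin are found by computing the mutual
information (MMI) of each registered frame against the bin reference,
splitting the pooled MMI values with Otsu's threshold, and removing the
low-MMI group only when the split is decisive (inter-class variance a large
enough fraction of the total) and removal stays under a safety cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .errors import DegenerateInputError, FitError
from .metrics import mmi

__all__ = [
    "RigidShift",
    "TiltFit",
    "register_translation",
    "fit_ascan_tilt",
    "apply_tilt",
    "detect_outliers",
    "otsu_split",
]


@dataclass
class RigidShift:
    """Translation of the moving frame's content relative to the reference.

    ``moving[z, x] ~ reference[z - axial_shift, x - transverse_shift]``;
    registering means shifting the moving frame by the negated values.
    """

    axial_shift: float
    transverse_shift: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.axial_shift, self.transverse_shift)


@dataclass
class TiltFit:
    """Linear model of axial shift across A-scans.

    ``per_column_shift[i]`` is the integer lag maximising the normalised
    cross-correlation between the A-scans at ``sampled_columns[i]``;
    ``slope``/``intercept`` are the ordinary least-squares line through
    (column, lag). Shift at column ``c`` is ``slope * c + intercept``.
    """

    slope: float
    intercept: float
    sampled_columns: np.ndarray
    per_column_shift: np.ndarray

    def shift_at(self, columns: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(columns, dtype=float) + self.intercept


def register_translation(
    moving: np.ndarray,
    reference: np.ndarray,
    subpixel: bool = False,
    upsample_factor: int = 10,
    presmooth_sigma: float = 1.0,
) -> tuple[RigidShift, np.ndarray]:
    """Estimate and remove the global translation between two frames.

    The shift is estimated on Gaussian-presmoothed copies
    (``presmooth_sigma`` px; 0 disables) — smoothing suppresses the speckle
    contribution to the correlation without biasing the peak location — and
    applied to the raw moving frame. Returns the estimated
    :class:`RigidShift` and the moving frame shifted by its negation (linear
    interpolation for subpixel shifts, zero fill).
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise DegenerateInputError("frames must have the same shape")
    if np.ptp(moving) == 0 or np.ptp(reference) == 0:
        raise DegenerateInputError("constant image cannot be registered")
    if presmooth_sigma > 0:
        mov_est = ndimage.gaussian_filter(moving, presmooth_sigma)
        ref_est = ndimage.gaussian_filter(reference, presmooth_sigma)
    else:
        mov_est, ref_est = moving, reference
    # phase_cross_correlation returns the shift to apply to `moving` to align
    # it with `reference`, i.e. the negative of the content displacement.
    # Plain cross-correlation (normalization=None): phase whitening weights
    # all frequencies equally and locks onto speckle noise on smooth frames.
    shift, _, _ = phase_cross_correlation(
        ref_est,
        mov_est,
        upsample_factor=upsample_factor if subpixel else 1,
        normalization=None,
    )
    rigid = RigidShift(axial_shift=-float(shift[0]), transverse_shift=-float(shift[1]))
    if not subpixel:
        rigid = RigidShift(round(rigid.axial_shift), round(rigid.transverse_shift))
    registered = ndimage.shift(
        moving,
        (-rigid.axial_shift, -rigid.transverse_shift),
        order=1,
        mode="constant",
        cval=0.0,
    )
    return rigid, registered


def _best_lag(ref_col: np.ndarray, mov_col: np.ndarray, max_lag: int) -> tuple[int, float]:
    """Lag in [-max_lag, max_lag] maximising zero-mean normalised correlation.

    Positive lag means the moving A-scan content sits deeper (larger z) than
    the reference: ``mov[z + lag] ~ ref[z]``.
    """
    h = ref_col.size
    r = ref_col - ref_col.mean()
    m = mov_col - mov_col.mean()
    sr, sm = r.std(), m.std()
    if sr == 0 or sm == 0:
        return 0, 0.0
    r /= sr
    m /= sm
    full = np.correlate(m, r, mode="full")  # index k <-> lag = k - (h - 1)
    lags = np.arange(-(h - 1), h)
    window = np.abs(lags) <= max_lag
    overlap = h - np.abs(lags[window])
    vals = full[window] / overlap
    best = int(np.argmax(vals))
    return int(lags[window][best]), float(vals[best])


def fit_ascan_tilt(
    moving: np.ndarray,
    reference: np.ndarray,
    stride: int = 20,
    max_lag: int | None = None,
    corr_floor: float = 0.3,
    column_window: int = 2,
    presmooth_sigma: float = 1.5,
) -> TiltFit:
    """Fit the linear A-scan tilt between a moving frame and a reference.

    Correlations are computed every ``stride`` columns; each sampled A-scan
    is the mean over ``2 * column_window + 1`` neighbouring columns, axially
    smoothed by ``presmooth_sigma`` px, which suppresses speckle in the lag
    estimate. Columns whose best normalised correlation falls below
    ``corr_floor`` are excluded from the fit. ``max_lag`` defaults to 10% of
    the frame height.

    Raises
    ------
    FitError
        If fewer than 2 usable columns remain.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise DegenerateInputError("frames must have the same shape")
    if stride < 1:
        raise DegenerateInputError("stride must be >= 1")
    h, w = moving.shape
    if max_lag is None:
        max_lag = max(1, h // 10)

    def _column(img: np.ndarray, c: int) -> np.ndarray:
        lo, hi = max(0, c - column_window), min(w, c + column_window + 1)
        col = img[:, lo:hi].mean(axis=1)
        if presmooth_sigma > 0:
            col = ndimage.gaussian_filter1d(col, presmooth_sigma)
        return col

    cols, shifts = [], []
    for c in range(0, w, stride):
        lag, val = _best_lag(_column(reference, c), _column(moving, c), max_lag)
        if val >= corr_floor:
            cols.append(c)
            shifts.append(lag)
    if len(cols) < 2:
        raise FitError(
            f"only {len(cols)} usable column(s) above correlation floor {corr_floor}"
        )
    cols_a = np.asarray(cols, dtype=float)
    shifts_a = np.asarray(shifts, dtype=float)
    slope, intercept = np.polyfit(cols_a, shifts_a, 1)
    return TiltFit(
        slope=float(slope),
        intercept=float(intercept),
        sampled_columns=cols_a.astype(int),
        per_column_shift=shifts_a,
    )


def apply_tilt(frame: np.ndarray, fit: TiltFit) -> np.ndarray:
    """Remove a fitted tilt: shift column ``c`` axially by ``-(slope*c + intercept)``.

    Linear interpolation, zero fill outside the frame.
    """
    frame = np.asarray(frame, dtype=float)
    if not (np.isfinite(fit.slope) and np.isfinite(fit.intercept)):
        raise DegenerateInputError("tilt fit must be finite")
    if fit.slope == 0 and fit.intercept == 0:
        return frame.copy()
    h, w = frame.shape
    zz, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    coords = np.array([zz + fit.slope * xx + fit.intercept, xx])
    return ndimage.map_coordinates(frame, coords, order=1, mode="constant", cval=0.0)


def otsu_split(values: np.ndarray, separation_min: float = 0.85) -> tuple[float | None, bool]:
    """Otsu threshold over a 1-D value set plus a decisiveness check.

    Returns ``(threshold, decisive)``. ``decisive`` is True when the
    inter-class variance at the Otsu split exceeds ``separation_min`` times
    the total variance — i.e. the set genuinely splits into two groups.
    A (near-)constant set returns ``(None, False)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.ptp(values) < 1e-12:
        return None, False
    thr = float(threshold_otsu(values, nbins=min(256, max(2, values.size * 8))))
    low = values < thr
    if not low.any() or low.all():
        return thr, False
    w0 = low.mean()
    w1 = 1.0 - w0
    between = w0 * w1 * (values[low].mean() - values[~low].mean()) ** 2
    total = values.var()
    return thr, bool(total > 0 and between / total >= separation_min)


def detect_outliers(
    bin_frames: list[np.ndarray] | np.ndarray,
    reference: np.ndarray,
    n_histogram_bins: int = 64,
    separation_min: float = 0.85,
    max_remove_frac: float = 0.2,
) -> np.ndarray:
    """Indices of frames to keep after MMI-based outlier rejection.

    Each frame's mutual information against the reference is computed; the
    set is Otsu-split and, when the split is decisive, sub-threshold frames
    are flagged. Never removes more than ``max_remove_frac`` of the frames
    (the lowest-MMI ones go first) and never returns an empty set.
    """
    frames = list(bin_frames)
    if len(frames) < 2:
        return np.arange(len(frames))
    # The reference (when present among the frames) matches itself with an
    # MMI equal to its histogram entropy — an artefact that would dominate
    # the Otsu split — so it is always kept and excluded from the split.
    is_ref = np.array([f is reference or np.array_equal(f, reference) for f in frames])
    candidates = np.nonzero(~is_ref)[0]
    if candidates.size < 2:
        return np.arange(len(frames))
    mmis = np.array([mmi(frames[i], reference, n_histogram_bins) for i in candidates])
    thr, decisive = otsu_split(mmis, separation_min)
    if thr is None or not decisive:
        return np.arange(len(frames))
    flagged = candidates[mmis < thr]
    max_remove = int(np.floor(max_remove_frac * len(frames)))
    max_remove = min(max_remove, len(frames) - 1)
    if flagged.size > max_remove:
        order = np.argsort(mmis[np.isin(candidates, flagged)])  # lowest MMI first
        flagged = flagged[order[:max_remove]]
    keep = np.setdiff1d(np.arange(len(frames)), flagged)
    return keep
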