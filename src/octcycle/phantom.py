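"""Synthetic OCT phantom: layered-retina B-scan videos with known ground truth.

The phantom emulates the statistical structure that the one-cycle denoising
pipeline assumes: a static layered eye cross-section (vitreous, retina with a
configurable number of interfaces, bright RPE band, textured choroid,
homogeneous sclera, dark background), deformed per frame by

1. cardiac pulsation — an axial displacement of the retina/choroid boundary
   region, modulated by the pulse waveform value at the frame timestamp;
2. global eye-motion translation jitter (axial + transverse, i.i.d. Gaussian);
3. a progressive A-scan tilt — an axial shift growing linearly across columns
   whose edge-column magnitude accumulates frame to frame;

and finally multiplied by fully developed speckle modelled as i.i.d.
mean-one gamma noise: ``I_noisy = I_clean * S`` with ``S ~ Gamma(L, 1/L)``
(L = ``speckle_looks``; L=1 gives exponential intensity statistics, large L
approaches the noise-free limit). A pulse-oximeter trace synchronised to the
deformation is generated alongside, so the full pulse-binning path can be
exercised end to end with known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError, SizingError
from .types import BScanVideo, PulseTrace, RoiMaskSet

__all__ = [
    "PhantomConfig",
    "PhantomOutput",
    "make_phantom",
    "make_clean_frame",
    "make_pulse_trace",
    "pulse_waveform",
    "unwarp_frame",
]

#: Label values used in phantom mask sets (0 is unused).
PHANTOM_LABELMAP = {
    "vitreous": 1,
    "rnfl": 2,
    "retina": 3,  # inner retinal layers between RNFL and RPE
    "rpe": 4,
    "choroid": 5,
    "sclera": 6,
    "background": 7,
}

# Reflectivity levels of the piecewise-constant anatomy (arbitrary linear units).
_VITREOUS_LEVEL = 0.0
_LAYER_LEVELS = (0.65, 0.35)  # alternating retinal layer contrast
_RPE_LEVEL = 0.95
_CHOROID_BASE = 0.45
_CHOROID_TEXTURE_AMP = 0.12
_SCLERA_LEVEL = 0.55
_BACKGROUND_LEVEL = 0.02


@dataclass
class PhantomConfig:
    """Geometry, acquisition and noise parameters of the synthetic phantom.

    Defaults reproduce the full-scale acquisition conditions the pipeline is
    designed for: 30 s of 1536x1024 B-scans at ~100 Hz (3000 frames),
    1.95 um axial / 5.9 um transverse pixels, a retina with 11 interfaces
    delimiting ~50 um layers, and a ~1 Hz heart beat. Use
    :meth:`PhantomConfig.desk` for a down-scaled preset suited to quick runs.
    """

    frame_height: int = 1536
    frame_width: int = 1024
    axial_px_um: float = 1.95
    transverse_px_um: float = 5.9
    axial_res_um: float = 6.3
    transverse_res_um: float = 20.0
    bscan_rate_hz: float = 100.0
    duration_s: float = 30.0
    heart_period_s: float = 1.0
    period_jitter_sd_s: float = 0.0
    pulse_rate_hz: float = 250.0
    first_peak_s: float = 0.25
    trace_pad_s: float = 1.0
    systole_frac: float = 0.4
    n_interfaces: int = 11
    layer_thickness_um: float = 50.0
    curvature_amp_frac: float = 0.05
    n_vessels: int = 4
    vessel_shadow_depth: float = 0.35
    speckle_looks: float = 1.0
    pulsation_amp_px: float = 3.0
    pulsation_sigma_frac: float = 0.08
    jitter_sd_px: float = 2.0
    tilt_drift_px_per_frame: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "frame_height frame_width axial_px_um transverse_px_um bscan_rate_hz "
            "duration_s heart_period_s pulse_rate_hz systole_frac n_interfaces "
            "layer_thickness_um speckle_looks pulsation_sigma_frac "
            "axial_res_um transverse_res_um"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        nonneg = (
            "period_jitter_sd_s pulsation_amp_px jitter_sd_px trace_pad_s "
            "curvature_amp_frac n_vessels vessel_shadow_depth"
        ).split()
        if not 0 <= self.vessel_shadow_depth < 1:
            raise ConfigError("vessel_shadow_depth must be in [0, 1)")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_interfaces < 2:
            raise ConfigError("n_interfaces must be >= 2")
        if self.pulse_rate_hz < 4.0 / self.heart_period_s:
            raise ConfigError("pulse sampling rate must be >= 4 / heart_period_s")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.bscan_rate_hz))

    @classmethod
    def desk(cls, **overrides) -> "PhantomConfig":
        """Down-scaled preset: 256x256 px, 10 s at 100 Hz (1000 frames).

        Samples the same physical anatomy at a 2x coarser axial pitch
        (3.9 um/px) so the full 11-interface, 50-um-layer retina still fits
        in 256 rows.
        """
        defaults = dict(
            frame_height=256,
            frame_width=256,
            axial_px_um=3.9,
            transverse_px_um=5.9,
            duration_s=10.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def full(cls, **overrides) -> "PhantomConfig":
        """Full-scale preset matching the acquisition defaults."""
        return cls(**overrides)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomOutput:
    """Everything :func:`make_phantom` knows about the data it generated."""

    video: BScanVideo
    clean_video: BScanVideo
    pulse: PulseTrace
    masks: RoiMaskSet
    base_frame: np.ndarray
    true_phase_per_frame: np.ndarray
    true_global_shifts: np.ndarray  # (n_frames, 2): (axial, transverse) px
    true_tilt_slopes: np.ndarray  # px of axial shift per A-scan index
    config: PhantomConfig = field(repr=False, default=None)


def _layer_geometry(config: PhantomConfig) -> dict:
    """Depth extents of each anatomical band; raises SizingError on overflow."""
    h = config.frame_height
    t_px = config.layer_thickness_um / config.axial_px_um
    retina_px = (config.n_interfaces - 1) * t_px
    curve_amp = config.curvature_amp_frac * h
    z0 = round(0.15 * h)  # top of retina (ILM) at the frame centre column
    z1f = z0 + retina_px  # retina/choroid boundary (Bruch's membrane)
    choroid_px = max(8, round(0.15 * h))
    bg_px = max(8, round(0.08 * h))
    sclera_bot = h - bg_px
    if sclera_bot - (z1f + choroid_px + 0.5 * curve_amp) < 8 or z0 - 0.5 * curve_amp < 2:
        raise SizingError(
            f"frame_height={h} px cannot hold {config.n_interfaces - 1} layers of "
            f"{config.layer_thickness_um} um at {config.axial_px_um} um/px plus "
            "vitreous/choroid/sclera/background bands"
        )
    return dict(
        z0=z0, z1f=z1f, t_px=t_px, curve_amp=curve_amp,
        choroid_px=choroid_px, sclera_bot=sclera_bot,
    )


def _curvature(config: PhantomConfig, geo: dict) -> np.ndarray:
    """Per-column axial offset of the layer stack (px): a smooth parabolic bowl.

    Mimics the curvature of the retina around the optic nerve head; it also
    gives the anatomy transverse structure, without which lateral image
    registration would be ill-posed (a frame of horizontal stripes carries no
    lateral information).
    """
    w = config.frame_width
    x = np.arange(w, dtype=float)
    half = max((w - 1) / 2.0, 1.0)
    return geo["curve_amp"] * (((x - half) / half) ** 2 - 0.5)


def make_clean_frame(
    config: PhantomConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, RoiMaskSet]:
    """Build the static noise-free anatomy frame and its ROI label image.

    Depth structure per column (top to bottom): vitreous (0),
    ``n_interfaces - 1`` alternating-contrast retinal layers each
    ``layer_thickness_um`` thick (first = RNFL, last = bright RPE), a
    textured choroid, homogeneous sclera, and a dark background strip at the
    bottom. The whole stack is offset per column by a smooth parabolic
    curvature. The choroid texture is a smoothed random field drawn from
    ``rng`` (seeded from the config when not given) and is the only
    stochastic element.
    """
    geo = _layer_geometry(config)
    h, w = config.frame_height, config.frame_width
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 11]))

    curve = _curvature(config, geo)
    z = np.arange(h, dtype=float)
    zf = z[:, None] - curve[None, :]  # depth in the flat (uncurved) stack

    z0, z1f, t_px = geo["z0"], geo["z1f"], geo["t_px"]
    n_layers = config.n_interfaces - 1
    choroid_bot = z1f + geo["choroid_px"]

    levels = np.array([_LAYER_LEVELS[k % 2] for k in range(n_layers)], dtype=float)
    levels[-1] = _RPE_LEVEL

    frame = np.full((h, w), _VITREOUS_LEVEL, dtype=np.float64)
    labels = np.full((h, w), PHANTOM_LABELMAP["vitreous"], dtype=np.uint8)

    in_retina = (zf >= z0) & (zf < z1f)
    layer_idx = np.clip(((zf - z0) // t_px).astype(int), 0, n_layers - 1)
    frame[in_retina] = levels[layer_idx[in_retina]]
    labels[in_retina] = PHANTOM_LABELMAP["retina"]
    labels[in_retina & (layer_idx == 0)] = PHANTOM_LABELMAP["rnfl"]
    labels[in_retina & (layer_idx == n_layers - 1)] = PHANTOM_LABELMAP["rpe"]

    in_choroid = (zf >= z1f) & (zf < choroid_bot)
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
    texture *= _CHOROID_TEXTURE_AMP / max(texture.std(), 1e-12)
    frame[in_choroid] = np.clip(_CHOROID_BASE + texture[in_choroid], 0.05, None)
    labels[in_choroid] = PHANTOM_LABELMAP["choroid"]

    # Vessel shadows: partial attenuation of everything below the inner
    # retinal surface at a few lateral positions, as large retinal vessels
    # cast in real B-scans. They localise the frame laterally; they stop at
    # the choroid/sclera boundary so the sclera stays strictly homogeneous.
    if config.n_vessels > 0 and config.vessel_shadow_depth > 0:
        x = np.arange(w, dtype=float)
        centers = rng.uniform(0.1 * w, 0.9 * w, size=config.n_vessels)
        width = max(2.0, w / 80.0)
        shadow = np.zeros(w)
        for xc in centers:
            shadow += np.exp(-0.5 * ((x - xc) / width) ** 2)
        atten = 1.0 - config.vessel_shadow_depth * np.clip(shadow, 0.0, 1.0)
        below_ilm = (zf >= z0) & (zf < choroid_bot)
        frame[below_ilm] *= np.broadcast_to(atten[None, :], frame.shape)[below_ilm]

    in_sclera = (zf >= choroid_bot) & (z[:, None] < geo["sclera_bot"])
    frame[in_sclera] = _SCLERA_LEVEL
    labels[in_sclera] = PHANTOM_LABELMAP["sclera"]

    in_bg = z[:, None] >= geo["sclera_bot"]
    frame[np.broadcast_to(in_bg, frame.shape)] = _BACKGROUND_LEVEL
    labels[np.broadcast_to(in_bg, frame.shape)] = PHANTOM_LABELMAP["background"]

    # Instrument PSF: the optical resolution (FWHM) limits how sharp any
    # interface can appear, so the ideal piecewise-constant anatomy is
    # blurred to the stated axial/transverse resolution.
    sigma_z = config.axial_res_um / config.axial_px_um / 2.355
    sigma_x = config.transverse_res_um / config.transverse_px_um / 2.355
    frame = ndimage.gaussian_filter(frame, sigma=(sigma_z, sigma_x))

    return frame.astype(np.float32), RoiMaskSet(labels, dict(PHANTOM_LABELMAP))


def pulse_waveform(t: np.ndarray, peak_times: np.ndarray, systole_frac: float = 0.4) -> np.ndarray:
    """Normalised cardiac waveform in [0, 1], peaking exactly at each peak time.

    A raised-cosine systolic bump of fractional width ``systole_frac`` is
    centred on every peak (so the bump straddles the end of one cycle and the
    start of the next); the waveform is 0 in mid-cycle diastole. Samples
    outside [first peak - half bump, last peak + half bump] evaluate the
    nearest cycle's bump, which decays to 0.
    """
    t = np.asarray(t, dtype=float)
    peaks = np.asarray(peak_times, dtype=float)
    if peaks.size == 0:
        return np.zeros_like(t)
    # Distance to the nearest peak, in seconds, then normalised by local period.
    idx = np.searchsorted(peaks, t)
    left = peaks[np.clip(idx - 1, 0, peaks.size - 1)]
    right = peaks[np.clip(idx, 0, peaks.size - 1)]
    dt = np.minimum(np.abs(t - left), np.abs(t - right))
    periods = np.diff(peaks)
    period = float(np.median(periods)) if periods.size else 1.0
    half_width = 0.5 * systole_frac * period
    w = np.where(dt < half_width, 0.5 * (1.0 + np.cos(np.pi * dt / half_width)), 0.0)
    return w


def make_pulse_trace(
    config: PhantomConfig, rng: np.random.Generator | None = None
) -> PulseTrace:
    """Generate the quasi-periodic pulse-oximeter trace with known peak times.

    Peaks start at ``first_peak_s`` and are spaced ``heart_period_s`` plus
    i.i.d. Gaussian per-cycle jitter; the trace spans the video duration plus
    ``trace_pad_s`` so the last video frames still fall inside a complete
    cycle. True peak times are stored on the returned trace.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 23]))
    t_end = config.duration_s + config.trace_pad_s
    peaks = [config.first_peak_s]
    while True:
        step = config.heart_period_s
        if config.period_jitter_sd_s > 0:
            step += rng.normal(0.0, config.period_jitter_sd_s)
        step = max(step, 0.25 * config.heart_period_s)
        nxt = peaks[-1] + step
        if nxt > t_end:
            break
        peaks.append(nxt)
    peaks = np.asarray(peaks)
    sample_times = np.arange(0.0, t_end + 0.5 / config.pulse_rate_hz, 1.0 / config.pulse_rate_hz)
    intensities = 0.1 + 0.85 * pulse_waveform(sample_times, peaks, config.systole_frac)
    return PulseTrace(sample_times, intensities, peak_times=peaks)


def _pulsation_profile(config: PhantomConfig, geo: dict) -> np.ndarray:
    """Depth profile g(z) in [0, 1] of the cardiac displacement.

    Equal to 1 at the retina/choroid boundary and decaying as a Gaussian of
    SD ``pulsation_sigma_frac * frame_height`` away from it, so the choroid
    and outer retina move with the pulse while the vitreous stays put.
    """
    z = np.arange(config.frame_height, dtype=float)
    sigma = config.pulsation_sigma_frac * config.frame_height
    return np.exp(-0.5 * ((z - geo["z1f"]) / sigma) ** 2)


def _warp_frame(
    base: np.ndarray,
    puls_px: float,
    profile: np.ndarray,
    dz: float,
    dx: float,
    tilt_slope: float,
) -> np.ndarray:
    """Apply pulsation + global translation + A-scan tilt by backward warp.

    The output frame is ``base`` with content displaced downward by
    ``puls_px * g(z) + dz + tilt_slope * x`` axially and by ``dx``
    transversally; linear interpolation, out-of-frame filled with 0.
    """
    h, w = base.shape
    zz, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    u_z = puls_px * profile[:, None] + dz + tilt_slope * xx
    coords = np.array([zz - u_z, xx - dx])
    return ndimage.map_coordinates(base, coords, order=1, mode="constant", cval=0.0)


def unwarp_frame(frame: np.ndarray, dz: float, dx: float, tilt_slope: float = 0.0) -> np.ndarray:
    """Invert the recorded global shift + tilt of a phantom frame.

    Used to check ground-truth consistency: applying the recorded
    ``true_global_shifts`` / ``true_tilt_slopes`` inversely to a noise-free
    frame recovers the reference frame up to interpolation error.
    """
    h, w = frame.shape
    zz, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    coords = np.array([zz + dz + tilt_slope * xx, xx + dx])
    return ndimage.map_coordinates(frame, coords, order=1, mode="constant", cval=0.0)


def make_phantom(config: PhantomConfig) -> PhantomOutput:
    """Generate a complete synthetic acquisition.

    Returns the speckled video, its noise-free counterpart, the synchronised
    pulse trace, ROI masks and the per-frame ground truth (cardiac phase,
    global shifts, tilt slopes). Deterministic given ``config.rng_seed``.
    """
    geo = _layer_geometry(config)
    ss = np.random.SeedSequence([config.rng_seed, 7])
    r_texture, r_pulse, r_jitter, r_speckle = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    base, masks = make_clean_frame(config, rng=r_texture)
    pulse = make_pulse_trace(config, rng=r_pulse)
    profile = _pulsation_profile(config, geo)

    n = config.n_frames
    timestamps = np.arange(n, dtype=float) / config.bscan_rate_hz
    w_t = pulse_waveform(timestamps, pulse.peak_times, config.systole_frac)

    peaks = pulse.peak_times
    idx = np.searchsorted(peaks, timestamps, side="right")
    phase = np.full(n, np.nan)
    inside = (idx >= 1) & (idx < peaks.size)
    k = idx[inside] - 1
    phase[inside] = (timestamps[inside] - peaks[k]) / (peaks[k + 1] - peaks[k])

    if config.jitter_sd_px > 0:
        shifts = r_jitter.normal(0.0, config.jitter_sd_px, size=(n, 2))
    else:
        shifts = np.zeros((n, 2))
    denom = max(config.frame_width - 1, 1)
    tilt_slopes = config.tilt_drift_px_per_frame * np.arange(n, dtype=float) / denom

    base64 = base.astype(np.float64)
    clean = np.empty((n, config.frame_height, config.frame_width), dtype=np.float32)
    static = (
        config.pulsation_amp_px == 0
        and config.jitter_sd_px == 0
        and config.tilt_drift_px_per_frame == 0
    )
    for i in range(n):
        if static:
            clean[i] = base
        else:
            clean[i] = _warp_frame(
                base64,
                config.pulsation_amp_px * w_t[i],
                profile,
                shifts[i, 0],
                shifts[i, 1],
                tilt_slopes[i],
            )

    if math.isinf(config.speckle_looks):
        noisy = clean.copy()
    else:
        L = config.speckle_looks
        noisy = np.empty_like(clean)
        for i in range(n):  # per-frame draw keeps peak memory at one frame
            s = r_speckle.gamma(L, 1.0 / L, size=clean[i].shape)
            noisy[i] = clean[i] * s.astype(np.float32)

    mk = dict(axial_px_um=config.axial_px_um, transverse_px_um=config.transverse_px_um)
    return PhantomOutput(
        video=BScanVideo(noisy, timestamps, **mk),
        clean_video=BScanVideo(clean, timestamps.copy(), **mk),
        pulse=pulse,
        masks=masks,
        base_frame=base,
        true_phase_per_frame=phase,
        true_global_shifts=shifts,
        true_tilt_slopes=tilt_slopes,
        config=config,
    )
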