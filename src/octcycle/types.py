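"""Core in-memory containers shared across the pipeline.

Axis convention (used everywhere in the package): axis 0 is axial (depth, z,
increasing downwards into the tissue), axis 1 is transverse (x, across
A-scans). A B-scan frame is a 2-D float array ``frame[z, x]``; an A-scan is a
single column ``frame[:, c]``. Indexing is 0-based. Metrics operate on linear
intensity as stored; no implicit log-compression is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, MaskError

__all__ = [
    "BScanVideo",
    "PulseTrace",
    "BinAssignment",
    "RoiMaskSet",
    "DisplacementField",
    "REGION_NAMES",
]

#: Canonical ROI names understood by the metrics modules.
REGION_NAMES = (
    "vitreous",
    "rnfl",
    "retina",
    "rpe",
    "choroid",
    "sclera",
    "background",
)


@dataclass
class BScanVideo:
    """An ordered stack of B-scan frames with per-frame timestamps.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, linear intensity.
    timestamps
        Acquisition time of each frame in seconds, strictly increasing.
    axial_px_um, transverse_px_um
        Physical pixel sizes in micrometres.
    intensity_scale
        Factor by which integer input data were divided on load (1.0 for
        float input); kept so outputs can be rescaled on write.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    axial_px_um: float = 1.95
    transverse_px_um: float = 5.9
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ConfigError(
                f"frames must be a 3-D (n, H, W) stack, got shape {self.frames.shape}"
            )
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ConfigError(
                "timestamps must have one entry per frame "
                f"({self.frames.shape[0]} frames, {self.timestamps.size} timestamps)"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ConfigError("timestamps must be strictly increasing")
        if self.axial_px_um <= 0 or self.transverse_px_um <= 0:
            raise ConfigError("pixel sizes must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]


@dataclass
class PulseTrace:
    """A sampled pulse-oximeter signal, optionally with detected peaks.

    ``peak_times`` is ``None`` until peak detection has run (or the trace was
    generated synthetically with known peaks).
    """

    sample_times: np.ndarray
    intensities: np.ndarray
    peak_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.sample_times.ndim != 1 or self.sample_times.shape != self.intensities.shape:
            raise ConfigError("sample_times and intensities must be matching 1-D arrays")
        if self.sample_times.size > 1 and not np.all(np.diff(self.sample_times) > 0):
            raise ConfigError("sample_times must be strictly increasing")
        if self.peak_times is not None:
            self.peak_times = np.asarray(self.peak_times, dtype=float)
            if self.peak_times.size > 1 and not np.all(np.diff(self.peak_times) > 0):
                raise ConfigError("peak_times must be strictly increasing")

    @property
    def sampling_interval_s(self) -> float:
        return float(np.median(np.diff(self.sample_times)))

    def with_peaks(self, peak_times: np.ndarray) -> "PulseTrace":
        return PulseTrace(self.sample_times, self.intensities, np.asarray(peak_times, float))


@dataclass
class BinAssignment:
    """Per-frame cardiac phase and bin index.

    ``phase`` is NaN and ``bin_index`` is -1 for frames outside any complete
    cardiac cycle (before the first or after the last detected peak).
    """

    n_bins: int
    phase: np.ndarray
    bin_index: np.ndarray

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")
        self.phase = np.asarray(self.phase, dtype=float)
        self.bin_index = np.asarray(self.bin_index, dtype=int)

    @property
    def assigned(self) -> np.ndarray:
        """Boolean mask of frames inside a complete cycle."""
        return self.bin_index >= 0

    def counts(self) -> np.ndarray:
        """Number of assigned frames per bin, shape ``(n_bins,)``."""
        return np.bincount(self.bin_index[self.assigned], minlength=self.n_bins)

    def frames_in_bin(self, b: int) -> np.ndarray:
        """Indices of frames assigned to bin ``b``, in acquisition order."""
        return np.nonzero(self.bin_index == b)[0]


@dataclass
class RoiMaskSet:
    """Labelled ROI masks sharing the frame grid.

    A single labelled image plus a name->label map. Labels are mutually
    exclusive by construction; the composite region ``"retina"`` is resolved
    as the union of the ``rnfl``, ``retina`` (inner layers) and ``rpe``
    labels when those are present, matching how the anatomical retina spans
    the RNFL through the RPE.
    """

    labels: np.ndarray
    labelmap: dict[str, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise MaskError("labels must be a single-channel 2-D image")
        unknown = set(self.labelmap) - set(REGION_NAMES)
        if unknown:
            raise MaskError(f"unknown region name(s): {sorted(unknown)}")

    def has(self, name: str) -> bool:
        return name in self.labelmap

    def region(self, name: str) -> np.ndarray:
        """Boolean mask for a named region.

        Raises :class:`MaskError` if the region is absent or empty.
        """
        if name == "retina":
            parts = [n for n in ("rnfl", "retina", "rpe") if n in self.labelmap]
            if not parts:
                raise MaskError("no retina-related labels present")
            mask = np.zeros(self.labels.shape, dtype=bool)
            for n in parts:
                mask |= self.labels == self.labelmap[n]
        else:
            if name not in self.labelmap:
                raise MaskError(f"region {name!r} not present in mask set")
            mask = self.labels == self.labelmap[name]
        if not mask.any():
            raise MaskError(f"region {name!r} is empty")
        return mask


@dataclass
class DisplacementField:
    """Dense per-pixel 2-D displacement in pixels.

    ``u_axial[z, x]`` and ``u_transverse[z, x]`` give the displacement of the
    structure located at ``(z, x)`` in the reference image: a feature at
    ``(z, x)`` appears at ``(z + u_axial, x + u_transverse)`` in the warped
    image.
    """

    u_axial: np.ndarray
    u_transverse: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u_axial = np.asarray(self.u_axial, dtype=float)
        self.u_transverse = np.asarray(self.u_transverse, dtype=float)
        if self.u_axial.shape != self.u_transverse.shape or self.u_axial.ndim != 2:
            raise ConfigError("displacement components must be matching 2-D arrays")
        if not (np.all(np.isfinite(self.u_axial)) and np.all(np.isfinite(self.u_transverse))):
            raise ConfigError("displacement field must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u_axial.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_axial, self.u_transverse)

    def __neg__(self) -> "DisplacementField":
        return DisplacementField(-self.u_axial, -self.u_transverse)
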