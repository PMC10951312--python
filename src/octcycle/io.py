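"""File formats and run configuration.

On-disk conventions:

* videos — multi-page single-channel TIFF (float32, or integer data promoted
  to float on read with the scale factor recorded), with a mandatory
  timestamps sidecar CSV (``frame_index,timestamp_s``);
* pulse traces — CSV with columns ``time_s,intensity``;
* ROI masks — single-page labelled TIFF plus a JSON map of region name to
  label value;
* bin assignments / registration reports — CSV;
* run configuration — one JSON document, round-tripping losslessly, with
  unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .denoise import DenoiseParams
from .errors import ConfigError, MaskError, VideoFormatError
from .metrics import LayerDetectParams
from .motion import DemonsParams, GaussianExpansionParams
from .phantom import PhantomConfig
from .types import BScanVideo, PulseTrace, RoiMaskSet

__all__ = [
    "read_video",
    "write_video",
    "read_pulse",
    "write_pulse",
    "read_masks",
    "write_masks",
    "RunConfig",
    "config_hash",
    "write_manifest",
]


def _timestamps_path(video_path: Path) -> Path:
    return video_path.with_name(video_path.stem + "_timestamps.csv")


def write_video(
    path: str | Path,
    video: BScanVideo,
    timestamps_path: str | Path | None = None,
) -> Path:
    """Write frames as a multi-page float32 TIFF plus a timestamps CSV.

    Returns the path of the timestamps sidecar.
    """
    path = Path(path)
    tifffile.imwrite(path, np.asarray(video.frames, dtype=np.float32))
    ts = Path(timestamps_path) if timestamps_path else _timestamps_path(path)
    pd.DataFrame(
        {"frame_index": np.arange(video.n_frames), "timestamp_s": video.timestamps}
    ).to_csv(ts, index=False)
    return ts


def read_video(
    path: str | Path,
    timestamps_path: str | Path | None = None,
    axial_px_um: float = 1.95,
    transverse_px_um: float = 5.9,
) -> BScanVideo:
    """Read a multi-page TIFF video and its timestamps sidecar.

    Integer data are promoted to float in [0, 1] and the divisor recorded as
    ``intensity_scale``. Raises on mismatched page sizes or a missing
    sidecar.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) != 1:
            raise VideoFormatError(
                f"TIFF pages have mismatched sizes: {sorted(shapes)}"
            )
        frames = tf.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    scale = 1.0
    if np.issubdtype(frames.dtype, np.integer):
        scale = float(np.iinfo(frames.dtype).max)
        frames = frames.astype(np.float32) / scale
    else:
        frames = frames.astype(np.float32)

    ts = Path(timestamps_path) if timestamps_path else _timestamps_path(path)
    if not ts.exists():
        raise VideoFormatError(
            f"missing timestamps sidecar {ts.name!r} next to {path.name!r}"
        )
    table = pd.read_csv(ts)
    if "timestamp_s" not in table.columns:
        raise VideoFormatError(f"{ts} lacks a 'timestamp_s' column")
    timestamps = table.sort_values("frame_index")["timestamp_s"].to_numpy()
    if timestamps.size != frames.shape[0]:
        raise VideoFormatError(
            f"{timestamps.size} timestamps for {frames.shape[0]} frames"
        )
    return BScanVideo(
        frames, timestamps, axial_px_um, transverse_px_um, intensity_scale=scale
    )


def write_pulse(path: str | Path, trace: PulseTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.sample_times, "intensity": trace.intensities}
    ).to_csv(path, index=False)


def read_pulse(path: str | Path) -> PulseTrace:
    table = pd.read_csv(path)
    for col in ("time_s", "intensity"):
        if col not in table.columns:
            raise VideoFormatError(f"{path} lacks a {col!r} column")
    return PulseTrace(table["time_s"].to_numpy(), table["intensity"].to_numpy())


def write_masks(path: str | Path, masks: RoiMaskSet, labels_path: str | Path) -> None:
    tifffile.imwrite(Path(path), masks.labels.astype(np.uint8))
    Path(labels_path).write_text(json.dumps(masks.labelmap, indent=2))


def read_masks(path: str | Path, labels_path: str | Path) -> RoiMaskSet:
    """Read a labelled-mask TIFF and its JSON label map."""
    labels = tifffile.imread(Path(path))
    if labels.ndim != 2:
        raise MaskError("mask TIFF must be a single-page single-channel image")
    labelmap = {str(k): int(v) for k, v in json.loads(Path(labels_path).read_text()).items()}
    return RoiMaskSet(labels, labelmap)


# ---------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameter groups plus the run seed, as one document."""

    seed: int = 0
    verbosity: str = "info"
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    denoise: DenoiseParams = dataclasses.field(default_factory=DenoiseParams)
    layers: LayerDetectParams = dataclasses.field(default_factory=LayerDetectParams)
    expansion: GaussianExpansionParams = dataclasses.field(
        default_factory=GaussianExpansionParams
    )
    demons: DemonsParams = dataclasses.field(default_factory=DemonsParams)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        groups = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(groups)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, value in data.items():
            f = groups[name]
            if dataclasses.is_dataclass(f.type) or name in (
                "phantom", "denoise", "layers", "expansion", "demons",
            ):
                sub_cls = cls.__dataclass_fields__[name].default_factory
                sub_fields = {sf.name for sf in dataclasses.fields(sub_cls)}
                bad = set(value) - sub_fields
                if bad:
                    raise ConfigError(f"unknown key(s) in {name!r}: {sorted(bad)}")
                if name == "expansion" and value.get("center") is not None:
                    value = dict(value, center=tuple(value["center"]))
                if name == "demons" and value.get("scales") is not None:
                    value = dict(value, scales=tuple(value["scales"]))
                kwargs[name] = sub_cls(**value)
            else:
                kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the canonicalised config document."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(out_dir: str | Path, config: RunConfig, command: str) -> Path:
    """Write a reproducibility manifest next to the outputs of a CLI run."""
    import numpy
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(
        command=command,
        seed=config.seed,
        config_sha256=config_hash(config),
        config=config.to_dict(),
        versions=dict(
            octcycle=__version__, numpy=numpy.__version__, scipy=scipy.__version__
        ),
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
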