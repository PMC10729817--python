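"""Reading, writing and segmenting multi-plane time-series data.

A record is a directory of multi-page TIFFs (one file per rising-slope
z-stack, one page per focal plane, bottom-to-top in ascending z) plus a JSON
sidecar carrying the acquisition metadata, provenance and, for synthetic
data, the ground-truth log.  Round trips are lossless: pixel data are stored
as float32 and reread bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "MultiPlaneStack",
    "StackSeries",
    "SidecarError",
    "read_series",
    "write_series",
    "segment_rising_slopes",
]

logger = logging.getLogger(__name__)

SIDECAR_NAME = "series.json"
SIDECAR_VERSION = 1
REQUIRED_CONFIG_FIELDS = (
    "fps",
    "scan_hz",
    "scan_amplitude_um",
    "pixel_size_um",
    "frame_shape",
    "duration_s",
)


class SidecarError(ValueError):
    """Missing or malformed acquisition-metadata sidecar."""


@dataclass
class MultiPlaneStack:
    """One rising-slope z-stack: planes x height x width, ascending z."""

    intensities: np.ndarray
    z_positions: np.ndarray
    t_start: float
    stack_index: int

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(f"stack {self.stack_index}: intensities must be 3-D")
        if len(self.z_positions) != self.intensities.shape[0]:
            raise ValueError(f"stack {self.stack_index}: one z position per plane required")
        if len(self.z_positions) > 1 and not np.all(np.diff(self.z_positions) > 0):
            raise ValueError(f"stack {self.stack_index}: z_positions must be strictly increasing")

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[0]


@dataclass
class StackSeries:
    """Time-ordered rising-slope stacks plus their acquisition config."""

    stacks: list[MultiPlaneStack]
    config: "object"  # phantom.AcquisitionConfig (kept duck-typed to avoid a cycle)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.stacks)

    @property
    def stack_times(self) -> np.ndarray:
        return np.array([s.t_start for s in self.stacks])


def _config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    d["frame_shape"] = list(d["frame_shape"])
    return d


def _config_from_dict(d: dict):
    from .phantom import AcquisitionConfig

    missing = [k for k in REQUIRED_CONFIG_FIELDS if k not in d]
    if missing:
        raise SidecarError(
            "sidecar is missing required acquisition fields: " + ", ".join(missing)
        )
    kwargs = dict(d)
    kwargs["frame_shape"] = tuple(kwargs["frame_shape"])
    return AcquisitionConfig(**kwargs)


def write_series(series: StackSeries, path: str | Path) -> Path:
    """Write a series to ``path``: stack_XXXX.tif files plus the sidecar."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        for stack in series.stacks:
            fname = path / f"stack_{stack.stack_index:04d}.tif"
            tifffile.imwrite(fname, np.asarray(stack.intensities, dtype=np.float32))
        sidecar = {
            "version": SIDECAR_VERSION,
            "config": _config_to_dict(series.config),
            "provenance": series.provenance,
            "stacks": [
                {
                    "file": f"stack_{s.stack_index:04d}.tif",
                    "stack_index": s.stack_index,
                    "t_start": s.t_start,
                    "z_positions": s.z_positions.tolist(),
                }
                for s in series.stacks
            ],
        }
        (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    except OSError as exc:
        raise OSError(f"failed writing series to {path}: {exc}") from exc
    return path


def read_series(path: str | Path) -> StackSeries:
    """Read a series directory written by :func:`write_series`."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise SidecarError(
            f"no sidecar {SIDECAR_NAME} in {path}; required fields: "
            + ", ".join(REQUIRED_CONFIG_FIELDS)
        )
    sidecar = json.loads(sidecar_path.read_text())
    config = _config_from_dict(sidecar["config"])
    stacks = []
    shape = None
    for entry in sidecar["stacks"]:
        data = tifffile.imread(path / entry["file"])
        if data.ndim == 2:
            data = data[None]
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(
                f"ragged series: stack {entry['stack_index']} has shape "
                f"{data.shape}, expected {shape}"
            )
        stacks.append(
            MultiPlaneStack(
                intensities=data,
                z_positions=np.asarray(entry["z_positions"]),
                t_start=entry["t_start"],
                stack_index=entry["stack_index"],
            )
        )
    return StackSeries(stacks=stacks, config=config, provenance=sidecar.get("provenance", {}))


def segment_rising_slopes(
    frames: np.ndarray,
    cfg,
    t0: float = 0.0,
    keep_falling: bool = False,
) -> StackSeries | tuple[StackSeries, list[MultiPlaneStack]]:
    """Partition a raw frame stream into rising-slope z-stacks.

    ``frames`` is a (n, H, W) stream sampled at ``cfg.fps`` starting at
    ``t0``; frame times are pushed through the triangular scan phase to
    decide rising vs falling.  Falling-slope frames are discarded by default
    (``keep_falling=True`` returns them as reversed, ascending-z stacks).  A
    trailing partial stack is dropped with a warning.
    """
    from .phantom import triangular_scan_z

    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n, height, width) stream")
    planes = cfg.planes_per_rising_slope
    period_frames = int(round(cfg.fps / cfg.scan_hz))
    if len(frames) < planes:
        warnings.warn(
            f"stream of {len(frames)} frames is shorter than one rising slope "
            f"({planes} frames); no stacks produced",
            stacklevel=2,
        )
        series = StackSeries(stacks=[], config=cfg, provenance={"segmented": True})
        return (series, []) if keep_falling else series

    rising: dict[int, dict[int, int]] = {}
    falling: dict[int, list[int]] = {}
    for i in range(len(frames)):
        t = t0 + i / cfg.fps
        z, phase_name, plane = triangular_scan_z(t, cfg)
        # half-tick tolerance absorbs rounding at cycle boundaries
        cycle = int(np.floor(t * cfg.scan_hz + 0.5 / period_frames))
        if phase_name == "rising":
            rising.setdefault(cycle, {})[plane] = i
        else:
            falling.setdefault(cycle, []).append(i)

    stacks = []
    dropped = 0
    for cycle in sorted(rising):
        idx = rising[cycle]
        if len(idx) != planes:
            dropped += len(idx)
            warnings.warn(
                f"dropping partial rising slope (cycle {cycle}, {len(idx)}/{planes} frames)",
                stacklevel=2,
            )
            continue
        order = [idx[p] for p in range(planes)]
        z_positions = np.array(
            [triangular_scan_z(t0 + i / cfg.fps, cfg)[0] for i in order]
        )
        stacks.append(
            MultiPlaneStack(
                intensities=frames[order],
                z_positions=z_positions,
                t_start=t0 + order[0] / cfg.fps,
                stack_index=len(stacks),
            )
        )

    n_rising = sum(len(v) for v in rising.values())
    n_falling = sum(len(v) for v in falling.values())
    assert n_rising + n_falling == len(frames)
    logger.info(
        "segmented %d frames: %d stacks, %d falling-slope frames, %d dropped",
        len(frames), len(stacks), n_falling, dropped,
    )
    series = StackSeries(stacks=stacks, config=cfg, provenance={"segmented": True, "t0": t0})
    if not keep_falling:
        return series
    falling_stacks = []
    for cycle in sorted(falling):
        idx = falling[cycle]
        if len(idx) != planes:
            continue
        order = idx[::-1]  # reversed: ascending z
        z_positions = np.array(
            [triangular_scan_z(t0 + i / cfg.fps, cfg)[0] for i in order]
        )
        falling_stacks.append(
            MultiPlaneStack(
                intensities=frames[order],
                z_positions=z_positions,
                t_start=t0 + min(order) / cfg.fps,
                stack_index=len(falling_stacks),
            )
        )
    return series, falling_stacks
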