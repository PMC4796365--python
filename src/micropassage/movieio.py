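"""Movie container and multi-page TIFF input/output.

Movies are stored as multi-page TIFFs with channels interleaved within each
time point (plane order t0c0, t0c1, t1c0, ...), plus a JSON sidecar holding
the channel map, pixel size and frame interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigError, FormatError

__all__ = ["Movie", "read_movie", "write_movie"]


@dataclass
class Movie:
    """Time-ordered multi-channel 2-D frames.

    frames : array of shape (time, channel, y, x)
    channel_map : role -> plane index, e.g. {"actin": 0, "dna": 1};
        optional roles: "lamina", "bead".
    """

    frames: np.ndarray
    channel_map: dict[str, int] = field(
        default_factory=lambda: {"actin": 0, "dna": 1})
    frame_interval_min: float = 2.0
    pixel_size_um: float = 0.325

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise FormatError("frames must have shape (time, channel, y, x)")
        if self.frame_interval_min <= 0 or self.pixel_size_um <= 0:
            raise ConfigError("frame interval and pixel size must be > 0")
        idx = sorted(self.channel_map.values())
        if idx != list(range(self.frames.shape[1])):
            raise ConfigError(
                f"channel_map indices {idx} do not enumerate the "
                f"{self.frames.shape[1]} channel planes")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]

    def channel(self, role: str) -> np.ndarray:
        """All frames of one channel role, shape (time, y, x)."""
        if role not in self.channel_map:
            raise ConfigError(f"movie has no {role!r} channel")
        return self.frames[:, self.channel_map[role]]

    def frame(self, t: int, role: str) -> np.ndarray:
        return self.channel(role)[t]


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as interleaved multi-page TIFF + JSON sidecar."""
    path = Path(path)
    t, c, ny, nx = movie.frames.shape
    planes = movie.frames.reshape(t * c, ny, nx)
    tifffile.imwrite(path, planes)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "channel_map": movie.channel_map,
        "frame_interval_min": movie.frame_interval_min,
        "pixel_size_um": movie.pixel_size_um,
    }, indent=2, sort_keys=True))
    return sidecar


def read_movie(path: str | Path, sidecar: str | Path | None = None) -> Movie:
    """Read a multi-page TIFF movie with its JSON sidecar.

    The plane count must be divisible by the sidecar's channel count; the
    sidecar must define channel_map, pixel_size_um and frame_interval_min.
    """
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(path.suffix + ".json")
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise ConfigError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("channel_map", "pixel_size_um", "frame_interval_min"):
        if key not in meta:
            raise ConfigError(f"sidecar lacks required key {key!r}")
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None]
    n_ch = len(meta["channel_map"])
    if planes.shape[0] % n_ch != 0:
        raise FormatError(
            f"plane count {planes.shape[0]} not divisible by channel "
            f"count {n_ch}")
    t = planes.shape[0] // n_ch
    frames = planes.reshape(t, n_ch, *planes.shape[1:])
    return Movie(frames=frames,
                 channel_map={k: int(v) for k, v in meta["channel_map"].items()},
                 frame_interval_min=float(meta["frame_interval_min"]),
                 pixel_size_um=float(meta["pixel_size_um"]))
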