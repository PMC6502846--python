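"""Time-lapse AFM movie container and TIFF + JSON sidecar I/O.

A movie is an ordered stack of height maps (nm) with the acquisition
metadata needed downstream: pixel size (nm/px), frame interval (s) and the
time offset of frame 0 relative to the moment C9 was added to the fluid
cell (the kinetic time origin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["MovieStack", "read_movie", "write_movie", "MovieFormatError"]

#: sidecar keys that must be present next to the TIFF
REQUIRED_METADATA = ("pixel_size_nm", "frame_interval_s", "time_offset_s")


class MovieFormatError(ValueError):
    """Raised when a movie on disk is missing metadata or malformed."""


@dataclass
class MovieStack:
    """Ordered stack of AFM height maps with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Height maps in nm.
    pixel_size : float
        Lateral sampling in nm per pixel.
    frame_interval : float
        Time between consecutive frames in s.
    time_offset : float
        Time of frame 0 relative to C9 addition, in s.
    meta : dict
        Free-form provenance (e.g. the generating configuration).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    time_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise MovieFormatError(
                f"frames must be (n_frames, rows, cols), got shape {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise MovieFormatError("frames contain non-finite heights")
        if self.pixel_size <= 0:
            raise MovieFormatError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise MovieFormatError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame (s, relative to C9 addition)."""
        return self.time_offset + self.frame_interval * np.arange(self.n_frames)

    @property
    def duration(self) -> float:
        """Total movie duration in s (first to last frame)."""
        return self.frame_interval * (self.n_frames - 1)

    def copy(self) -> "MovieStack":
        return replace(self, frames=self.frames.copy(), meta=dict(self.meta))

    def __len__(self) -> int:
        return self.n_frames


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(stack: MovieStack, path: str | Path, overwrite: bool = False) -> Path:
    """Write a movie as multi-frame float32 TIFF plus a JSON sidecar.

    Refuses to clobber existing files unless ``overwrite`` is set.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not overwrite and (path.exists() or sidecar.exists()):
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    payload = {
        "pixel_size_nm": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "time_offset_s": stack.time_offset,
        "n_frames": stack.n_frames,
        "meta": stack.meta,
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a movie written by :func:`write_movie`.

    Raises :class:`MovieFormatError` naming any missing sidecar key.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MovieFormatError(
            f"missing metadata sidecar {sidecar}; required keys: "
            + ", ".join(REQUIRED_METADATA)
        )
    payload = json.loads(sidecar.read_text())
    missing = [k for k in REQUIRED_METADATA if k not in payload]
    if missing:
        raise MovieFormatError(f"sidecar {sidecar} missing keys: {', '.join(missing)}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:  # single-frame movie
        frames = frames[None]
    if frames.ndim != 3:
        raise MovieFormatError(f"expected a 2D/3D TIFF stack, got ndim={frames.ndim}")
    return MovieStack(
        frames=np.asarray(frames, dtype=np.float32),
        pixel_size=float(payload["pixel_size_nm"]),
        frame_interval=float(payload["frame_interval_s"]),
        time_offset=float(payload["time_offset_s"]),
        meta=payload.get("meta", {}),
    )
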