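"""Time-lapse image stack container and on-disk format.

A recording is a multi-page grayscale TIFF (one page per frame) plus a JSON
sidecar holding the two acquisition numbers every downstream stage needs:
the pixel size in µm/px and the frame interval in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "write_stack", "read_stack"]


@dataclass
class ImageStack:
    """Ordered 2D intensity frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, ny, nx)
        Intensity frames in arbitrary units.  Stored as given (uint16 for
        rendered/recorded data, float for intermediate work).
    pixel_size_um : float
        Physical size of one pixel, µm/px.
    frame_interval_s : float
        Constant time between consecutive frames, seconds.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) array")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if not (self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_s


def write_stack(stack: ImageStack, tiff_path: str | Path,
                meta_path: str | Path | None = None) -> None:
    """Write a multi-page grayscale TIFF plus its JSON metadata sidecar.

    ``meta_path`` defaults to the TIFF path with a ``.json`` suffix.
    """
    tiff_path = Path(tiff_path)
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(tiff_path, frames, photometric="minisblack")
    if meta_path is None:
        meta_path = tiff_path.with_suffix(".json")
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "n_frames": int(stack.n_frames),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_stack(tiff_path: str | Path,
               meta_path: str | Path | None = None) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    tiff_path = Path(tiff_path)
    if meta_path is None:
        meta_path = tiff_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:  # single page
        frames = frames[None]
    return ImageStack(frames, float(meta["pixel_size_um"]),
                      float(meta["frame_interval_s"]))
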