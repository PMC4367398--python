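"""Preprocessing of registered RGB-D frames.

A potted plant photographed against a cluttered indoor background is
separated from that background purely by its distance to the camera: every
pixel whose depth reading falls inside a configurable window (default
0.8-1.5 m) is foreground, everything else -- including pixels with no depth
reading at all -- is background.  The foreground mask is then thinned to a
one-pixel-wide skeleton (Zhang's 2D thinning) on which line detection
operates.  Color is never consulted for masking, so the step is independent
of illumination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.morphology import skeletonize as _zhang_thin

from .errors import DimensionError

#: Kinect convention: a zero depth value means "no reading".
INVALID_DEPTH_MM = 0

DEFAULT_NEAR_MM = 800
DEFAULT_FAR_MM = 1500


@dataclass
class RGBDPair:
    """A registered depth/color frame.

    ``depth`` is a 2D integer array in millimetres with 0 marking an invalid
    reading; ``color`` is an (H, W, 3) uint8 array on the same pixel grid.
    """

    depth: np.ndarray
    color: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        self.color = np.asarray(self.color)
        if self.depth.ndim != 2 or self.color.ndim != 3 or self.color.shape[2] != 3:
            raise DimensionError(
                f"expected (H,W) depth and (H,W,3) color, got {self.depth.shape} "
                f"and {self.color.shape}"
            )
        if self.depth.shape != self.color.shape[:2]:
            raise DimensionError(
                f"depth {self.depth.shape} and color {self.color.shape[:2]} "
                "are not on the same pixel grid"
            )
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative millimetres")


@dataclass
class ForegroundMask:
    mask: np.ndarray
    near_mm: int
    far_mm: int


@dataclass
class SkeletonImage:
    skel: np.ndarray


def depth_mask(pair: RGBDPair, near_mm: int = DEFAULT_NEAR_MM,
               far_mm: int = DEFAULT_FAR_MM) -> ForegroundMask:
    """Foreground = valid depth readings inside the closed window [near, far]."""
    if not near_mm < far_mm:
        raise ValueError(f"need near_mm < far_mm, got [{near_mm}, {far_mm}]")
    d = pair.depth
    mask = (d != INVALID_DEPTH_MM) & (d >= near_mm) & (d <= far_mm)
    return ForegroundMask(mask=mask, near_mm=near_mm, far_mm=far_mm)


def skeletonize(mask: ForegroundMask | np.ndarray) -> SkeletonImage:
    """One-pixel-wide skeleton of the foreground (Zhang thinning).

    Fragmented masks are allowed; each connected component thins to a
    connected skeleton component.  Empty input yields an empty skeleton.
    Sensor-dropout holes inside the mask are left as-is (no in-fill).
    """
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, bool)
    if not m.any():
        return SkeletonImage(skel=np.zeros_like(m, dtype=bool))
    return SkeletonImage(skel=_zhang_thin(m))


# ---------------------------------------------------------------------------
# PNG I/O: depth is 16-bit single-channel (value = millimetres), color is
# 8-bit RGB, masks/skeletons are 8-bit 0/255.

def load_pair(depth_path, color_path, meta: dict | None = None) -> RGBDPair:
    depth = np.asarray(iio.imread(depth_path)).astype(np.int64)
    color = np.asarray(iio.imread(color_path))
    if color.ndim == 3 and color.shape[2] == 4:
        color = color[:, :, :3]
    return RGBDPair(depth=depth, color=color, meta=meta or {})


def save_depth(path, depth: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(depth, dtype=np.uint16))


def save_color(path, color: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(color, dtype=np.uint8))


def save_binary(path, binary: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(binary, bool) * np.uint8(255)))


def load_binary(path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 0
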