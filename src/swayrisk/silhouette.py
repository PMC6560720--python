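"""Silhouette extraction from depth video by background subtraction.

The background model is the per-pixel median depth over the leading
person-free frames.  A pixel is a foreground candidate when it returns a
valid depth at least ``threshold_mm`` closer to the camera than the
background; the silhouette is the largest 8-connected candidate
component.  Invalid (zero) depth pixels are never foreground.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .depth_io import DepthFrame, DepthSequence

__all__ = [
    "BackgroundModel",
    "SilhouetteMask",
    "build_background_model",
    "extract_silhouette",
    "extract_all",
    "write_mask_png",
]

DEFAULT_THRESHOLD_MM = 300.0

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel background depth (mm) with a validity flag per pixel."""

    grid: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.shape != self.valid.shape:
            raise ValueError("background grid and validity mask differ in shape")


@dataclass(frozen=True)
class SilhouetteMask:
    """Binary person mask for one frame."""

    mask: np.ndarray
    index: int

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def build_background_model(seq: DepthSequence) -> BackgroundModel:
    """Median depth over the leading background frames, ignoring invalid pixels.

    Pixels with no valid return in any background frame are flagged invalid
    and can never contribute foreground.
    """
    if seq.background_frames < 1:
        raise ValueError("sequence has no background frames to model from")
    stack = np.stack(
        [f.grid.astype(float) * seq.depth_scale_mm for f in seq.frames[: seq.background_frames]]
    )
    stack[stack == 0] = np.nan
    import warnings

    with warnings.catch_warnings():
        # pixels with no valid return in any background frame are all-NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        grid = np.nanmedian(stack, axis=0)
    valid = ~np.isnan(grid)
    grid = np.where(valid, grid, 0.0)
    return BackgroundModel(grid=grid, valid=valid)


def extract_silhouette(
    frame: DepthFrame,
    bg: BackgroundModel,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    depth_scale_mm: float = 1.0,
    opening_radius: int = 0,
) -> SilhouetteMask:
    """Largest 8-connected component of closer-than-background pixels.

    ``opening_radius`` > 0 applies a binary opening with a square
    structuring element of side ``2r+1`` to the candidate set before
    component selection (off by default).
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    if frame.grid.shape != bg.grid.shape:
        raise ValueError("frame and background dimensions differ")
    depth = frame.grid.astype(float) * depth_scale_mm
    candidates = (frame.grid > 0) & bg.valid & (depth <= bg.grid - threshold_mm)
    if opening_radius > 0:
        side = 2 * opening_radius + 1
        candidates = ndimage.binary_opening(candidates, structure=np.ones((side, side), bool))
    if not candidates.any():
        return SilhouetteMask(mask=candidates, index=frame.index)
    labels, n = ndimage.label(candidates, structure=_EIGHT_CONNECTED)
    if n == 1:
        return SilhouetteMask(mask=candidates, index=frame.index)
    sizes = ndimage.sum_labels(candidates, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return SilhouetteMask(mask=labels == keep, index=frame.index)


def extract_all(
    seq: DepthSequence,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    opening_radius: int = 0,
) -> list[SilhouetteMask]:
    """Background model + per-frame silhouettes for all non-background frames."""
    bg = build_background_model(seq)
    return [
        extract_silhouette(
            f, bg, threshold_mm=threshold_mm, depth_scale_mm=seq.depth_scale_mm,
            opening_radius=opening_radius,
        )
        for f in seq.person_frames()
    ]


def write_mask_png(mask: SilhouetteMask, path: str | Path) -> Path:
    """Export a mask as 8-bit PNG (0/255) for visual inspection."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out, (mask.mask.astype(np.uint8)) * 255)
    return out
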