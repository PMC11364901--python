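"""Tensor construction for the volumetric regression network.

Raw rotation videos and confocal z-stacks are converted into fixed-size
input/target tensors: the input is a stack of ROI-cropped, resized frames
sampled equispaced over one rotation period (default 100×100×10); the target
is the confocal stack cropped to one global ROI, resized and resampled in z
to the same depth.

Conventions: Otsu thresholding for binarization; a single dilation pass with
a radius-1 disk before component labeling; per-frame ROIs for videos (the
cell may drift) but one shared union ROI for confocal targets (slices must
stay co-registered); bilinear resizing; min-max normalization over the whole
output tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, morphology, transform

from .exceptions import DegenerateImageError, InsufficientFramesError, NoCellError
from .phantom import Image2D, RotationVideo

DEFAULT_SIDE = 100
DEFAULT_DEPTH = 10


@dataclass(frozen=True)
class Mask:
    """A binary H×W mask with values in {0, 1}."""

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if not np.isin(p, (0, 1)).all():
            raise ValueError("Mask values must be 0 or 1")
        object.__setattr__(self, "pixels", p.astype(np.uint8))


@dataclass(frozen=True)
class ROIStack:
    """Network input: ROI frames stacked over time, shape (side, side, depth)."""

    tensor: np.ndarray
    source_frame_indices: tuple[int, ...]

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=np.float64)
        if t.ndim != 3:
            raise ValueError("ROIStack tensor must be 3-D (H, W, D)")
        if t.shape[2] != len(self.source_frame_indices):
            raise ValueError("depth must match the number of source frames")
        if not np.all(np.isfinite(t)):
            raise ValueError("ROIStack requires finite values")
        if t.min() < -1e-9 or t.max() > 1 + 1e-9:
            raise ValueError("ROIStack values must lie in [0, 1]")
        object.__setattr__(self, "tensor", np.clip(t, 0.0, 1.0))

    @property
    def shape(self):
        return self.tensor.shape


@dataclass(frozen=True)
class VolumeStack:
    """A 3-D intensity volume as (H, W, Z), slices ordered bottom → top."""

    tensor: np.ndarray
    z_spacing: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=np.float64)
        if t.ndim != 3:
            raise ValueError("VolumeStack tensor must be 3-D (H, W, Z)")
        if not np.all(np.isfinite(t)):
            raise ValueError("VolumeStack requires finite values")
        object.__setattr__(self, "tensor", t)

    @property
    def shape(self):
        return self.tensor.shape


def binarize(image: Image2D | np.ndarray) -> Mask:
    """Otsu-threshold an image so the cell is foreground.

    Polarity is normalized against the image border: the background intensity
    is taken as the median of the border pixels, and foreground is the side
    of the Otsu threshold away from it (cells may be bright on dark or dark
    on bright).
    """
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    if px.max() == px.min():
        raise DegenerateImageError("constant image: threshold undefined")
    thr = filters.threshold_otsu(px)
    border = np.concatenate([px[0], px[-1], px[:, 0], px[:, -1]])
    if np.median(border) > thr:
        mask = px < thr
    else:
        mask = px > thr
    return Mask(mask.astype(np.uint8))


def _largest_component_bbox(mask: Mask) -> tuple[int, int, int, int]:
    """Bounding box (min_row, min_col, max_row, max_col) of the largest
    8-connected component after one radius-1 disk dilation."""
    dilated = morphology.dilation(mask.pixels.astype(bool), morphology.disk(1))
    labels = measure.label(dilated, connectivity=2)
    if labels.max() == 0:
        raise NoCellError("no foreground component found")
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    return largest.bbox


def extract_roi(image: Image2D | np.ndarray) -> Image2D:
    """Crop the bounding rectangle of the largest cell component.

    The mask is dilated once (radius-1 disk) before labeling, so the ROI
    carries a 1-pixel margin around the raw silhouette.
    """
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    r0, c0, r1, c1 = _largest_component_bbox(binarize(px))
    return Image2D(px[r0:r1, c0:c1])


def _minmax(t: np.ndarray) -> np.ndarray:
    lo, hi = t.min(), t.max()
    return (t - lo) / (hi - lo) if hi > lo else np.zeros_like(t)


def _resize(img: np.ndarray, side: int) -> np.ndarray:
    return transform.resize(img, (side, side), order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)


def period_sample_indices(period_frames: float, depth: int) -> tuple[int, ...]:
    """Nearest-integer indices of ``depth`` frames equispaced over one period,
    starting at frame 0 (endpoint excluded: frame ``period`` repeats frame 0)."""
    return tuple(int(round(k * period_frames / depth)) for k in range(depth))


def video_to_input_stack(
    video: RotationVideo,
    period_frames: float,
    depth: int = DEFAULT_DEPTH,
    side: int = DEFAULT_SIDE,
) -> ROIStack:
    """Build the network input tensor from one rotation period of a video.

    ``depth`` frames are sampled equispaced over the period starting at frame
    0; each is ROI-cropped (per-frame, tolerating drift), bilinearly resized
    to ``side``×``side`` and stacked along the third axis; the whole stack is
    then min-max normalized.
    """
    if period_frames < depth:
        raise ValueError("period_frames must be at least the stack depth")
    if len(video) < period_frames:
        raise InsufficientFramesError(
            f"video has {len(video)} frames; period is {period_frames}"
        )
    indices = period_sample_indices(period_frames, depth)
    planes = [_resize(extract_roi(video.frames[i]).pixels, side) for i in indices]
    tensor = _minmax(np.stack(planes, axis=-1))
    return ROIStack(tensor=tensor, source_frame_indices=indices)


def z_resample_indices(n_slices: int, depth: int) -> tuple[int, ...]:
    """Nearest-integer indices of ``depth`` equispaced slices spanning the
    full stack (both endpoints included)."""
    return tuple(int(round(v)) for v in np.linspace(0, n_slices - 1, depth))


def confocal_to_target_stack(
    slices: np.ndarray,
    depth: int = DEFAULT_DEPTH,
    side: int = DEFAULT_SIDE,
) -> VolumeStack:
    """Build the regression target tensor from raw confocal slices.

    One global bounding rectangle is computed from the union of per-slice
    masks so all z-slices stay co-registered; slices are cropped with that
    single window, resized to ``side``×``side``, resampled in z to ``depth``
    equispaced slices, and min-max normalized.  Input ``slices`` is (Z, H, W),
    bottom → top; the output tensor is (side, side, depth).
    """
    raw = np.asarray(slices, dtype=float)
    if raw.ndim != 3:
        raise ValueError("expected a (Z, H, W) slice array")
    if raw.shape[0] < depth:
        raise InsufficientFramesError(
            f"{raw.shape[0]} raw slices < target depth {depth}"
        )
    union = np.zeros(raw.shape[1:], dtype=bool)
    for s in raw:
        if s.max() > s.min():
            union |= binarize(s).pixels.astype(bool)
    if not union.any():
        raise NoCellError("union mask across slices is empty")
    r0, c0, r1, c1 = _largest_component_bbox(Mask(union.astype(np.uint8)))
    z_idx = z_resample_indices(raw.shape[0], depth)
    planes = [_resize(raw[z, r0:r1, c0:c1], side) for z in z_idx]
    tensor = _minmax(np.stack(planes, axis=-1))
    return VolumeStack(tensor=tensor, z_spacing=(raw.shape[0] - 1) / max(depth - 1, 1))
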