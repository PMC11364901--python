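"""Rotation-quality metrics for single-cell rotation videos.

A cell spinning steadily in an acoustic trap produces a periodic
frame-to-first-frame correlation series; its period gives the frames per
revolution, and per-revolution checks (feature-point angle deviation,
major-axis diameter) quantify off-axis wobble and shape consistency.

The correlation statistic is the Pearson coefficient between pixel
intensities, computed after each frame is re-centered on its binarized
centroid so translational drift does not masquerade as rotation-phase change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage import feature as skfeature
from skimage import measure, morphology, transform

from .exceptions import (
    AperiodicSignalError,
    DegenerateImageError,
    LostFeatureError,
    NoCellError,
)
from .phantom import Image2D, RotationVideo
from .preprocess import binarize

MATCH_SCORE_FLOOR = 0.5
PEAK_PROMINENCE_FRACTION = 0.1


@dataclass(frozen=True)
class StabilityReport:
    """Summary of rotation stability for one video."""

    corr_series: np.ndarray
    period_frames: float
    angle_deviations_deg: tuple[float, ...]
    diameters_px: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.corr_series, dtype=float)
        if abs(c[0] - 1.0) > 1e-9:
            raise ValueError("corr_series must start at exactly 1")
        if np.any(np.abs(c) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.period_frames < 2:
            raise ValueError("period_frames must be at least 2")


def _centroid(px: np.ndarray) -> tuple[float, float]:
    mask = binarize(px).pixels
    if mask.sum() == 0:
        raise NoCellError("empty mask: centroid undefined")
    r, c = ndimage.center_of_mass(mask)
    return float(r), float(c)


def _recenter(px: np.ndarray) -> np.ndarray:
    """Shift a frame so its binarized centroid sits at the image center."""
    r, c = _centroid(px)
    h, w = px.shape
    return ndimage.shift(px, ((h - 1) / 2 - r, (w - 1) / 2 - c), order=1,
                         mode="constant", cval=0.0, prefilter=False)


def correlation_series(video: RotationVideo) -> np.ndarray:
    """Pearson correlation of every frame against frame 0.

    Frames are centroid-registered before comparison.  Entry 0 is exactly 1;
    a constant frame raises, naming the offending index.
    """
    ref = None
    out = np.empty(len(video))
    for k, frame in enumerate(video.frames):
        px = frame.pixels
        if px.max() == px.min():
            raise DegenerateImageError(f"frame {k} is constant: correlation undefined")
        reg = _recenter(px)
        if k == 0:
            ref = reg - reg.mean()
            ref_norm = np.sqrt(np.sum(ref**2))
            out[0] = 1.0
            continue
        d = reg - reg.mean()
        denom = ref_norm * np.sqrt(np.sum(d**2))
        out[k] = float(np.sum(ref * d) / denom) if denom > 0 else np.nan
    return out


def _refine_peak(series: np.ndarray, i: int) -> float:
    """Sub-frame peak position by parabolic interpolation around index i."""
    if i <= 0 or i >= len(series) - 1:
        return float(i)
    y0, y1, y2 = series[i - 1], series[i], series[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i)
    return i + 0.5 * (y0 - y2) / denom


def estimate_period(
    corr_series: np.ndarray,
    height_tolerance: float = 0.25,
    octave_tolerance: float = 0.02,
) -> float:
    """Rotation period in frames from the correlation series.

    The period is the mean spacing between successive local maxima exceeding
    a prominence floor (10% of the series range), each refined to sub-frame
    precision by parabolic interpolation.  Frame 0 (correlation 1 by
    construction) anchors the first spacing.

    A nearly 2-fold-symmetric cell also produces correlation maxima at half
    revolutions, slightly below the full-revolution peaks.  Two guards
    remove this octave ambiguity: peaks more than ``height_tolerance`` of
    the range below the tallest peak are discarded outright, and if the
    surviving peak heights alternate low/high by more than
    ``octave_tolerance`` of the range, the spacing is doubled.
    """
    s = np.asarray(corr_series, dtype=float)
    if len(s) < 3:
        raise AperiodicSignalError("series too short for period estimation")
    rng_ = s.max() - s.min()
    prominence = PEAK_PROMINENCE_FRACTION * rng_
    peaks, _ = signal.find_peaks(s, prominence=prominence)
    if len(peaks) == 0:
        raise AperiodicSignalError("no interior correlation peak found")
    floor = s[peaks].max() - height_tolerance * rng_
    peaks = peaks[s[peaks] >= floor]
    heights = s[peaks]
    if len(heights) >= 3:
        odd, even = heights[0::2], heights[1::2]
        if len(even) and even.mean() - odd.mean() > octave_tolerance * rng_:
            # half-revolution echoes: keep only the full-revolution peaks
            # (they sit where the cell exactly realigns; the echoes may be
            # slightly displaced and would bias the mean spacing)
            peaks = peaks[1::2]
    refined = np.array([_refine_peak(s, int(p)) for p in peaks])
    anchors = np.concatenate([[0.0], refined])
    return float(np.mean(np.diff(anchors)))


def track_feature(
    video: RotationVideo,
    template_center: tuple[int, int],
    template_half: int,
    period_frames: float,
    n_revs: int,
) -> tuple[float, ...]:
    """Angle deviation of a tracked feature point after each full revolution.

    A square template around ``template_center`` (row, col) in frame 0 is
    located by normalized cross-correlation in the frames nearest k·period
    (k = 1..n_revs).  The deviation is the angle, at the cell centroid,
    between the frame-0 feature vector and the frame-k feature vector,
    reported as an absolute value in degrees.  A match score below 0.5 raises.
    """
    r0, c0 = template_center
    h = template_half
    frame0 = video.frames[0].pixels
    if not (h <= r0 < frame0.shape[0] - h and h <= c0 < frame0.shape[1] - h):
        raise ValueError("template window must lie inside frame 0")
    if round(n_revs * period_frames) > len(video) - 1:
        raise ValueError("video too short for the requested revolutions")
    template = frame0[r0 - h: r0 + h + 1, c0 - h: c0 + h + 1]
    cen0 = _centroid(frame0)
    v0 = np.array([r0 - cen0[0], c0 - cen0[1]])
    deviations = []
    for k in range(1, n_revs + 1):
        idx = int(round(k * period_frames))
        px = video.frames[idx].pixels
        resp = skfeature.match_template(px, template, pad_input=True)
        score = resp.max()
        if score < MATCH_SCORE_FLOOR:
            raise LostFeatureError(
                f"match score {score:.2f} below {MATCH_SCORE_FLOOR} at frame {idx}"
            )
        rk, ck = np.unravel_index(int(resp.argmax()), resp.shape)
        cenk = _centroid(px)
        vk = np.array([rk - cenk[0], ck - cenk[1]])
        dot = float(np.dot(v0, vk))
        cross = float(v0[0] * vk[1] - v0[1] * vk[0])
        dev = abs(np.degrees(np.arctan2(cross, dot)))
        deviations.append(float(dev))
    return tuple(deviations)


def measure_major_axis(image: Image2D | np.ndarray) -> float:
    """Major-axis diameter (px) of the largest cell component.

    The silhouette is binarized and dilated once, and an ellipse is fitted
    from second-order image moments; the returned value is the ellipse's
    major-axis length in pixels.
    """
    return _major_axis_region(image).axis_major_length


def measure_major_axis_detailed(image: Image2D | np.ndarray):
    """Major axis plus a circular-Hough consistency check.

    Returns ``(diameter_px, hough_diameter_px, low_confidence)``; the Hough
    diameter comes from the best-scoring circle in a radius band around the
    moments estimate, and ``low_confidence`` flags >10% disagreement (cells
    are rarely true circles, so this is advisory, not an error).
    """
    region = _major_axis_region(image)
    d = region.axis_major_length
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    edges = skfeature.canny(px, sigma=1.5)
    radii = np.arange(max(3, int(d / 2 * 0.6)), int(d / 2 * 1.4) + 1)
    hough = transform.hough_circle(edges, radii)
    _, _, _, best_r = transform.hough_circle_peaks(hough, radii, num_peaks=1)
    hough_d = float(2 * best_r[0]) if len(best_r) else float("nan")
    low_conf = not np.isfinite(hough_d) or abs(hough_d - d) / d > 0.10
    return float(d), hough_d, bool(low_conf)


def _major_axis_region(image):
    # dilation only bridges gaps for labeling; moments are taken on the
    # undilated mask so the fitted axis is not inflated by the margin
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    mask = binarize(px).pixels.astype(bool)
    dilated = morphology.dilation(mask, morphology.disk(1))
    labels = measure.label(dilated, connectivity=2)
    if labels.max() == 0:
        raise NoCellError("no component for axis measurement")
    largest = max(measure.regionprops(labels), key=lambda r: r.area)
    component = (labels == largest.label) & mask
    if not component.any():
        component = labels == largest.label
    props = measure.regionprops(component.astype(np.uint8))
    return props[0]


def stability_report(
    video: RotationVideo,
    template_center: tuple[int, int] | None = None,
    template_half: int = 6,
    n_revs: int | None = None,
) -> StabilityReport:
    """Full stability analysis of one rotation video.

    Computes the correlation series, estimates the period from it, measures
    the major-axis diameter at every revolution boundary (including frame 0),
    and — when a feature template is given — the per-revolution angle
    deviations of that feature.
    """
    series = correlation_series(video)
    period = estimate_period(series)
    max_revs = int((len(video) - 1) // period)
    if n_revs is None:
        n_revs = max_revs
    n_revs = min(n_revs, max_revs)
    diameters = tuple(
        measure_major_axis(video.frames[int(round(k * period))])
        for k in range(n_revs + 1)
    )
    deviations: tuple[float, ...] = ()
    if template_center is not None and n_revs >= 1:
        deviations = track_feature(video, template_center, template_half, period, n_revs)
    return StabilityReport(
        corr_series=series,
        period_frames=period,
        angle_deviations_deg=deviations,
        diameters_px=diameters,
    )
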