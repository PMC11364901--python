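"""Quantitative 3-D morphology of reconstructed cell volumes.

From a predicted (or ground-truth) volume this module derives:

* a gray-level co-occurrence matrix (GLCM) pooled over the 13 unique 3-D
  unit offsets, and the six standard texture scalars — contrast,
  correlation, energy, homogeneity, dissimilarity, entropy;
* grayscale intensity histograms (the density form doubles as the
  classifier's "grayscale distribution" feature vector);
* a triangular isosurface mesh via marching cubes; and
* pairwise Pearson cross-correlation matrices between reconstructions.

Feature formulas follow the common co-occurrence convention with
``homogeneity = Σ p / (1 + |i − j|)`` and base-2 entropy; both are
switchable.  GLCMs are computed inside an Otsu foreground mask by default so
that empty background does not flatten the texture statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, transform

from .exceptions import EmptyGLCMError, EmptySurfaceError, UndefinedStatisticError
from .preprocess import VolumeStack

#: the 13 unique unit directions at Chebyshev distance 1 (one per +/- pair)
OFFSETS_13 = tuple(
    off for off in itertools.product((0, 1, -1), repeat=3)
    if off != (0, 0, 0) and (off > (0, 0, 0))
)


def _vol(volume) -> np.ndarray:
    v = volume.tensor if isinstance(volume, VolumeStack) else np.asarray(volume)
    return np.asarray(v, dtype=float)


@dataclass(frozen=True)
class QuantizedVolume:
    """Integer-labelled volume; ``single_level`` flags a constant input."""

    labels: np.ndarray
    levels: int
    single_level: bool = False


@dataclass(frozen=True)
class GLCM:
    """Normalized co-occurrence matrix p(i, j) with its provenance."""

    matrix: np.ndarray
    levels: int
    offsets: tuple
    symmetric: bool

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.levels, self.levels):
            raise ValueError("GLCM must be levels x levels")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must be normalized to sum 1")


@dataclass(frozen=True)
class GLCMFeatures:
    """The six co-occurrence texture scalars.

    ``correlation`` is NaN with ``correlation_defined=False`` for a
    degenerate (single-level) matrix.
    """

    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    dissimilarity: float
    entropy: float
    correlation_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "contrast": self.contrast,
            "correlation": self.correlation,
            "energy": self.energy,
            "homogeneity": self.homogeneity,
            "dissimilarity": self.dissimilarity,
            "entropy": self.entropy,
        }

    FEATURE_NAMES = ("contrast", "correlation", "energy",
                     "homogeneity", "dissimilarity", "entropy")


@dataclass(frozen=True)
class Mesh:
    """Triangular surface mesh in voxel coordinates."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    def enclosed_volume(self) -> float:
        """Signed volume by summing tetrahedra against the origin."""
        v = self.vertices
        t = v[self.faces]  # (F, 3, 3)
        return float(abs(np.einsum("ij,ij->i", t[:, 0],
                                   np.cross(t[:, 1], t[:, 2])).sum()) / 6.0)

    def is_watertight(self) -> bool:
        """Every undirected edge is shared by exactly two faces."""
        edges = np.concatenate([
            self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]],
        ])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def quantize(volume, levels: int = 8) -> QuantizedVolume:
    """Uniformly bin a volume's [min, max] range into integer labels.

    Bins are half-open with the final bin closed, so the midpoint of a
    2-level range maps to the upper label.  A constant volume yields all-zero
    labels with the ``single_level`` flag set.
    """
    if levels < 2:
        raise ValueError("levels must be at least 2")
    v = _vol(volume)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return QuantizedVolume(np.zeros(v.shape, dtype=np.int64), levels, True)
    labels = np.floor((v - lo) / (hi - lo) * levels).astype(np.int64)
    np.clip(labels, 0, levels - 1, out=labels)
    return QuantizedVolume(labels, levels, False)


def glcm_3d(
    qvolume: QuantizedVolume | np.ndarray,
    levels: int | None = None,
    offsets=OFFSETS_13,
    symmetric: bool = True,
    mask: np.ndarray | None = None,
) -> GLCM:
    """Pooled 3-D co-occurrence matrix over the given voxel offsets.

    Pairs are counted whenever both voxels are in bounds (and inside ``mask``
    when given), pooled across offsets, symmetrized by adding the transpose,
    and normalized to sum 1.
    """
    if isinstance(qvolume, QuantizedVolume):
        labels, levels = qvolume.labels, qvolume.levels
    else:
        labels = np.asarray(qvolume)
        if levels is None:
            levels = int(labels.max()) + 1
    if labels.max() >= levels:
        raise ValueError("labels must be below `levels`")
    counts = np.zeros((levels, levels), dtype=np.float64)
    valid = np.ones(labels.shape, dtype=bool) if mask is None else mask.astype(bool)
    for dz, dy, dx in offsets:
        src = _offset_slice((dz, dy, dx), labels.shape, source=True)
        dst = _offset_slice((dz, dy, dx), labels.shape, source=False)
        a, b = labels[src], labels[dst]
        ok = valid[src] & valid[dst]
        if not ok.any():
            continue
        idx = a[ok].ravel() * levels + b[ok].ravel()
        counts += np.bincount(idx, minlength=levels * levels).reshape(levels, levels)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise EmptyGLCMError("no valid voxel pairs for the GLCM")
    return GLCM(counts / total, levels, tuple(offsets), symmetric)


def _offset_slice(offset, shape, source: bool):
    sl = []
    for d, s in zip(offset, shape):
        if d == 0:
            sl.append(slice(None))
        elif (d > 0) == source:
            sl.append(slice(0, s - abs(d)))
        else:
            sl.append(slice(abs(d), s))
    return tuple(sl)


def glcm_features(
    glcm: GLCM | np.ndarray,
    entropy_base: float = 2.0,
    homogeneity_form: str = "inverse_linear",
) -> GLCMFeatures:
    """The six texture scalars of a normalized GLCM.

    contrast       Σ p(i,j)·(i−j)²
    dissimilarity  Σ p(i,j)·|i−j|
    energy         Σ p(i,j)²
    homogeneity    Σ p(i,j)/(1+|i−j|)   (or 1/(1+(i−j)²) with ``inverse_square``)
    entropy        −Σ p·log p, base 2 by default, with 0·log 0 = 0
    correlation    Σ p(i,j)(i−μᵢ)(j−μⱼ)/(σᵢσⱼ); NaN + flag when σᵢσⱼ = 0
    """
    p = glcm.matrix if isinstance(glcm, GLCM) else np.asarray(glcm, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized before feature extraction")
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    diff = i - j
    contrast = float(np.sum(p * diff**2))
    dissimilarity = float(np.sum(p * np.abs(diff)))
    energy = float(np.sum(p**2))
    if homogeneity_form == "inverse_linear":
        homogeneity = float(np.sum(p / (1.0 + np.abs(diff))))
    elif homogeneity_form == "inverse_square":
        homogeneity = float(np.sum(p / (1.0 + diff**2)))
    else:
        raise ValueError(f"unknown homogeneity_form {homogeneity_form!r}")
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / math.log(entropy_base))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    denom = math.sqrt(var_i * var_j)
    if denom == 0:
        correlation, defined = float("nan"), False
    else:
        correlation = float(np.sum(p * (i - mu_i) * (j - mu_j)) / denom)
        defined = True
    return GLCMFeatures(contrast, correlation, energy, homogeneity,
                        dissimilarity, entropy, correlation_defined=defined)


def volume_glcm_features(
    volume,
    levels: int = 8,
    masked: bool = True,
    slice_wise: bool = False,
    slice_axis: int = 2,
    **feature_kwargs,
) -> GLCMFeatures:
    """Quantize → co-occur → featurize, inside the Otsu foreground by default.

    ``slice_wise`` restricts offsets to the in-plane directions (zero
    component along ``slice_axis``, the z axis of an (H, W, Z) stack) for
    workflows that treat the stack as independent sections; the default
    pools all 13 3-D directions.
    """
    v = _vol(volume)
    mask = None
    if masked and v.max() > v.min():
        mask = v > filters.threshold_otsu(v)
        if mask.sum() < 2:
            mask = None
    q = quantize(v, levels)
    offsets = OFFSETS_13
    if slice_wise:
        offsets = tuple(o for o in OFFSETS_13 if o[slice_axis] == 0)
    g = glcm_3d(q, offsets=offsets, mask=mask)
    return glcm_features(g, **feature_kwargs)


def grayscale_histogram(volume, bins: int = 256):
    """Counts and density over uniform bins spanning [0, 1].

    Returns ``(counts, density, bin_edges)``; counts sum to the voxel count
    and the density (counts / total) sums to 1.
    """
    if bins < 2:
        raise ValueError("bins must be at least 2")
    v = _vol(volume)
    counts, edges = np.histogram(v, bins=bins, range=(0.0, 1.0))
    density = counts / counts.sum() if counts.sum() else counts.astype(float)
    return counts, density, edges


def isosurface_mesh(volume, isovalue="auto") -> Mesh:
    """Marching-cubes surface of a volume at an isovalue.

    ``auto`` uses the Otsu threshold of the voxel intensities.  Vertices are
    in voxel coordinates; the volume is padded by one voxel of its minimum
    value so surfaces touching the boundary stay closed.
    """
    v = _vol(volume)
    if isovalue == "auto":
        if v.max() == v.min():
            raise EmptySurfaceError("constant volume: auto isovalue undefined")
        isovalue = float(filters.threshold_otsu(v))
    if not (v.min() < isovalue < v.max()):
        raise EmptySurfaceError(
            f"isovalue {isovalue} outside intensity range [{v.min()}, {v.max()}]"
        )
    padded = np.pad(v, 1, constant_values=float(v.min()))
    verts, faces, _, _ = measure.marching_cubes(padded, level=isovalue)
    return Mesh(vertices=verts - 1.0, faces=faces)


def cross_correlation_matrix(volumes) -> np.ndarray:
    """Pairwise Pearson correlation between flattened volumes.

    Volumes are resampled to the first volume's shape before comparison.
    The diagonal is 1; entries involving a constant volume are NaN (the
    undefined-correlation flag).
    """
    arrs = [_vol(v) for v in volumes]
    if len(arrs) < 2:
        raise ValueError("need at least two volumes")
    ref_shape = arrs[0].shape
    flat = []
    for a in arrs:
        if a.shape != ref_shape:
            a = transform.resize(a, ref_shape, order=1, mode="edge",
                                 anti_aliasing=False, preserve_range=True)
        flat.append(a.ravel())
    n = len(flat)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = flat[i] - flat[i].mean(), flat[j] - flat[j].mean()
            denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
            out[i, j] = out[j, i] = np.sum(a * b) / denom if denom > 0 else np.nan
    return out
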