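"""Statistical layer: dimensionality reduction, classification and drug
time-course analysis of morphometric features.

* PCA to three components on standardized features (the six co-occurrence
  scalars live on very different scales; without z-scoring, contrast
  dominates every component).
* Four-class SVM (linear kernel, C=1, one-vs-one) evaluated by leave-one-out
  cross-validation with a full confusion-matrix report — the small-sample
  regime this pipeline operates in makes LOO the natural estimator.
* Traditional image augmentation (flips, right-angle rotations, small affine
  jitter, additive noise) with per-output provenance.
* Time-course scoring of drug response: six-feature trajectories over
  timepoints, the per-feature coefficient of variation (CV, percent), and a
  paired t-test between two conditions' CV vectors, paired by feature
  (n = 6, df = 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from skimage import transform
from sklearn.model_selection import LeaveOneOut
from sklearn.svm import SVC

from .exceptions import UndefinedStatisticError
from .morphometrics import GLCMFeatures, volume_glcm_features
from .phantom import Image2D

FEATURE_NAMES = GLCMFeatures.FEATURE_NAMES


@dataclass(frozen=True)
class ConfusionReport:
    """Leave-one-out classification summary."""

    classes: tuple[str, ...]
    matrix: np.ndarray  # rows = true class, cols = predicted
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float

    def __post_init__(self):
        if self.matrix.shape != (len(self.classes),) * 2:
            raise ValueError("confusion matrix must be K x K")
        if not np.isclose(self.accuracy,
                          np.trace(self.matrix) / self.matrix.sum()):
            raise ValueError("accuracy must equal trace / total")


@dataclass(frozen=True)
class TimeCourseReport:
    """Feature trajectories over a drug exposure time course."""

    timepoints: tuple
    trajectories: dict[str, tuple[float, ...]]
    cv_per_feature: dict[str, float]
    test: tuple[float, float, int] | None = None  # (t, two-sided p, df)


def histogram_feature_table(volumes, labels, bins: int = 64) -> pd.DataFrame:
    """Build the grayscale-distribution feature table for classification.

    Each volume becomes one row of ``bins`` density-normalized histogram
    values over [0, 1] plus a ``label`` column — the feature vector the
    leave-one-out SVM consumes.
    """
    from .morphometrics import grayscale_histogram

    rows = []
    for vol in volumes:
        _, density, _ = grayscale_histogram(vol, bins=bins)
        rows.append(density)
    table = pd.DataFrame(rows, columns=[f"bin_{i}" for i in range(bins)])
    table["label"] = list(labels)
    return table


def pca_project(table: pd.DataFrame, k: int = 3, standardize: bool = True):
    """Project a feature table onto its top-k principal components.

    Columns are centered (and z-scored by default); the covariance
    eigendecomposition supplies loadings sorted by explained variance.
    Returns ``(scores, loadings, explained_variance_ratio)`` where
    ``loadings`` is (n_features, k) with orthonormal columns.
    """
    x = np.asarray(table.select_dtypes("number") if isinstance(table, pd.DataFrame)
                   else table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D table with at least two samples")
    if k > x.shape[1]:
        raise ValueError("k exceeds the number of features")
    xc = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    rank = np.linalg.matrix_rank(xc)
    if k > rank:
        raise ValueError(f"k={k} exceeds the data rank {rank}")
    # SVD of the centered matrix == eigendecomposition of the covariance
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (x.shape[0] - 1)
    ratio = var / var.sum()
    loadings = vt[:k].T
    scores = xc @ loadings
    return scores, loadings, ratio[:k]


def svm_loo_classify(
    table: pd.DataFrame,
    label_column: str = "label",
    C: float = 1.0,
) -> ConfusionReport:
    """Leave-one-out linear-SVM classification of a labelled feature table.

    Each sample is predicted by an SVC (linear kernel, one-vs-one, given C)
    trained on all remaining samples; predictions aggregate into a confusion
    matrix with per-class precision, recall, F1 and overall accuracy.
    """
    if label_column not in table.columns:
        raise ValueError(f"table must contain a {label_column!r} column")
    y = table[label_column].to_numpy()
    x = table.drop(columns=[label_column]).to_numpy(dtype=float)
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError(
            "leave-one-out needs >= 2 samples per class; "
            f"class {counts.idxmin()!r} has {counts.min()}"
        )
    idx = {c: i for i, c in enumerate(classes)}
    matrix = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for train_ix, test_ix in LeaveOneOut().split(x):
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
        clf.fit(x[train_ix], y[train_ix])
        pred = clf.predict(x[test_ix])[0]
        matrix[idx[y[test_ix][0]], idx[pred]] += 1
    precision, recall, f1 = {}, {}, {}
    for c in classes:
        i = idx[c]
        tp = matrix[i, i]
        p = tp / matrix[:, i].sum() if matrix[:, i].sum() else 0.0
        r = tp / matrix[i].sum() if matrix[i].sum() else 0.0
        precision[c], recall[c] = float(p), float(r)
        f1[c] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    accuracy = float(np.trace(matrix) / matrix.sum())
    return ConfusionReport(classes, matrix, precision, recall, f1, accuracy)


def augment_images(
    images: list[Image2D],
    n_out: int,
    seed: int,
    max_shift_px: float = 2.0,
    max_rotate_deg: float = 10.0,
    noise_sd: float = 0.01,
):
    """Traditional augmentation: flips, 90°-multiple rotations, small affine
    jitter and additive Gaussian noise.

    The first ``len(images)`` outputs are the originals unchanged; the rest
    are seeded random transforms of cyclically chosen sources.  Returns
    ``(augmented, provenance)`` where ``provenance[i]`` is the source index
    of output ``i``.
    """
    if n_out < len(images):
        raise ValueError("n_out must be at least the number of inputs")
    rng = np.random.default_rng(seed)
    out = list(images)
    provenance = list(range(len(images)))
    k = 0
    while len(out) < n_out:
        src = k % len(images)
        px = images[src].pixels.copy()
        if rng.random() < 0.5:
            px = px[:, ::-1]
        if rng.random() < 0.5:
            px = px[::-1, :]
        px = np.rot90(px, k=int(rng.integers(0, 4)))
        angle = rng.uniform(-max_rotate_deg, max_rotate_deg)
        shift = rng.uniform(-max_shift_px, max_shift_px, size=2)
        px = transform.rotate(px, angle, order=1, mode="edge")
        px = ndimage.shift(px, shift, order=1, mode="nearest", prefilter=False)
        if noise_sd > 0:
            px = px + rng.normal(0, noise_sd, size=px.shape)
        out.append(Image2D(np.clip(px, 0.0, 1.0)))
        provenance.append(src)
        k += 1
    return out, provenance


def coefficient_of_variation(series, population: bool = False) -> float:
    """CV in percent: 100 · SD / |mean| (sample SD with n−1 by default)."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("CV needs at least two observations")
    mean = x.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero-mean data")
    sd = x.std(ddof=0 if population else 1)
    return float(100.0 * sd / abs(mean))


def paired_t_test(a, b) -> tuple[float, float, int]:
    """Two-sided paired t-test on matched observations.

    Returns ``(t, p, df)`` with ``t`` signed per ``a − b`` and ``df = n − 1``.
    Zero-variance differences (including a == b elementwise) are degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired t-test needs equal-length 1-D samples, n >= 2")
    d = a - b
    if np.allclose(d, d[0]):
        raise UndefinedStatisticError("zero-variance paired differences")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), len(a) - 1


def time_course_report(
    volumes_by_time: dict,
    group_b: dict | None = None,
    levels: int = 8,
    **glcm_kwargs,
) -> TimeCourseReport:
    """Six-feature trajectories and CVs over a drug-exposure time course.

    Each timepoint's volume goes through the GLCM pipeline; CVs are computed
    per feature across timepoints.  When a second condition ``group_b`` is
    supplied, the two six-long CV vectors are compared with a paired t-test
    (paired by feature, df = 5).
    """
    if len(volumes_by_time) < 2:
        raise ValueError("need at least two timepoints")
    times = tuple(volumes_by_time.keys())
    feats = [volume_glcm_features(v, levels=levels, **glcm_kwargs)
             for v in volumes_by_time.values()]
    trajectories = {
        name: tuple(getattr(f, name) for f in feats) for name in FEATURE_NAMES
    }
    cvs = {name: coefficient_of_variation(vals)
           for name, vals in trajectories.items()}
    test = None
    if group_b is not None:
        other = time_course_report(group_b, levels=levels, **glcm_kwargs)
        a_vec = [cvs[n] for n in FEATURE_NAMES]
        b_vec = [other.cv_per_feature[n] for n in FEATURE_NAMES]
        test = paired_t_test(a_vec, b_vec)
    return TimeCourseReport(times, trajectories, cvs, test)
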