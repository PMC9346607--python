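"""Soil removal and species segmentation.

Vegetation is separated from soil by Otsu thresholding of a vegetation
index (NDVI by default) — the threshold maximizing between-class variance
over a 256-bin histogram, with an optional manual offset for fine-tuning.
Maize, barnyardgrass and velvetleaf are then separated by an RBF-kernel
support vector machine on per-pixel spectral features (the five band
reflectances) plus gray-level co-occurrence texture features (contrast,
homogeneity, energy, entropy at 1-pixel offset averaged over four
directions) computed on a window of the green band. Accuracy is assessed
with a confusion matrix on held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .indices import compute_index
from .raster import RasterGrid

__all__ = [
    "ConfusionReport",
    "otsu_threshold",
    "vegetation_mask",
    "texture_features",
    "TEXTURE_FEATURE_NAMES",
    "pixel_feature_table",
    "train_species_svm",
    "classify_species",
    "confusion",
]

TEXTURE_FEATURE_NAMES = ("glcm_contrast", "glcm_homogeneity", "glcm_energy", "glcm_entropy")

_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over a ``nbins``-bin histogram of the sample.

    Returns the bin-center threshold maximizing the between-class variance;
    ties break toward the lower threshold. Constant input raises.
    """
    values = np.asarray(values, float).ravel()
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty sample")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("constant input has no Otsu threshold")
    counts, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = counts.astype(np.float64) / counts.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        # between-class variance for threshold after bin t
        sigma_b = (mu_total * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # candidate thresholds are cut points after bin t; argmax takes the
    # first (lowest) maximizer, i.e. ties break toward the lower threshold
    t = int(np.argmax(sigma_b[:-1]))
    return float(centers[t])


def vegetation_mask(
    grid: RasterGrid, channel: str = "NDVI", manual_offset: float = 0.0
) -> np.ndarray:
    """Boolean vegetation mask: index > (Otsu threshold + manual offset).

    Nodata pixels are always excluded (False).
    """
    index = compute_index(grid, channel)
    vals = index.values[0]
    valid = ~np.isnan(vals)
    thr = otsu_threshold(vals[valid]) + manual_offset
    mask = np.zeros(vals.shape, dtype=bool)
    mask[valid] = vals[valid] > thr
    return mask


def texture_features(window: np.ndarray, levels: int = 256) -> np.ndarray:
    """GLCM texture features of a 2-D window (contrast, homogeneity,
    energy, entropy) at 1-pixel offset averaged over 4 directions.

    The window is quantized to ``levels`` gray levels over [0, 1]-scaled
    values before the co-occurrence matrix is built. Windows smaller than
    3x3 raise.
    """
    window = np.asarray(window, float)
    if window.ndim != 2 or min(window.shape) < 3:
        raise ValueError(f"texture window must be at least 3x3, got {window.shape}")
    finite = np.isfinite(window)
    w = np.where(finite, window, np.nanmin(window[finite]) if finite.any() else 0.0)
    lo, hi = float(w.min()), float(w.max())
    scaled = np.zeros_like(w) if hi == lo else (w - lo) / (hi - lo)
    q = np.minimum((scaled * levels).astype(np.int64), levels - 1).astype(np.uint8)
    glcm = graycomatrix(
        q, distances=[1], angles=list(_GLCM_ANGLES), levels=levels,
        symmetric=True, normed=True,
    )
    contrast = float(graycoprops(glcm, "contrast").mean())
    homogeneity = float(graycoprops(glcm, "homogeneity").mean())
    energy = float((graycoprops(glcm, "ASM")).mean())
    p = glcm[:, :, 0, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=(0, 1))
    entropy = float(ent.mean())
    return np.array([contrast, homogeneity, energy, entropy])


def pixel_feature_table(
    grid: RasterGrid,
    rows: np.ndarray,
    cols: np.ndarray,
    labels: np.ndarray | None = None,
    window: int = 5,
    levels: int = 64,
) -> pd.DataFrame:
    """Spectral + texture features for sampled pixels of a 5-band raster.

    For each (row, col) the five band reflectances and the GLCM features of
    a ``window`` x ``window`` green-band neighborhood (clipped at edges)
    are collected. ``levels`` caps the texture quantization — a small
    window cannot populate a full 8-bit co-occurrence matrix, so a coarser
    quantization is both faster and statistically saner. ``labels``
    optionally attaches a class label column.
    """
    rows = np.asarray(rows, int)
    cols = np.asarray(cols, int)
    if rows.shape != cols.shape:
        raise ValueError("rows and cols must have equal length")
    half = window // 2
    green = grid.band("G")
    nrow, ncol = grid.shape
    records = []
    for k, (r, c) in enumerate(zip(rows, cols)):
        rec = {role: float(grid.values[i, r, c]) for i, role in enumerate(grid.band_roles)}
        r0, r1 = max(0, r - half), min(nrow, r + half + 1)
        c0, c1 = max(0, c - half), min(ncol, c + half + 1)
        win = green[r0:r1, c0:c1]
        if min(win.shape) < 3:  # pad degenerate edge windows
            win = green[
                max(0, min(r0, nrow - 3)) : max(3, r1),
                max(0, min(c0, ncol - 3)) : max(3, c1),
            ]
        tex = texture_features(win, levels=levels)
        rec.update(dict(zip(TEXTURE_FEATURE_NAMES, tex)))
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    table.insert(0, "row", rows)
    table.insert(1, "col", cols)
    if labels is not None:
        table["label"] = np.asarray(labels)
    return table


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in table.columns if c not in ("row", "col", "label")]
    X = table[cols].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    return X


def train_species_svm(table: pd.DataFrame, seed: int = 0, C: float = 10.0,
                      gamma: str | float = "scale") -> Pipeline:
    """Fit the species classifier: standardized features into an RBF SVM.

    Requires at least two classes with at least five samples each.
    """
    if "label" not in table.columns:
        raise ValueError("training table needs a 'label' column")
    y = table["label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(f"need at least 2 classes to train, got {classes.tolist()}")
    small = classes[counts < 5]
    if small.size:
        raise ValueError(f"classes with fewer than 5 samples: {small.tolist()}")
    X = _feature_matrix(table)
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)),
        ]
    )
    model.fit(X, y)
    return model


def classify_species(model: Pipeline, table: pd.DataFrame) -> np.ndarray:
    """One predicted species label per feature-table row."""
    return model.predict(_feature_matrix(table))


@dataclass
class ConfusionReport:
    """Square confusion-count matrix with derived accuracy metrics."""

    matrix: pd.DataFrame  # rows = truth, cols = prediction
    overall_accuracy: float
    per_class: pd.DataFrame  # precision / recall per class

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())


def confusion(labels_true, labels_pred) -> ConfusionReport:
    """Confusion matrix, overall accuracy and per-class precision/recall."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError(
            f"length mismatch: {labels_true.shape} truth vs {labels_pred.shape} predictions"
        )
    classes = np.unique(np.concatenate([labels_true, labels_pred]))
    counts = _sk_confusion(labels_true, labels_pred, labels=classes)
    matrix = pd.DataFrame(counts, index=classes, columns=classes)
    total = counts.sum()
    accuracy = float(np.trace(counts) / total) if total else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.diag(counts) / counts.sum(axis=1)
        precision = np.diag(counts) / counts.sum(axis=0)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall}, index=classes
    )
    return ConfusionReport(matrix=matrix, overall_accuracy=accuracy, per_class=per_class)
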