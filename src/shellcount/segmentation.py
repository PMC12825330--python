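"""Sparse-annotation pixel classification of the transduced (reporter) volume.

Cytoplasmic reporter expression varies strongly from cell to cell, and the
illumination is ramped with imaging depth, so a single global intensity
threshold cannot separate dim transduced cells from background.  Instead, a
small set of user-annotated voxels (drawn in both dim and bright regions, at
several depths) trains a bagged-tree classifier on multiscale image features
(smoothed intensity, gradient magnitude, Laplacian).  The resulting per-voxel
transduction probability is thresholded at 0.5 and small objects are removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .volumes import BinaryMask, IntensityVolume, VoxelGeometry

__all__ = [
    "SparseAnnotation",
    "ProbabilityVolume",
    "denoise",
    "extract_features",
    "train_pixel_classifier",
    "predict_probability",
    "segment_transduced",
    "PixelClassifier",
    "annotation_from_csv",
    "annotation_from_paint_volume",
]

logger = logging.getLogger(__name__)

TRANSDUCED = 1
BACKGROUND = 0

DEFAULT_FEATURE_SCALES_UM = (0.5, 1.0)


@dataclass
class SparseAnnotation:
    """Hand-labelled training voxels for the pixel classifier.

    ``coordinates`` are (z, y, x) voxel indices; ``labels`` holds 1 for
    transduced and 0 for background.  Annotations are typically drawn on a
    few planes spanning the depth range (e.g. 25, 50 and 75 µm) in both dim
    and bright regions so the classifier sees the full intensity variation.
    """

    coordinates: np.ndarray  # (n, 3) int
    labels: np.ndarray  # (n,) int in {0, 1}
    plane_depths_um: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=np.intp))
        self.labels = np.asarray(self.labels, dtype=np.intp).ravel()
        if self.coordinates.shape != (len(self.labels), 3):
            raise ValueError("coordinates must be (n, 3) matching n labels")
        present = set(np.unique(self.labels))
        if not present <= {BACKGROUND, TRANSDUCED}:
            raise ValueError(f"labels must be 0 (background) or 1 (transduced), got {present}")

    def validate(self, shape: tuple[int, int, int], min_per_class: int = 10) -> None:
        for axis in range(3):
            c = self.coordinates[:, axis]
            if c.size and (c.min() < 0 or c.max() >= shape[axis]):
                raise ValueError(f"annotation coordinates out of bounds on axis {axis}")
        for cls in (BACKGROUND, TRANSDUCED):
            n = int(np.sum(self.labels == cls))
            if n < min_per_class:
                raise ValueError(
                    f"need >= {min_per_class} annotated voxels per class, "
                    f"class {cls} has {n}"
                )


@dataclass
class ProbabilityVolume:
    """Per-voxel probability of belonging to the transduced volume."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("probability volume must be 3D (z, y, x)")
        if self.data.size and (self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")


def _sigmas_voxels(size_um: float, geometry: VoxelGeometry, clamp: bool = False):
    """Per-axis Gaussian sigma in voxels for an isotropic physical size in µm."""
    sigmas = np.array([size_um / s for s in geometry.spacing_zyx])
    if clamp and np.any(sigmas < 1.0):
        warnings.warn(
            f"feature scale {size_um} µm is below one voxel on some axis; clamping",
            stacklevel=3,
        )
        sigmas = np.maximum(sigmas, 1.0)
    return sigmas


def denoise(vol: IntensityVolume, gaussian_diameter_um: float = 0.829) -> IntensityVolume:
    """Gaussian denoising with a physical kernel size.

    ``gaussian_diameter_um`` is the kernel diameter; the per-axis sigma is
    ``(diameter / 2) / spacing`` voxels, so the smoothing is isotropic in
    physical space despite anisotropic voxels.
    """
    if gaussian_diameter_um <= 0:
        raise ValueError("gaussian diameter must be positive")
    sigmas = _sigmas_voxels(gaussian_diameter_um / 2.0, vol.geometry)
    out = ndimage.gaussian_filter(vol.data.astype(np.float32), sigma=sigmas)
    np.maximum(out, 0, out=out)
    return IntensityVolume(data=out, geometry=vol.geometry, channel_name=vol.channel_name)


def extract_features(
    vol: IntensityVolume, scales_um: tuple[float, ...] = DEFAULT_FEATURE_SCALES_UM
) -> np.ndarray:
    """Per-voxel feature stack: 3 features (smooth, |∇|, ∇²) per scale.

    Returns an array of shape ``vol.shape + (3 * len(scales_um),)`` in
    float32.  Gradient magnitude and Laplacian make the classifier sensitive
    to edges and blob shapes, not just absolute intensity.
    """
    if len(scales_um) < 1:
        raise ValueError("need at least one feature scale")
    data = vol.data.astype(np.float32)
    feats = np.empty(data.shape + (3 * len(scales_um),), dtype=np.float32)
    for i, scale in enumerate(scales_um):
        sigmas = _sigmas_voxels(scale, vol.geometry, clamp=True)
        feats[..., 3 * i] = ndimage.gaussian_filter(data, sigma=sigmas)
        feats[..., 3 * i + 1] = ndimage.gaussian_gradient_magnitude(data, sigma=sigmas)
        feats[..., 3 * i + 2] = ndimage.gaussian_laplace(data, sigma=sigmas)
    return feats


@dataclass
class PixelClassifier:
    """Trained probabilistic voxel classifier with its feature recipe."""

    model: RandomForestClassifier
    scales_um: tuple[float, ...]
    training_accuracy: float = float("nan")

    def predict_volume(self, features: np.ndarray, chunk_voxels: int = 2_000_000) -> np.ndarray:
        """Per-voxel transduction probability, predicted in chunks to bound memory."""
        shape = features.shape[:-1]
        flat = features.reshape(-1, features.shape[-1])
        out = np.empty(flat.shape[0], dtype=np.float32)
        cls_index = int(np.flatnonzero(self.model.classes_ == TRANSDUCED)[0])
        for start in range(0, flat.shape[0], chunk_voxels):
            sl = slice(start, start + chunk_voxels)
            out[sl] = self.model.predict_proba(flat[sl])[:, cls_index]
        return out.reshape(shape)


def train_pixel_classifier(
    features: np.ndarray,
    annotation: SparseAnnotation,
    seed: int = 0,
    n_estimators: int = 25,
    max_depth: int | None = 14,
    scales_um: tuple[float, ...] = DEFAULT_FEATURE_SCALES_UM,
) -> PixelClassifier:
    """Train a bagged-decision-tree voxel classifier on sparse annotations.

    The ensemble is seeded, so identical features + annotation + seed give a
    bit-reproducible model.  Requires at least 10 annotated voxels per class.
    """
    annotation.validate(features.shape[:-1])
    z, y, x = annotation.coordinates.T
    X = features[z, y, x]
    t = annotation.labels
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        min_samples_leaf=2,
        random_state=int(seed),
        n_jobs=1,
    )
    model.fit(X, t)
    acc = float(model.score(X, t))
    logger.info("pixel classifier trained on %d voxels, training accuracy %.3f", len(t), acc)
    return PixelClassifier(model=model, scales_um=tuple(scales_um), training_accuracy=acc)


def predict_probability(classifier: PixelClassifier, vol: IntensityVolume) -> ProbabilityVolume:
    """Convenience wrapper: features → classifier → ProbabilityVolume."""
    feats = extract_features(vol, classifier.scales_um)
    prob = classifier.predict_volume(feats)
    return ProbabilityVolume(data=prob, geometry=vol.geometry)


def segment_transduced(
    prob: ProbabilityVolume,
    geometry: VoxelGeometry | None = None,
    prob_threshold: float = 0.5,
    min_object_um3: float = 10.0,
) -> BinaryMask:
    """Threshold the probability volume and drop small objects.

    Voxels with probability >= ``prob_threshold`` are kept (probabilities
    *lower* than the threshold are excluded), then 26-connected components
    whose physical volume is not strictly larger than ``min_object_um3`` are
    removed.
    """
    if not (0.0 <= prob_threshold <= 1.0):
        raise ValueError("prob_threshold must lie in [0, 1]")
    if min_object_um3 < 0:
        raise ValueError("min_object_um3 must be non-negative")
    geometry = geometry or prob.geometry
    mask = prob.data >= prob_threshold
    mask = filter_small_objects(mask, geometry, min_object_um3)
    return BinaryMask(data=mask, geometry=geometry)


def filter_small_objects(
    mask: np.ndarray, geometry: VoxelGeometry, min_object_um3: float
) -> np.ndarray:
    """Remove 26-connected components with physical volume <= ``min_object_um3``."""
    if min_object_um3 == 0 or not mask.any():
        return mask.copy()
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    comp, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    counts = np.bincount(comp.ravel(), minlength=n + 1)
    volumes = counts * geometry.voxel_volume
    keep = volumes > min_object_um3  # strict: "larger than"
    keep[0] = False
    return keep[comp]


def annotation_from_csv(path, geometry: VoxelGeometry | None = None) -> SparseAnnotation:
    """Read annotations from CSV with columns z,y,x,label (label in {background,transduced} or {0,1})."""
    df = pd.read_csv(path)
    label_map = {"background": BACKGROUND, "transduced": TRANSDUCED, "0": 0, "1": 1}
    labels = np.array([label_map[str(v).strip().lower()] for v in df["label"]])
    coords = df[["z", "y", "x"]].to_numpy(dtype=np.intp)
    depths = ()
    if geometry is not None:
        depths = tuple(sorted(set(np.round(coords[:, 0] * geometry.dz, 3))))
    return SparseAnnotation(coordinates=coords, labels=labels, plane_depths_um=depths)


def annotation_from_paint_volume(
    paint: np.ndarray, geometry: VoxelGeometry | None = None
) -> SparseAnnotation:
    """Convert a paint-style uint8 volume (0 unlabeled, 1 background, 2 transduced)."""
    paint = np.asarray(paint)
    coords = np.argwhere(paint > 0)
    labels = np.where(paint[tuple(coords.T)] == 2, TRANSDUCED, BACKGROUND)
    depths = ()
    if geometry is not None:
        depths = tuple(sorted(set(np.round(np.unique(coords[:, 0]) * geometry.dz, 3))))
    return SparseAnnotation(coordinates=coords, labels=labels, plane_depths_um=depths)
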