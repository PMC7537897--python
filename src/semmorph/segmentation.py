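"""ROI extraction and unsupervised fuzzy segmentation.

Two stages mirror how the micrographs are analysed: first the background
is filtered away with a region-based (two-phase, piecewise-constant)
active contour, then the retained region of interest is partitioned into
intensity classes by fuzzy c-means (FCM) with graded per-pixel
memberships, optionally refined progressively by re-clustering the
ambiguous stratum.

Everything here is deterministic: the active contour is the morphological
Chan-Vese evolution from a fixed (Otsu) initialization, and FCM centers
start at evenly spaced quantiles of the ROI feature distribution, so no
seeds are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import morphological_chan_vese

from .image import CalibratedImage

__all__ = [
    "ROI",
    "FuzzyLabeling",
    "DegenerateFeatureError",
    "EmptyROIError",
    "active_contour_roi",
    "fuzzy_cluster_segment",
    "progressive_refine",
    "wavelet_detail_energy",
]

_ZERO_DIST = 1e-24


class DegenerateFeatureError(ValueError):
    """Fewer distinct feature values than requested classes."""


class EmptyROIError(ValueError):
    """The region of interest contains no pixels."""


@dataclass
class ROI:
    """Binary region of interest with provenance and warning flags."""

    mask: np.ndarray
    provenance: str = ""
    degenerate_contrast: bool = False
    empty: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        self.empty = not bool(self.mask.any())

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "ROI":
        return cls(np.ones(shape, dtype=bool), provenance="full-frame")


@dataclass
class FuzzyLabeling:
    """Per-pixel class memberships over K classes inside an ROI.

    ``memberships`` holds one row per ROI pixel (flattened row-major order
    of the True pixels of ``roi_mask``); each row sums to 1. Classes are
    sorted by ascending center intensity, and ``hard_labels`` is the
    per-pixel argmax (ties to the lower class index), -1 outside the ROI.
    """

    memberships: np.ndarray        # (N_roi, K)
    class_centers: np.ndarray      # (K, F)
    roi_mask: np.ndarray           # bool (H, W)
    hard_labels: np.ndarray        # int (H, W), -1 outside ROI
    iterations_run: int
    final_objective: float
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return self.class_centers.shape[0]

    def membership_images(self) -> np.ndarray:
        """(K, H, W) membership fields, 0 outside the ROI."""
        k = self.n_classes
        out = np.zeros((k,) + self.roi_mask.shape)
        for j in range(k):
            chan = np.zeros(self.roi_mask.shape)
            chan[self.roi_mask] = self.memberships[:, j]
            out[j] = chan
        return out


# ---------------------------------------------------------------------------
# Active contour
# ---------------------------------------------------------------------------


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = float(np.logical_and(a, b).sum())
    denom = float(a.sum() + b.sum())
    return 2 * inter / denom if denom else 1.0


def active_contour_roi(
    image: CalibratedImage,
    init: ROI | str = "otsu",
    max_iter: int = 200,
    smoothing: int = 1,
) -> ROI:
    """Region-based (two-phase piecewise-constant) background filtering.

    Evolves the morphological Chan-Vese contour from an Otsu-threshold
    initialization (or a caller-supplied mask) and returns the phase that
    best agrees with the initialization as foreground. On a zero-contrast
    image the initialization is returned unchanged with a
    ``degenerate_contrast`` warning flag.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    px = image.pixels
    if isinstance(init, ROI):
        if init.mask.shape != px.shape:
            raise ValueError("init mask shape does not match image")
        init_mask = init.mask
    elif init == "otsu":
        init_mask = None  # set below once contrast is known
    else:
        raise ValueError("init must be an ROI or 'otsu'")

    if float(px.max() - px.min()) < 1e-9:
        mask = init_mask if init_mask is not None else np.zeros(px.shape, bool)
        return ROI(mask, provenance="active_contour(degenerate)",
                   degenerate_contrast=True)

    if init_mask is None:
        init_mask = px > threshold_otsu(px)

    ls = morphological_chan_vese(
        px, num_iter=max_iter, init_level_set=init_mask.astype(np.int8),
        smoothing=smoothing,
    )
    phase1 = ls.astype(bool)
    fg = phase1 if _dice(phase1, init_mask) >= _dice(~phase1, init_mask) else ~phase1
    return ROI(fg, provenance=f"active_contour(iter={max_iter},smooth={smoothing})")


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def wavelet_detail_energy(pixels: np.ndarray, family: str = "db4",
                          smooth_px: float = 1.0) -> np.ndarray:
    """Per-pixel local energy of the level-1 wavelet detail.

    Reconstructs the image with the approximation band zeroed and returns
    the smoothed squared detail — a cheap texture channel that separates
    filamentous interiors from flat background at the same intensity.
    """
    h, w = pixels.shape
    ca, details = pywt.dwt2(pixels, family, mode="symmetric")
    detail_img = pywt.idwt2((np.zeros_like(ca), details), family,
                            mode="symmetric")[:h, :w]
    return ndimage.gaussian_filter(detail_img**2, smooth_px)


def _feature_images(image: CalibratedImage, features: str) -> np.ndarray:
    """(H, W, F) per-pixel feature stack."""
    if features == "intensity":
        return image.pixels[:, :, None]
    if features == "intensity+wavelet":
        return np.dstack([image.pixels, wavelet_detail_energy(image.pixels)])
    raise ValueError("features must be 'intensity' or 'intensity+wavelet'")


def _feature_matrix(image: CalibratedImage, roi_mask: np.ndarray,
                    features: str) -> np.ndarray:
    return _feature_images(image, features)[roi_mask]


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Optimal memberships for squared distances d2 (N, K)."""
    zero = d2 <= _ZERO_DIST
    u = np.where(zero, 1.0, d2) ** (-1.0 / (m - 1.0))
    u[zero.any(axis=1)] = 0.0
    u[zero] = 1.0
    # rows with a zero distance: uniform over the coincident centers
    rs = u.sum(axis=1, keepdims=True)
    return u / rs


def _fcm_iterate(X: np.ndarray, centers: np.ndarray, m: float, tol: float,
                 max_iter: int):
    """Alternating FCM minimization; returns (u, centers, trace, iters)."""
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = _fcm_memberships(d2, m)
        # objective J(u_t, c_{t-1}): each half-step minimizes J, so this
        # recorded sequence is non-increasing.
        trace.append(float((u**m * d2).sum()))
        um = u**m
        denom = um.sum(axis=0)[:, None]
        new_centers = np.where(denom > 0, um.T @ X / np.where(denom == 0, 1, denom),
                               centers)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    u = _fcm_memberships(d2, m)
    return u, centers, trace, it


def _quantile_init(X: np.ndarray, k: int) -> np.ndarray:
    qs = (np.arange(k) + 0.5) / k
    return np.quantile(X, qs, axis=0)


def fuzzy_cluster_segment(
    image: CalibratedImage,
    roi: ROI,
    n_classes: int = 2,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    features: str = "intensity",
) -> FuzzyLabeling:
    """Partition the ROI into ``n_classes`` fuzzy intensity classes.

    Minimizes the classical weighted within-class objective
    sum_ik u_ik^m ||x_i - c_k||^2 by alternating membership and center
    updates from a deterministic quantile initialization; stops when the
    largest center displacement falls below ``tol``. Classes come back
    sorted by ascending center intensity.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not fuzziness > 1:
        raise ValueError("fuzziness must be > 1")
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if roi.mask.shape != image.shape:
        raise ValueError("ROI shape does not match image")
    if roi.empty or not roi.mask.any():
        raise EmptyROIError("cannot cluster an empty ROI")

    X = _feature_matrix(image, roi.mask, features)
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_classes > n_distinct:
        raise DegenerateFeatureError(
            f"n_classes={n_classes} exceeds {n_distinct} distinct feature values"
        )

    centers = _quantile_init(X, n_classes)
    u, centers, trace, iters = _fcm_iterate(X, centers, fuzziness, tol, max_iter)

    order = np.argsort(centers[:, 0], kind="stable")
    centers = centers[order]
    u = u[:, order]

    hard = np.full(image.shape, -1, dtype=np.int32)
    hard[roi.mask] = np.argmax(u, axis=1)  # argmax ties -> lower index
    return FuzzyLabeling(
        memberships=u,
        class_centers=centers,
        roi_mask=roi.mask.copy(),
        hard_labels=hard,
        iterations_run=iters,
        final_objective=trace[-1] if trace else 0.0,
        objective_trace=trace,
    )


def progressive_refine(
    labeling: FuzzyLabeling,
    image: CalibratedImage,
    ambiguity_threshold: float = 0.8,
    max_rounds: int = 1,
    fuzziness: float = 2.0,
) -> FuzzyLabeling:
    """Resolve the ambiguous stratum using local spatial context.

    A pixel whose top membership falls below ``ambiguity_threshold`` sits
    between class centers, where intensity alone cannot decide; its
    membership is recomputed against the (fixed) class centers from its
    neighbourhood-averaged features, so isolated noisy pixels inherit the
    class of their surroundings. The averaging window grows by one ring
    per round (3x3, then 5x5, ...). With no ambiguous pixels, or
    ``max_rounds=0``, the labeling is returned unchanged.
    """
    if not (0.0 < ambiguity_threshold < 1.0):
        raise ValueError("ambiguity_threshold must be in (0, 1)")
    if max_rounds < 0:
        raise ValueError("max_rounds must be >= 0")

    u = labeling.memberships.copy()
    centers = labeling.class_centers
    features = "intensity" if centers.shape[1] == 1 else "intensity+wavelet"
    feats = _feature_images(image, features)
    iters = labeling.iterations_run

    for round_idx in range(max_rounds):
        ambiguous = u.max(axis=1) < ambiguity_threshold
        if not ambiguous.any():
            break
        size = 3 + 2 * round_idx
        smoothed = np.dstack([
            ndimage.uniform_filter(feats[:, :, f], size=size)
            for f in range(feats.shape[2])
        ])
        Xa = smoothed[labeling.roi_mask][ambiguous]
        d2 = ((Xa[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u[ambiguous] = _fcm_memberships(d2, fuzziness)
        iters += 1

    hard = np.full(image.shape, -1, dtype=np.int32)
    hard[labeling.roi_mask] = np.argmax(u, axis=1)
    X = _feature_matrix(image, labeling.roi_mask, features)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return FuzzyLabeling(
        memberships=u,
        class_centers=centers.copy(),
        roi_mask=labeling.roi_mask,
        hard_labels=hard,
        iterations_run=iters,
        final_objective=float((u**fuzziness * d2).sum()),
        objective_trace=list(labeling.objective_trace),
    )
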