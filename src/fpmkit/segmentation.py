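"""Binary-mask and object construction from the average-intensity image.

Two built-in schemes, both operating on the total-intensity map S0:

* ``puncta`` — for small, roughly isotropic structures (e.g. adhesion
  complexes near the diffraction limit): white top-hat background
  suppression, Gaussian smoothing, a global 256-bin Otsu threshold,
  optional hole filling, an area filter, and 8-connected labeling. Each
  connected component becomes one object.
* ``filaments`` — for extended linear structures: multiscale Hessian
  ridge enhancement, quantile thresholding, skeletonization, cutting the
  skeleton at junction pixels, branch-length pruning, and dilation of
  each branch into its object mask. Each skeleton branch becomes one
  object; dilated pixels are assigned to the nearest branch so labels
  stay disjoint.

Both schemes are intensity-scale invariant: all linear filters commute
with scaling and the Otsu / quantile thresholds are computed on the
image's own histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import morphology as skmorph
from skimage.filters import gaussian

__all__ = [
    "SegmentationResult",
    "PunctaParams",
    "FilamentParams",
    "otsu_threshold",
    "segment_puncta",
    "segment_filaments",
    "edit_mask",
]

#: 8-connectivity structuring element used for all labeling
EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    """A binary mask plus its integer object labels (0 = background)."""

    mask: np.ndarray
    labels: np.ndarray
    scheme: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask.shape != self.labels.shape:
            raise ValueError("mask and labels must share dimensions")
        if np.any((self.labels > 0) != self.mask):
            raise ValueError("labels must be nonzero exactly on the mask")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def object_ids(self) -> np.ndarray:
        return np.arange(1, self.n_objects + 1)


@dataclass
class PunctaParams:
    """Parameters of the puncta scheme (pixel units).

    Defaults suit diffraction-limited puncta at ~0.1 um/px: the top-hat
    radius comfortably exceeds the punctum radius, and the area floor
    rejects single-pixel noise islands.
    """

    tophat_radius: int = 8
    smooth_sigma: float = 1.0
    min_area: int = 10
    fill_holes: bool = True


@dataclass
class FilamentParams:
    """Parameters of the filaments scheme (pixel units)."""

    ridge_sigmas: Sequence[float] = (1.0, 2.0, 3.0)
    ridge_threshold: float = 0.98  # quantile of the enhanced image
    min_branch_length: int = 10
    dilation_radius: int = 2


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold on a 256-bin histogram of the sample.

    Returns the bin edge maximizing the between-class variance
    (equivalently, minimizing the weighted intra-class variance); a pixel
    is foreground when its value is >= the returned threshold. Ties are
    broken toward the lower threshold. Raises when all values are equal,
    because the histogram carries no class structure.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("otsu_threshold: empty sample")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise ValueError("otsu_threshold: all values equal, no threshold exists")
    counts, edges = np.histogram(v, bins=256, range=(vmin, vmax))
    counts = counts.astype(float)
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    sum0 = np.cumsum(counts * centers)[:-1]
    sum_all = float(np.sum(counts * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (sum_all - sum0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    t = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(edges[t + 1])


def _label8(mask: np.ndarray) -> np.ndarray:
    labels, _ = ndimage.label(mask, structure=EIGHT_CONN)
    return labels.astype(np.int32)


def segment_puncta(S0: np.ndarray, params: PunctaParams | None = None) -> SegmentationResult:
    """Segment punctate structures from the average-intensity image."""
    params = params or PunctaParams()
    img = np.asarray(S0, dtype=float)
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise ValueError("S0 must be finite and nonnegative")

    enhanced = skmorph.white_tophat(img, footprint=skmorph.disk(params.tophat_radius))
    if params.smooth_sigma > 0:
        enhanced = gaussian(enhanced, sigma=params.smooth_sigma, preserve_range=True)

    if enhanced.max() == enhanced.min():
        warnings.warn("constant image: empty segmentation", stacklevel=2)
        empty = np.zeros(img.shape, dtype=bool)
        return SegmentationResult(empty, np.zeros(img.shape, np.int32), "puncta", asdict(params))

    mask = enhanced >= otsu_threshold(enhanced)
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if params.min_area > 0:
        # drop components with area < min_area
        labels = _label8(mask)
        if labels.max():
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, labels.max() + 1))
            small = np.flatnonzero(sizes < params.min_area) + 1
            mask = mask & ~np.isin(labels, small)
    return SegmentationResult(mask, _label8(mask), "puncta", asdict(params))


def _ridge_response(img: np.ndarray, sigmas: Sequence[float]) -> np.ndarray:
    """Largest-magnitude bright-ridge response across scales.

    At each scale the Hessian is computed with Gaussian derivatives and
    scale-normalized by sigma^2; a bright ridge has a strongly negative
    principal eigenvalue, so the response is max(0, -lambda_min), and the
    final map takes the maximum over scales.
    """
    response = np.zeros_like(img, dtype=float)
    for sigma in sigmas:
        h_elems = skfeature.hessian_matrix(
            img, sigma=sigma, order="rc", use_gaussian_derivatives=True
        )
        eigvals = skfeature.hessian_matrix_eigvals(h_elems)
        ridge = np.maximum(-eigvals[-1], 0.0) * sigma**2
        response = np.maximum(response, ridge)
    return response


def _skeleton_branches(skeleton: np.ndarray, min_branch_length: int) -> np.ndarray:
    """Cut a skeleton at junction pixels and label surviving branches."""
    neighbor_count = ndimage.convolve(
        skeleton.astype(int), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]), mode="constant"
    )
    junctions = skeleton & (neighbor_count >= 3)
    branches = skeleton & ~junctions
    labels = _label8(branches)
    if labels.max():
        sizes = ndimage.sum_labels(branches, labels, index=np.arange(1, labels.max() + 1))
        keep = np.flatnonzero(sizes >= min_branch_length) + 1
        labels = np.where(np.isin(labels, keep), labels, 0)
        # compact to 1..K
        remap = {old: new for new, old in enumerate(sorted(np.unique(labels[labels > 0])), 1)}
        labels = np.vectorize(lambda v: remap.get(v, 0), otypes=[np.int32])(labels)
    return labels


def segment_filaments(
    S0: np.ndarray, params: FilamentParams | None = None
) -> SegmentationResult:
    """Segment linear, extended structures from the average-intensity image."""
    params = params or FilamentParams()
    img = np.asarray(S0, dtype=float)
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise ValueError("S0 must be finite and nonnegative")

    p = dict(
        ridge_sigmas=list(params.ridge_sigmas),
        ridge_threshold=params.ridge_threshold,
        min_branch_length=params.min_branch_length,
        dilation_radius=params.dilation_radius,
    )
    response = _ridge_response(img, params.ridge_sigmas)
    threshold = np.quantile(response, params.ridge_threshold)
    binary = response > threshold
    if not binary.any():
        warnings.warn("no ridges above threshold: empty segmentation", stacklevel=2)
        empty = np.zeros(img.shape, dtype=bool)
        return SegmentationResult(empty, np.zeros(img.shape, np.int32), "filaments", p)

    skeleton = skmorph.skeletonize(binary)
    branch_labels = _skeleton_branches(skeleton, params.min_branch_length)
    if branch_labels.max() == 0:
        warnings.warn("no branches survive pruning: empty segmentation", stacklevel=2)
        empty = np.zeros(img.shape, dtype=bool)
        return SegmentationResult(empty, np.zeros(img.shape, np.int32), "filaments", p)

    kept_skeleton = branch_labels > 0
    mask = ndimage.binary_dilation(kept_skeleton, skmorph.disk(params.dilation_radius))
    # assign each mask pixel to its nearest branch so labels never overlap
    _, (ir, ic) = ndimage.distance_transform_edt(~kept_skeleton, return_indices=True)
    labels = np.where(mask, branch_labels[ir, ic], 0).astype(np.int32)
    return SegmentationResult(mask, labels, "filaments", p)


def edit_mask(
    result: SegmentationResult,
    op: Literal["add-region", "remove-labels"],
    payload,
) -> SegmentationResult:
    """Programmatic mask editing; returns a new result, inputs untouched.

    * ``remove-labels`` — payload is an iterable of label ids; survivors
      are compacted to 1..K preserving order.
    * ``add-region`` — payload is a boolean raster OR-ed into the mask;
      objects are then rebuilt as 8-connected components, so a region
      bridging two objects merges them.
    """
    if op == "remove-labels":
        to_remove = set(int(v) for v in payload)
        present = set(range(1, result.n_objects + 1))
        unknown = to_remove - present
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        labels = np.where(np.isin(result.labels, sorted(to_remove)), 0, result.labels)
        survivors = [v for v in range(1, result.n_objects + 1) if v not in to_remove]
        remap = np.zeros(result.n_objects + 1, dtype=np.int32)
        for new, old in enumerate(survivors, 1):
            remap[old] = new
        labels = remap[labels]
        return SegmentationResult(labels > 0, labels, result.scheme, dict(result.params))
    if op == "add-region":
        region = np.asarray(payload, dtype=bool)
        if region.shape != result.mask.shape:
            raise ValueError("region dimensions do not match the mask")
        mask = result.mask | region
        return SegmentationResult(mask, _label8(mask), result.scheme, dict(result.params))
    raise ValueError(f"unknown edit operation {op!r}")
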