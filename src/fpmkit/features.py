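"""Per-object morphological, intensity and polarization features.

Each segmented object carries:

* morphology — area (pixel count), perimeter and eccentricity from
  standard region properties of the 8-connected mask, and midline arc
  length L in micrometres;
* intensity — mean S0 over the object, and the local signal-to-
  background ratio S/B measured against an annulus surrounding the
  object (all object pixels in the image are excluded from the
  background estimate so neighbours do not contaminate it);
* polarization — mean order p_bar (arithmetic mean over pixels where
  the order is defined), the axial circular mean azimuth in the image
  frame (alpha_image) and relative to the midline (alpha_midline), and
  the azimuthal disorder s0 (axial circular standard deviation), all in
  degrees on [0, 180).

Angle features use only pixels whose azimuth is defined; objects without
enough such pixels (or without a valid midline) carry NaN for the
corresponding features rather than a guessed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .circular import axial_mean, axial_std
from .core import FPMStack
from .midline import Midline, MidlineParams, assign_tangents, compute_midline, relative_azimuth
from .segmentation import SegmentationResult
from .stats import PixelMaps

__all__ = [
    "FPMObject",
    "extract_features",
    "local_signal_to_background",
    "azimuthal_disorder",
    "image_level_order",
]


@dataclass
class FPMObject:
    """One segmented structure and its scalar features."""

    id: int
    group: str = ""
    image: str = ""
    area: int = 0
    perimeter: float = np.nan
    eccentricity: float = np.nan
    centroid: tuple[float, float] = (np.nan, np.nan)  # (x, y)
    length_um: float = np.nan
    mean_intensity: float = np.nan
    local_sb: float = np.nan
    mean_order: float = np.nan
    mean_azimuth_image: float = np.nan
    mean_azimuth_midline: float = np.nan
    azimuth_std: float = np.nan
    group_label: Optional[str] = None
    cluster_id: Optional[int] = None
    custom_means: Dict[str, float] = field(default_factory=dict)
    midline: Optional[Midline] = None
    pixel_indices: Optional[np.ndarray] = None  # (N, 2) rows (row, col)

    def get(self, name: str) -> float:
        """Scalar feature lookup by CSV column name."""
        aliases = {"label": "group_label", "cluster": "cluster_id", "object_id": "id"}
        name = aliases.get(name, name)
        if name.startswith("custom_"):
            return self.custom_means[name[len("custom_"):]]
        if not hasattr(self, name):
            raise KeyError(f"unknown feature {name!r}")
        return getattr(self, name)


def local_signal_to_background(
    object_mask: np.ndarray,
    S0: np.ndarray,
    all_objects_mask: np.ndarray,
    buffer_px: int = 2,
    annulus_px: int = 2,
) -> float:
    """Local S/B: mean object S0 over mean S0 in a surrounding annulus.

    The annulus is the dilation of the object by ``buffer_px +
    annulus_px`` minus its dilation by ``buffer_px``; pixels belonging to
    *any* object are excluded from the background. Returns NaN when no
    background pixel remains (object fills the frame, or the annulus is
    fully occupied by neighbours).
    """
    if buffer_px < 1 or annulus_px < 1:
        raise ValueError("buffer_px and annulus_px must be >= 1")
    object_mask = np.asarray(object_mask, dtype=bool)
    if not object_mask.any():
        raise ValueError("empty object")
    outer = ndimage.binary_dilation(object_mask, skmorph.disk(buffer_px + annulus_px))
    inner = ndimage.binary_dilation(object_mask, skmorph.disk(buffer_px))
    ring = outer & ~inner & ~np.asarray(all_objects_mask, dtype=bool)
    signal = float(np.mean(S0[object_mask]))
    if not ring.any():
        return float("nan")
    background = float(np.mean(S0[ring]))
    if background == 0:
        return float("nan")
    return signal / background


def azimuthal_disorder(alpha_deg: np.ndarray) -> float:
    """Axial circular standard deviation s0 (degrees) of pixel azimuths.

    NaN when fewer than 2 defined azimuths are available, or when the
    sample has no preferred direction (vanishing resultant).
    """
    a = np.asarray(alpha_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 2:
        return float("nan")
    return axial_std(a)


def image_level_order(maps: PixelMaps, mask: np.ndarray) -> float:
    """Mean order over all masked pixels (the image-level contrast to the
    object-based analysis). Raises on an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = maps.order[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.mean(vals))


def extract_features(
    segmentation: SegmentationResult,
    maps: PixelMaps,
    stack: FPMStack,
    group: str = "",
    image: str | None = None,
    sb_buffer_px: int = 2,
    sb_annulus_px: int = 2,
    midline_params: MidlineParams | None = None,
    compute_midlines: bool = True,
) -> List[FPMObject]:
    """Populate every object with its full scalar feature set."""
    if segmentation.labels.shape != maps.shape or maps.shape != stack.shape:
        raise ValueError("segmentation, maps and stack dimensions must agree")
    image_name = image if image is not None else stack.name
    midline_params = midline_params or MidlineParams()
    azimuth_deg = np.degrees(maps.azimuth) % 180.0

    objects: List[FPMObject] = []
    regions = skmeasure.regionprops(segmentation.labels, intensity_image=maps.S0)
    for region in regions:
        oid = int(region.label)
        obj_mask = segmentation.labels == oid
        pix = np.argwhere(obj_mask)
        obj = FPMObject(
            id=oid,
            group=group,
            image=image_name,
            area=int(region.area),
            perimeter=float(region.perimeter),
            eccentricity=float(region.eccentricity),
            centroid=(float(region.centroid[1]), float(region.centroid[0])),
            mean_intensity=float(region.intensity_mean),
            pixel_indices=pix,
        )

        order_vals = maps.order[obj_mask]
        order_vals = order_vals[np.isfinite(order_vals)]
        if order_vals.size:
            obj.mean_order = float(np.mean(order_vals))

        alpha_vals = azimuth_deg[obj_mask]
        alpha_vals = alpha_vals[np.isfinite(alpha_vals)]
        if alpha_vals.size:
            mean_deg, _ = axial_mean(alpha_vals)
            obj.mean_azimuth_image = mean_deg
        if alpha_vals.size >= 2:
            obj.azimuth_std = azimuthal_disorder(alpha_vals)

        obj.local_sb = local_signal_to_background(
            obj_mask, maps.S0, segmentation.mask, sb_buffer_px, sb_annulus_px
        )

        for cname, raster in maps.custom.items():
            vals = raster[obj_mask]
            vals = vals[np.isfinite(vals)]
            obj.custom_means[cname] = float(np.mean(vals)) if vals.size else float("nan")

        if compute_midlines:
            midline = compute_midline(obj_mask, params=midline_params)
            obj.midline = midline
            if midline.valid:
                obj.length_um = midline.arc_length_um(stack.pixel_size)
                tangent_field = assign_tangents(obj_mask, midline)
                rel = relative_azimuth(azimuth_deg, tangent_field)
                rel_vals = rel[obj_mask]
                rel_vals = rel_vals[np.isfinite(rel_vals)]
                if rel_vals.size:
                    mean_rel, _ = axial_mean(rel_vals)
                    obj.mean_azimuth_midline = mean_rel
        objects.append(obj)
    return objects
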