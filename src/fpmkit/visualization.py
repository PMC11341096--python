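"""Composite image renders and axial polar histograms.

Three composite views combine the pixelwise maps into single images:

* order-intensity overlay — the order map colormapped, with the
  normalized total intensity acting as the opacity (alpha) channel;
* azimuth-order-intensity HSV — hue from the azimuth (cyclic with
  period pi, so opposite directions share a color), saturation from the
  order, value from the normalized intensity;
* azimuth sticks — one line segment per sampled object pixel, oriented
  at the pixel azimuth and colored by a 180°-periodic cyclic map of
  either the image-frame or the midline-relative angle.

Polar histograms duplicate each axial angle at theta and theta + 180° so
both equivalent, opposite directions are shown.

All renders are deterministic for a fixed spec. Raster builders return
arrays; file output goes through matplotlib (Agg-compatible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import hsv_to_rgb

from .circular import axial_histogram
from .features import FPMObject
from .midline import assign_tangents, relative_azimuth
from .stats import PixelMaps

__all__ = [
    "RenderSpec",
    "StickOverlay",
    "render_order_intensity",
    "render_azimuth_hsv",
    "render_azimuth_sticks",
    "render_axial_polar_histogram",
    "axial_cyclic_color",
]


@dataclass
class RenderSpec:
    """Normalization and styling shared by the composite renders.

    Percentile bounds are robust alternatives to min/max normalization;
    set them to (0, 100) to normalize to the extremes.
    """

    intensity_percentiles: tuple[float, float] = (0.1, 99.9)
    order_percentiles: tuple[float, float] = (0.1, 99.9)
    stick_spacing: int = 4
    stick_length: float = 4.0
    colormap: str = "viridis"

    def __post_init__(self) -> None:
        for lo, hi in (self.intensity_percentiles, self.order_percentiles):
            if not (0 <= lo < hi <= 100):
                raise ValueError("percentile bounds must satisfy 0 <= lo < hi <= 100")


def _normalize(raster: np.ndarray, percentiles: tuple[float, float]) -> np.ndarray:
    vals = raster[np.isfinite(raster)]
    if vals.size == 0:
        return np.zeros_like(raster)
    lo, hi = np.percentile(vals, percentiles)
    if hi <= lo:
        return np.where(np.isfinite(raster), (raster >= lo).astype(float), 0.0)
    out = (raster - lo) / (hi - lo)
    return np.clip(np.nan_to_num(out, nan=0.0), 0.0, 1.0)


def axial_cyclic_color(angles_deg: np.ndarray) -> np.ndarray:
    """RGBA colors from a cyclic map with period 180° (alpha anchored at 0°)."""
    frac = (np.asarray(angles_deg, float) % 180.0) / 180.0
    return colormaps["hsv"](frac)


def render_order_intensity(maps: PixelMaps, spec: RenderSpec | None = None) -> np.ndarray:
    """RGBA raster: colormapped order with intensity as the alpha mask."""
    spec = spec or RenderSpec()
    order = _normalize(maps.order, spec.order_percentiles)
    rgba = colormaps[spec.colormap](order)
    rgba[..., 3] = _normalize(maps.S0, spec.intensity_percentiles)
    return rgba


def render_azimuth_hsv(maps: PixelMaps, spec: RenderSpec | None = None) -> np.ndarray:
    """RGB raster: hue = azimuth (period pi), saturation = order, value =
    normalized intensity. Undefined-azimuth pixels get saturation 0."""
    spec = spec or RenderSpec()
    alpha = maps.azimuth
    hue = ((alpha % np.pi) / np.pi)
    defined = np.isfinite(alpha)
    hue = np.where(defined, np.nan_to_num(hue, nan=0.0), 0.0)
    sat = np.clip(np.nan_to_num(maps.order, nan=0.0), 0.0, 1.0)
    sat = np.where(defined, sat, 0.0)
    value = _normalize(maps.S0, spec.intensity_percentiles)
    return hsv_to_rgb(np.stack([hue, sat, value], axis=-1))


@dataclass
class StickOverlay:
    """Azimuth sticks ready for plotting: one segment per sampled pixel."""

    segments: np.ndarray  # (N, 2, 2) endpoints in (x, y=row) display coords
    colors: np.ndarray  # (N, 4) RGBA
    angles_deg: np.ndarray  # (N,) the angle each stick encodes
    shape: tuple[int, int]

    def save(self, path, background: np.ndarray | None = None) -> None:
        import matplotlib.pyplot as plt
        from matplotlib.collections import LineCollection

        fig, ax = plt.subplots(figsize=(6, 6 * self.shape[0] / max(self.shape[1], 1)))
        if background is not None:
            ax.imshow(background, cmap="gray", interpolation="nearest")
        ax.add_collection(LineCollection(self.segments, colors=self.colors, linewidths=1.2))
        ax.set_xlim(-0.5, self.shape[1] - 0.5)
        ax.set_ylim(self.shape[0] - 0.5, -0.5)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def render_azimuth_sticks(
    maps: PixelMaps,
    objects: Sequence[FPMObject],
    spec: RenderSpec | None = None,
    color_by: Literal["azimuth_image", "azimuth_midline"] = "azimuth_image",
) -> StickOverlay:
    """Build azimuth sticks over object pixels on a regular grid.

    Pixels are sampled every ``spec.stick_spacing`` rows/columns within
    each object; pixels with undefined azimuth (or, for the midline
    variant, without a valid midline tangent) carry no stick. Sticks are
    drawn centered on the pixel, oriented at the *image-frame* azimuth,
    and colored by the chosen angle (image-frame or midline-relative).
    """
    spec = spec or RenderSpec()
    azimuth_deg = np.degrees(maps.azimuth) % 180.0
    h, w = maps.shape

    segs: list[np.ndarray] = []
    color_angles: list[float] = []
    for obj in objects:
        if obj.pixel_indices is None:
            continue
        if color_by == "azimuth_midline":
            if obj.midline is None or not obj.midline.valid:
                continue
            mask = np.zeros((h, w), dtype=bool)
            mask[obj.pixel_indices[:, 0], obj.pixel_indices[:, 1]] = True
            tangents = assign_tangents(mask, obj.midline)
        for r, c in obj.pixel_indices:
            if r % spec.stick_spacing or c % spec.stick_spacing:
                continue
            a = azimuth_deg[r, c]
            if not np.isfinite(a):
                continue
            if color_by == "azimuth_midline":
                t = tangents[r, c]
                if not np.isfinite(t):
                    continue
                color_angle = relative_azimuth(a, t)
            else:
                color_angle = a
            # y-up angle convention: row offset is the negative sine term
            dx = 0.5 * spec.stick_length * np.cos(np.deg2rad(a))
            dy = -0.5 * spec.stick_length * np.sin(np.deg2rad(a))
            segs.append(np.array([[c - dx, r - dy], [c + dx, r + dy]]))
            color_angles.append(float(color_angle))

    if segs:
        segments = np.stack(segs)
        angles = np.asarray(color_angles)
        colors = axial_cyclic_color(angles)
    else:
        segments = np.zeros((0, 2, 2))
        angles = np.zeros(0)
        colors = np.zeros((0, 4))
    return StickOverlay(segments=segments, colors=colors, angles_deg=angles, shape=(h, w))


def render_axial_polar_histogram(
    angles_deg: Sequence[float], n_bins: int, path=None
) -> np.ndarray:
    """Polar bar plot of the 180°-duplicated axial histogram.

    Returns the bin counts (summing to 2n); writes the figure when
    ``path`` is given.
    """
    counts, edges = axial_histogram(np.asarray(angles_deg, float), n_bins)
    if path is not None:
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(projection="polar")
        centers = np.deg2rad((edges[:-1] + edges[1:]) / 2.0)
        width = np.deg2rad(360.0 / n_bins)
        ax.bar(centers, counts, width=width, bottom=0.0,
               color="tab:blue", edgecolor="black", linewidth=0.5)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return counts
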