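"""Synthetic polarization scenes with known per-pixel ground truth.

The forward model renders the four-angle stack from per-pixel amplitude
A, order p_true and azimuth alpha_true:

    I_omega = B_g + A * (1 + p_true * cos 2(omega - alpha_true)) / 2

with optional Gaussian (optical) blur applied before the noise model
(detection). The half-amplitude parameterization makes the pipeline's
recovered order equal the scene's p_true exactly when the background
B_g is zero: per pixel S0 = A, S1 = A*p*cos 2a, S2 = A*p*sin 2a.

Scene builders produce the three morphologies used throughout testing —
punctate fields, curvilinear ("S-shaped") ribbons, and straight
filaments — each with a recorded ground-truth sidecar: per-object pixel
sets, generating centerlines, planted lengths, and per-pixel truth
rasters.

Image geometry follows the microscope convention: angles are measured
anticlockwise from the +x axis (x = column index) in a frame where y
increases upward, so a segment whose row index increases with column has
a *negative* (equivalently > 90° axial) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import LineString

from .core import FPMStack, POLARIZATION_ANGLES

__all__ = [
    "NoiseModel",
    "ObjectTruth",
    "SyntheticScene",
    "render_stack",
    "make_puncta_field",
    "make_sshape_scene",
    "make_filament_scene",
    "axial_angle_deg",
]


def axial_angle_deg(dx: np.ndarray | float, drow: np.ndarray | float):
    """Axial direction (degrees in [0,180)) of a step (dx, drow) in raster coords.

    Row index grows downward while the angle convention has y upward, so
    the row component enters with a minus sign.
    """
    return np.degrees(np.arctan2(-np.asarray(drow, float), np.asarray(dx, float))) % 180.0


@dataclass
class NoiseModel:
    """Detection noise: 'none', additive 'gaussian' (sigma in counts), or
    'poisson' (shot noise; gain = photoelectrons per count unit)."""

    kind: Literal["none", "gaussian", "poisson"] = "none"
    sigma: float = 0.0
    gain: float = 1.0


@dataclass
class ObjectTruth:
    """Ground-truth record for one planted object."""

    kind: Literal["punctum", "curve", "filament"]
    mask: np.ndarray
    centerline: Optional[np.ndarray] = None  # (N, 2) columns (x=col, y=row)
    length_px: Optional[float] = None
    length_um: Optional[float] = None
    center: Optional[tuple[float, float]] = None  # (x, y=row)
    radius: Optional[float] = None
    amplitude: float = 0.0


@dataclass
class SyntheticScene:
    """Per-pixel ground truth plus the rendering recipe.

    ``truth_azimuth_deg`` is axial, degrees in [0, 180), NaN where the
    order is zero (no preferred direction).
    """

    truth_order: np.ndarray
    truth_azimuth_deg: np.ndarray
    amplitude: np.ndarray
    background: float
    noise: NoiseModel = field(default_factory=NoiseModel)
    blur_sigma: float = 0.0
    pixel_size: float = 0.1
    seed: int = 0
    name: str = "scene"
    objects: list[ObjectTruth] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth_order.shape

    @property
    def object_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for obj in self.objects:
            mask |= obj.mask
        return mask


def render_stack(scene: SyntheticScene) -> FPMStack:
    """Render the four-angle stack from a scene (deterministic given seed)."""
    p = np.asarray(scene.truth_order, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("truth_order must lie in [0, 1]")
    alpha = np.deg2rad(np.nan_to_num(scene.truth_azimuth_deg, nan=0.0))
    a_map = np.asarray(scene.amplitude, dtype=float)
    if a_map.shape != p.shape or scene.truth_azimuth_deg.shape != p.shape:
        raise ValueError("truth rasters and amplitude must share dimensions")

    images = np.empty((4,) + p.shape, dtype=float)
    for k, omega_deg in enumerate(POLARIZATION_ANGLES):
        omega = np.deg2rad(omega_deg)
        images[k] = scene.background + a_map * (1.0 + p * np.cos(2.0 * (omega - alpha))) / 2.0

    if scene.blur_sigma > 0:
        for k in range(4):
            images[k] = ndimage.gaussian_filter(images[k], scene.blur_sigma)

    rng = np.random.default_rng(scene.seed)
    noise = scene.noise
    if noise.kind == "gaussian":
        images = images + rng.normal(0.0, noise.sigma, size=images.shape)
        images = np.clip(images, 0.0, None)
    elif noise.kind == "poisson":
        images = rng.poisson(np.clip(images, 0.0, None) * noise.gain).astype(float) / noise.gain
    elif noise.kind != "none":
        raise ValueError(f"unknown noise model {noise.kind!r}")

    return FPMStack(images, pixel_size=scene.pixel_size, name=scene.name)


# --- rasterization helpers ----------------------------------------------


def _resample_polyline(points: np.ndarray, spacing: float = 0.25) -> np.ndarray:
    """Resample an (N,2) polyline at (approximately) uniform arc spacing."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, arclen, pts[:, 0])
    y = np.interp(s, arclen, pts[:, 1])
    return np.column_stack([x, y])


def _polyline_tangents_deg(points: np.ndarray) -> np.ndarray:
    """Axial tangent angle (deg) per polyline vertex, central differences."""
    pts = np.asarray(points, dtype=float)
    d = np.gradient(pts, axis=0)
    return axial_angle_deg(d[:, 0], d[:, 1])


def _paint_curve(
    scene_shape: tuple[int, int],
    centerline: np.ndarray,
    width: float,
    dipole: str,
    fixed_angle: float | None,
    order: float,
    amplitude: float,
    truth_order: np.ndarray,
    truth_azimuth: np.ndarray,
    amp_map: np.ndarray,
) -> np.ndarray:
    """Rasterize a tube of given width around a centerline and write truth.

    Returns the boolean mask of painted pixels. Azimuths follow the
    dipole rule: 'parallel' = local tangent, 'normal' = tangent + 90°,
    'fixed' = fixed_angle.
    """
    dense = _resample_polyline(centerline, spacing=0.25)
    tangents = _polyline_tangents_deg(dense)
    tree = cKDTree(dense)
    h, w = scene_shape
    rows, cols = np.mgrid[0:h, 0:w]
    pix = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    dist, idx = tree.query(pix)
    mask = (dist <= width / 2.0).reshape(h, w)
    nearest = idx.reshape(h, w)
    # butt caps: cut the tube flat at the curve endpoints (no protruding
    # half-disks) so the generating curve is exactly the tube's medial axis
    for end_idx, interior_idx in ((0, min(4, len(dense) - 1)), (len(dense) - 1, max(len(dense) - 5, 0))):
        t_vec = dense[end_idx] - dense[interior_idx]
        norm = np.linalg.norm(t_vec)
        if norm == 0:
            continue
        t_vec = t_vec / norm
        at_end = nearest == end_idx
        beyond = ((cols - dense[end_idx, 0]) * t_vec[0] + (rows - dense[end_idx, 1]) * t_vec[1]) > 0
        mask &= ~(at_end & beyond)

    if dipole == "parallel":
        az = tangents[nearest]
    elif dipole == "normal":
        az = (tangents[nearest] + 90.0) % 180.0
    elif dipole == "fixed":
        if fixed_angle is None:
            raise ValueError("fixed dipole rule requires fixed_angle")
        az = np.full(scene_shape, float(fixed_angle) % 180.0)
    else:
        raise ValueError(f"unknown dipole rule {dipole!r}")

    truth_order[mask] = order
    truth_azimuth[mask] = az[mask]
    amp_map[mask] = amplitude
    return mask


def _blank_truth(shape: tuple[int, int]):
    truth_order = np.zeros(shape, dtype=float)
    truth_azimuth = np.full(shape, np.nan)
    amp_map = np.zeros(shape, dtype=float)
    return truth_order, truth_azimuth, amp_map


# --- scene builders ------------------------------------------------------


def make_puncta_field(
    shape: tuple[int, int] = (256, 256),
    n: int = 30,
    radius: float = 3.0,
    amplitude: float = 90.0,
    background: float = 10.0,
    order: float = 0.8,
    azimuth_deg: float | None = None,
    min_separation: float = 10.0,
    noise: NoiseModel | None = None,
    blur_sigma: float = 0.0,
    pixel_size: float = 0.1,
    seed: int = 0,
    name: str = "puncta",
) -> SyntheticScene:
    """A field of ``n`` disjoint circular puncta with uniform order.

    Centers are drawn by rejection sampling so that every pair of centers
    is at least ``2*radius + min_separation`` apart; each punctum gets a
    random axial azimuth unless ``azimuth_deg`` is given.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = radius + 2.0
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place puncta; relax n or min_separation")
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if all(np.hypot(cx - x, cy - y) >= 2 * radius + min_separation for x, y in centers):
            centers.append((cx, cy))

    truth_order, truth_azimuth, amp_map = _blank_truth(shape)
    rows, cols = np.mgrid[0:h, 0:w]
    objects = []
    for cx, cy in centers:
        az = rng.uniform(0.0, 180.0) if azimuth_deg is None else float(azimuth_deg) % 180.0
        mask = (cols - cx) ** 2 + (rows - cy) ** 2 <= radius**2
        truth_order[mask] = order
        truth_azimuth[mask] = az
        amp_map[mask] = amplitude
        objects.append(
            ObjectTruth(
                kind="punctum",
                mask=mask,
                center=(cx, cy),
                radius=radius,
                amplitude=amplitude,
            )
        )
    return SyntheticScene(
        truth_order=truth_order,
        truth_azimuth_deg=truth_azimuth,
        amplitude=amp_map,
        background=background,
        noise=noise or NoiseModel(),
        blur_sigma=blur_sigma,
        pixel_size=pixel_size,
        seed=seed,
        name=name,
        objects=objects,
    )


def make_sshape_scene(
    shape: tuple[int, int] = (128, 128),
    width: float = 5.0,
    dipole: Literal["parallel", "normal", "fixed"] = "normal",
    fixed_angle: float | None = None,
    order: float = 0.9,
    amplitude: float = 100.0,
    background: float = 5.0,
    sine_amplitude_frac: float = 0.22,
    rotation_deg: float = 0.0,
    noise: NoiseModel | None = None,
    blur_sigma: float = 0.0,
    pixel_size: float = 0.1,
    seed: int = 0,
    name: str = "sshape",
) -> SyntheticScene:
    """One S-shaped ribbon: a full sine period dilated to ``width`` px.

    The generating curve is recorded in the sidecar for midline-recovery
    tests; ``rotation_deg`` rotates the whole curve about the image
    center (anticlockwise in the y-up convention). With the 'normal'
    dipole rule every ground-truth azimuth is perpendicular to the local
    curve tangent, i.e. alpha_midline = 90° everywhere by construction.
    """
    h, w = shape
    t = np.linspace(0.0, 1.0, 400)
    span = 0.68 * min(h, w)
    x = (w - 1) / 2.0 + span * (t - 0.5)
    y = (h - 1) / 2.0 + sine_amplitude_frac * min(h, w) * np.sin(2.0 * np.pi * t)
    pts = np.column_stack([x, y])
    if rotation_deg:
        # anticlockwise in the y-up frame = clockwise in row coordinates
        th = np.deg2rad(rotation_deg)
        c0 = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        pts = (pts - c0) @ rot.T + c0
    if not LineString(pts).is_simple:
        raise ValueError("generating curve is self-intersecting")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    if lo[0] < width or lo[1] < width or hi[0] > w - 1 - width or hi[1] > h - 1 - width:
        raise ValueError("curve (plus width) does not fit in the frame")

    truth_order, truth_azimuth, amp_map = _blank_truth(shape)
    mask = _paint_curve(
        shape, pts, width, dipole, fixed_angle, order, amplitude,
        truth_order, truth_azimuth, amp_map,
    )
    length_px = float(LineString(pts).length)
    objects = [
        ObjectTruth(
            kind="curve",
            mask=mask,
            centerline=pts,
            length_px=length_px,
            length_um=length_px * pixel_size,
            amplitude=amplitude,
        )
    ]
    return SyntheticScene(
        truth_order=truth_order,
        truth_azimuth_deg=truth_azimuth,
        amplitude=amp_map,
        background=background,
        noise=noise or NoiseModel(),
        blur_sigma=blur_sigma,
        pixel_size=pixel_size,
        seed=seed,
        name=name,
        objects=objects,
    )


def make_filament_scene(
    shape: tuple[int, int] = (512, 512),
    lengths_um: Sequence[float] = (10.0, 25.0),
    width: float = 4.0,
    orientations_deg: Sequence[float] | None = None,
    amplitude: float = 80.0,
    background: float = 8.0,
    order: float = 0.7,
    dipole: Literal["parallel", "normal", "fixed"] = "parallel",
    fixed_angle: float | None = None,
    min_separation: float = 12.0,
    noise: NoiseModel | None = None,
    blur_sigma: float = 0.0,
    pixel_size: float = 0.1,
    seed: int = 0,
    name: str = "filaments",
) -> SyntheticScene:
    """Straight filaments with planted metric lengths.

    Each filament is a straight segment of length ``lengths_um[i]``
    (converted to pixels via ``pixel_size``) dilated to ``width`` px;
    positions and orientations are drawn at random (or taken from
    ``orientations_deg``) subject to fitting in the frame and keeping
    every pair of segments at least ``min_separation`` px apart. The
    sidecar records the exact planted length of every filament, which is
    what length-based filtering and the short/long split are tested
    against.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    placed: list[LineString] = []
    segments: list[np.ndarray] = []
    for i, length_um in enumerate(lengths_um):
        length_px = length_um / pixel_size
        if length_px > 0.9 * min(h, w) * np.sqrt(2):
            raise ValueError(f"filament of {length_um} um does not fit in the frame")
        ok = False
        for _ in range(5000):
            theta = (
                np.deg2rad(orientations_deg[i])
                if orientations_deg is not None
                else rng.uniform(0.0, np.pi)
            )
            # y-up convention: the row offset is the negative sine component
            dx = length_px * np.cos(theta)
            drow = -length_px * np.sin(theta)
            margin = width + 2.0
            x0 = rng.uniform(margin, w - margin)
            y0 = rng.uniform(margin, h - margin)
            x1, y1 = x0 + dx, y0 + drow
            if not (margin <= x1 <= w - margin and margin <= y1 <= h - margin):
                continue
            seg = LineString([(x0, y0), (x1, y1)])
            if all(seg.distance(other) >= width + min_separation for other in placed):
                placed.append(seg)
                segments.append(np.array([[x0, y0], [x1, y1]]))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place all filaments; enlarge the frame or relax separation"
            )

    truth_order, truth_azimuth, amp_map = _blank_truth(shape)
    objects = []
    for seg_pts, length_um in zip(segments, lengths_um):
        mask = _paint_curve(
            shape, seg_pts, width, dipole, fixed_angle, order, amplitude,
            truth_order, truth_azimuth, amp_map,
        )
        objects.append(
            ObjectTruth(
                kind="filament",
                mask=mask,
                centerline=seg_pts,
                length_px=length_um / pixel_size,
                length_um=float(length_um),
                amplitude=amplitude,
            )
        )
    return SyntheticScene(
        truth_order=truth_order,
        truth_azimuth_deg=truth_azimuth,
        amplitude=amp_map,
        background=background,
        noise=noise or NoiseModel(),
        blur_sigma=blur_sigma,
        pixel_size=pixel_size,
        seed=seed,
        name=name,
        objects=objects,
    )
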