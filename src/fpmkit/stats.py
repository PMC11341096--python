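"""Pixelwise polarization statistics.

For the four-angle excitation design the polarization response of a pixel,

    I_omega = a + b * cos 2(omega - phi),

is fully determined by three quantities computed with simple image
arithmetic:

    S0 = (I0 + I45 + I90 + I135) / 2
    S1 = I0 - I90
    S2 = I45 - I135

from which the order parameter and azimuth follow:

    p     = sqrt(S1^2 + S2^2) / S0
    alpha = atan2(S2, S1) / 2

``p`` is the normalized modulation amplitude (0 = isotropic response,
1 = fully modulated) and ``alpha`` is the mean in-plane dipole direction.
``alpha`` is *axial* (period pi) and is kept in [-pi/2, pi/2) internally
(radians); user-facing angle features are reported in degrees in [0, 180).

This module also provides the optional flat-field correction, a direct
least-squares sinusoid fit (equivalent to the closed form at the four
equally spaced angles, but defined for any angle set), and a registry for
user-defined per-pixel statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence

import numpy as np

from .core import FPMStack, FlatFieldStack, StackFormatError

__all__ = [
    "PixelMaps",
    "SinusoidFit",
    "compute_pixel_maps",
    "flat_field_correct",
    "fit_pixel_sinusoid",
    "register_custom_statistic",
    "unregister_custom_statistic",
    "custom_statistic_names",
    "wrap_axial_rad",
]


def wrap_axial_rad(alpha: np.ndarray | float) -> np.ndarray | float:
    """Wrap axial angles (radians) to [-pi/2, pi/2)."""
    return (np.asarray(alpha) + np.pi / 2) % np.pi - np.pi / 2


@dataclass
class PixelMaps:
    """Per-pixel polarization statistics derived from one stack.

    Attributes
    ----------
    S0, S1, S2 : ndarray
        Total intensity and the two modulation components.
    order : ndarray
        p = sqrt(S1^2+S2^2)/S0; NaN where S0 == 0. Deliberately *not*
        clipped at 1: noise can push the modulation amplitude above the
        total intensity, and clipping would bias signal-to-background
        analyses.
    azimuth : ndarray
        alpha = atan2(S2, S1)/2 in radians, wrapped to [-pi/2, pi/2);
        NaN where S1 == S2 == 0 (no modulation: the direction is
        undefined, and 0 is a valid direction so it must not be used as
        a placeholder).
    custom : dict
        Name -> raster for every registered custom statistic.
    """

    S0: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    order: np.ndarray
    azimuth: np.ndarray
    custom: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.S0.shape


@dataclass
class SinusoidFit:
    """Least-squares fit of a + b*cos 2(omega - phi) to one pixel's response.

    ``b >= 0`` is enforced by phase wrapping; ``phi`` lies in
    [-pi/2, pi/2) and defaults to 0 when b == 0 (the phase of a constant
    response is arbitrary).
    """

    offset: float
    amplitude: float
    phase: float
    rss: float

    def predict(self, angles_deg: Sequence[float]) -> np.ndarray:
        omega = np.deg2rad(np.asarray(angles_deg, dtype=float))
        return self.offset + self.amplitude * np.cos(2.0 * (omega - self.phase))


# --- custom statistic plug-in point -------------------------------------

_CUSTOM_STATISTICS: Dict[str, Callable] = {}


def register_custom_statistic(name: str, fn: Callable) -> None:
    """Register a per-pixel statistic ``fn(I0, I45, I90, I135) -> raster``.

    The function must be pure and vectorized over the four intensity
    rasters. After registration every :func:`compute_pixel_maps` call
    attaches the resulting raster under ``maps.custom[name]`` and object
    feature extraction reports its per-object mean as ``custom_<name>``.
    """
    if not name.isidentifier():
        raise ValueError(f"statistic name must be an identifier, got {name!r}")
    if name in _CUSTOM_STATISTICS:
        raise ValueError(f"custom statistic {name!r} already registered")
    _CUSTOM_STATISTICS[name] = fn


def unregister_custom_statistic(name: str) -> None:
    _CUSTOM_STATISTICS.pop(name, None)


def custom_statistic_names() -> list[str]:
    return list(_CUSTOM_STATISTICS)


# --- core computations ---------------------------------------------------


def compute_pixel_maps(stack: FPMStack) -> PixelMaps:
    """Compute S0/S1/S2 and the order and azimuth maps for a stack.

    Degenerate pixels are flagged with NaN rather than raising: order is
    undefined where S0 == 0, azimuth where S1 == S2 == 0.
    """
    i0, i45, i90, i135 = (stack.images[k] for k in range(4))
    s0 = (i0 + i45 + i90 + i135) / 2.0
    s1 = i0 - i90
    s2 = i45 - i135

    amplitude = np.hypot(s1, s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        order = np.where(s0 > 0, amplitude / np.where(s0 > 0, s0, 1.0), np.nan)

    azimuth = wrap_axial_rad(0.5 * np.arctan2(s2, s1))
    azimuth = np.where((s1 == 0) & (s2 == 0), np.nan, azimuth)

    custom = {
        name: np.asarray(fn(i0, i45, i90, i135), dtype=float)
        for name, fn in _CUSTOM_STATISTICS.items()
    }
    return PixelMaps(S0=s0, S1=s1, S2=s2, order=order, azimuth=azimuth, custom=custom)


def flat_field_correct(stack: FPMStack, flats: Sequence[FlatFieldStack]) -> FPMStack:
    """Apply the standard flat-field correction, one flat per polarization.

    For each angle the flat-field images are averaged across the supplied
    calibration stacks, the averaged image is divided by its own mean (so
    a spatially uniform flat is a no-op regardless of its level), and the
    data image is divided pixelwise by this normalized flat. Output
    intensities are clipped at 0.
    """
    if len(flats) == 0:
        raise ValueError("at least one flat-field stack is required")
    for f in flats:
        if f.shape != stack.shape:
            raise StackFormatError(
                f"flat-field shape {f.shape} does not match stack shape {stack.shape}"
            )
    mean_flat = np.mean([f.images for f in flats], axis=0)
    corrected = np.empty_like(stack.images)
    for k in range(4):
        flat = mean_flat[k]
        level = flat.mean()
        if not level > 0:
            raise ValueError("averaged flat-field image has nonpositive mean")
        normalized = flat / level
        if np.any(normalized <= 0):
            raise ValueError("flat-field correction refused: nonpositive flat pixels")
        corrected[k] = stack.images[k] / normalized
    return FPMStack(
        np.clip(corrected, 0.0, None), pixel_size=stack.pixel_size, name=stack.name
    )


def fit_pixel_sinusoid(
    intensities: Sequence[float],
    angles_deg: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
) -> SinusoidFit:
    """Least-squares fit of ``a + b*cos 2(omega - phi)`` to one pixel.

    The model is linear in ``(a, b*cos 2phi, b*sin 2phi)``, so the global
    optimum is found by ordinary least squares. For the four equally
    spaced angles 0/45/90/135 this reduces exactly to the closed form
    ``a = S0/2``, ``b = sqrt(S1^2+S2^2)/2``, ``phi = alpha``.
    """
    y = np.asarray(intensities, dtype=float)
    omega = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if y.shape != omega.shape:
        raise ValueError("intensities and angles must have the same length")
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    design = np.column_stack([np.ones_like(omega), np.cos(2 * omega), np.sin(2 * omega)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    a, c, s = coef
    b = float(np.hypot(c, s))
    # degenerate convention: a (numerically) constant response has b = 0
    # and phase 0 — the phase of an unmodulated pixel is arbitrary
    eps = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    if b <= eps:
        b = 0.0
        phi = 0.0
    else:
        phi = float(wrap_axial_rad(0.5 * np.arctan2(s, c)))
    residuals = y - design @ coef
    return SinusoidFit(offset=float(a), amplitude=b, phase=phi, rss=float(residuals @ residuals))
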