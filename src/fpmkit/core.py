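"""Core domain containers for excitation-resolved polarization stacks.

An "FPM stack" is the four-image series acquired while rotating the
excitation polarization through 0°, 45°, 90° and 135° (measured
anticlockwise from the +x axis of the microscope frame). Every downstream
quantity — total intensity S0, the modulation components S1/S2, the order
parameter p and the azimuth α — is pixelwise arithmetic on these four
registered images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the fixed excitation polarization sequence, degrees anticlockwise from +x
POLARIZATION_ANGLES: tuple[int, int, int, int] = (0, 45, 90, 135)


class StackFormatError(ValueError):
    """Raised when an input does not look like a 4-angle polarization stack."""


@dataclass
class FPMStack:
    """Four registered intensity images, one per excitation polarization.

    Parameters
    ----------
    images : ndarray, shape (4, H, W)
        Photoelectron counts (float, finite, >= 0) at excitation
        polarizations 0°, 45°, 90°, 135° in that order.
    pixel_size : float
        Lateral pixel size in micrometres per pixel (> 0).
    name : str
        Identifier used in object tables and exports.
    """

    images: np.ndarray
    pixel_size: float = 1.0
    name: str = "stack"
    polarization_angles: tuple[int, int, int, int] = field(
        default=POLARIZATION_ANGLES, init=False
    )

    def __post_init__(self) -> None:
        images = np.asarray(self.images, dtype=float)
        if images.ndim != 3 or images.shape[0] != 4:
            raise StackFormatError(
                f"expected 4 equally sized images, got array of shape {images.shape}"
            )
        if not np.all(np.isfinite(images)):
            raise StackFormatError("stack intensities must be finite")
        if np.any(images < 0):
            raise StackFormatError("stack intensities must be >= 0")
        if not self.pixel_size > 0:
            raise StackFormatError("pixel_size must be > 0 (um/pixel)")
        self.images = images

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each image."""
        return self.images.shape[1:]

    def scaled(self, factor: float) -> "FPMStack":
        """Return a copy with all intensities multiplied by ``factor``."""
        return FPMStack(self.images * factor, pixel_size=self.pixel_size, name=self.name)


@dataclass
class FlatFieldStack:
    """A flat-field calibration stack: four rasters, one per polarization.

    Values must be usable as divisors after averaging and mean
    normalization, i.e. strictly positive; the correction refuses
    otherwise.
    """

    images: np.ndarray

    def __post_init__(self) -> None:
        images = np.asarray(self.images, dtype=float)
        if images.ndim != 3 or images.shape[0] != 4:
            raise StackFormatError(
                f"flat-field stack must hold 4 images, got shape {images.shape}"
            )
        if not np.all(np.isfinite(images)):
            raise StackFormatError("flat-field values must be finite")
        self.images = images

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]
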