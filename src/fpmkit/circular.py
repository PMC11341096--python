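"""Axial (period-180°) circular statistics.

Fluorophore azimuths are *axial* data: a direction and its opposite are
physically indistinguishable, so all statistics operate modulo 180°. The
standard treatment is the double-angles transform: angles are doubled onto
the full circle, ordinary circular statistics are computed there, and mean
directions are halved back to the axial scale. Dispersion (the circular
standard deviation s0) is likewise halved so it is reported on the axial
scale.

All public functions take and return degrees; axial angles live in
[0, 180).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_axial_deg",
    "axial_mean",
    "axial_std",
    "axial_histogram",
]

#: resultant lengths below this are treated as "no preferred direction"
RESULTANT_EPS = 1e-9


def wrap_axial_deg(angles):
    """Wrap angles (degrees) onto the axial range [0, 180)."""
    return np.asarray(angles, dtype=float) % 180.0


def _doubled_resultant(angles_deg, weights=None):
    """Weighted resultant vector of the doubled sample.

    Returns (R_bar, doubled_direction_rad). ``R_bar`` is the mean resultant
    length in [0, 1]; the direction is that of the resultant of the doubled
    angles.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float)) * 2.0
    if a.size == 0:
        raise ValueError("empty angle sample")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != a.shape:
            raise ValueError("weights must match angles in shape")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if w.sum() <= 0:
            raise ValueError("weights must sum to a positive value")
    c = float(np.sum(w * np.cos(a)) / np.sum(w))
    s = float(np.sum(w * np.sin(a)) / np.sum(w))
    r_bar = float(np.hypot(c, s))
    direction = float(np.arctan2(s, c))
    return r_bar, direction


def axial_mean(angles_deg, weights=None):
    """Axial circular mean of a sample of angles.

    Parameters
    ----------
    angles_deg : array-like
        Axial angles in degrees (interpreted modulo 180°).
    weights : array-like, optional
        Nonnegative weights, same shape as ``angles_deg``.

    Returns
    -------
    mean_deg : float
        Mean axial direction in [0, 180); NaN when the doubled resultant
        vanishes (e.g. the orthogonal pair {0°, 90°}).
    r_bar : float
        Mean resultant length of the doubled sample, in [0, 1]. This is
        the concentration of the sample: 1 for identical angles, 0 for a
        perfectly balanced (e.g. uniform) axial sample.
    """
    r_bar, direction = _doubled_resultant(angles_deg, weights)
    if r_bar < RESULTANT_EPS:
        return float("nan"), r_bar
    mean_deg = (np.rad2deg(direction) / 2.0) % 180.0
    return float(mean_deg), r_bar


def axial_std(angles_deg, weights=None):
    """Axial circular standard deviation s0, in degrees.

    Computed as ``0.5 * sqrt(-2 ln R)`` where ``R`` is the mean resultant
    length of the doubled sample; the factor 1/2 maps the dispersion back
    from the doubled to the axial scale. Returns NaN when ``R`` is (numerically)
    zero, where the dispersion diverges.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 2:
        raise ValueError("axial_std requires at least 2 angles")
    r_bar, _ = _doubled_resultant(angles, weights)
    if r_bar < RESULTANT_EPS:
        return float("nan")
    # snap rounding-level deviations from R = 1 (identical angles) to 0
    if r_bar >= 1.0 - 1e-12:
        return 0.0
    return float(np.rad2deg(0.5 * np.sqrt(-2.0 * np.log(r_bar))))


def axial_histogram(angles_deg, n_bins, weights=None):
    """Polar histogram of axial angles with 180° duplication.

    Each angle contributes to the bin containing ``theta`` and to the bin
    containing ``theta + 180°`` so the histogram displays both equivalent,
    opposite directions; with unit weights the counts sum to ``2 n``.

    Parameters
    ----------
    angles_deg : array-like
        Axial angles in degrees.
    n_bins : int
        Number of bins over [0°, 360°); must be even so that the two
        copies of each angle fall in congruent bins.
    weights : array-like, optional

    Returns
    -------
    counts : ndarray, shape (n_bins,)
    bin_edges : ndarray, shape (n_bins + 1,)
        Edges in degrees over [0, 360].
    """
    if n_bins % 2 != 0:
        raise ValueError("n_bins must be even for axial duplication")
    a = wrap_axial_deg(angles_deg).ravel()
    dup = np.concatenate([a, a + 180.0])
    if weights is not None:
        w = np.asarray(weights, dtype=float).ravel()
        w = np.concatenate([w, w])
    else:
        w = None
    counts, edges = np.histogram(dup, bins=n_bins, range=(0.0, 360.0), weights=w)
    return counts, edges
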