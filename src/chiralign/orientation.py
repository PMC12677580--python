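"""Dominant-orientation analysis via the image structure tensor.

The dominant orientation of a fibrous texture (here, phalloidin-stained
actin) is obtained from the region-averaged structure tensor

    Jxx = <fx²>,  Jxy = <fx·fy>,  Jyy = <fy²>,

with fx, fy Gaussian-derivative gradients along the display-x (column)
and display-y (row) axes.  The eigenvector of the *smaller* eigenvalue
points along the texture; the normalised eigenvalue contrast is the
coherence (0 isotropic, 1 perfectly striped).

Angle convention
----------------
Angles are reported on (−90°, +90°] in the display frame as seen from
the culture-medium side: θ = 0 along the rectangle's long (horizontal)
axis, θ > 0 for textures running left-down → right-up on screen
(counter-clockwise tilt), θ < 0 for left-up → right-down (clockwise).
Because array rows increase downwards, this display angle is the
negative of the texture-direction angle measured in (row, col) array
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .circstats import wrap_axial

__all__ = [
    "OrientationResult",
    "structure_tensor",
    "dominant_orientation",
    "orientation_colormap",
]


@dataclass(frozen=True)
class OrientationResult:
    """Dominant angle, coherence and gradient energy of one region."""

    theta_deg: float
    coherence: float
    energy: float
    indeterminate: bool = False


def _gradients(image: np.ndarray, grad_sigma: float):
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError("image must be 2-D and at least 8x8 pixels")
    if grad_sigma <= 0:
        raise ValueError("grad_sigma must be positive")
    fx = ndimage.gaussian_filter(img, grad_sigma, order=(0, 1), mode="nearest")
    fy = ndimage.gaussian_filter(img, grad_sigma, order=(1, 0), mode="nearest")
    return fx, fy


def _trim(shape: tuple[int, int], grad_sigma: float) -> int:
    # discard a border where the derivative filters see the edge padding
    margin = int(np.ceil(3.0 * grad_sigma)) + 1
    return min(margin, min(shape) // 4)


def structure_tensor(image, grad_sigma: float = 1.0):
    """Region-averaged structure tensor (Jxx, Jxy, Jyy).

    Uniform weights over the region, with a ~3σ border excluded so edge
    padding does not bias the average.
    """
    fx, fy = _gradients(image, grad_sigma)
    t = _trim(fx.shape, grad_sigma)
    sl = (slice(t, fx.shape[0] - t or None), slice(t, fx.shape[1] - t or None))
    fxc, fyc = fx[sl], fy[sl]
    jxx = float(np.mean(fxc * fxc))
    jxy = float(np.mean(fxc * fyc))
    jyy = float(np.mean(fyc * fyc))
    return jxx, jxy, jyy


def dominant_orientation(image, grad_sigma: float = 1.0) -> OrientationResult:
    """Dominant texture orientation of a whole region.

    θ_raw = ½·atan2(2Jxy, Jxx − Jyy) is the direction of maximal
    gradient variance in array coordinates; the texture runs 90° away
    from it, and the sign is flipped to the display convention (see
    module docstring).  Blank regions (energy ≈ 0 relative to the image
    variance) are flagged indeterminate rather than raising.
    """
    img = np.asarray(image, dtype=float)
    jxx, jxy, jyy = structure_tensor(img, grad_sigma)
    energy = jxx + jyy
    eps = 1e-12 * (float(np.var(img)) + 1.0)
    if energy <= eps:
        return OrientationResult(0.0, 0.0, energy, indeterminate=True)
    theta_raw = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)  # gradient direction, rad
    theta_display = wrap_axial(90.0 - np.rad2deg(theta_raw))
    coherence = float(np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2) / energy)
    return OrientationResult(float(theta_display), min(coherence, 1.0), energy)


def orientation_colormap(
    image,
    grad_sigma: float = 1.0,
    window_sigma: float = 8.0,
) -> np.ndarray:
    """Per-pixel orientation map (degrees in (−90, 90], NaN where blank).

    The tensor products are averaged in a local Gaussian window of scale
    ``window_sigma`` instead of over the whole region.  Intended for QC
    overlays (render with a cyclic 180°-periodic colormap such as
    matplotlib's ``hsv``); quantitative statistics always use
    :func:`dominant_orientation` on whole crops.
    """
    if window_sigma <= 0:
        raise ValueError("window_sigma must be positive")
    img = np.asarray(image, dtype=float)
    fx, fy = _gradients(img, grad_sigma)
    jxx = ndimage.gaussian_filter(fx * fx, window_sigma, mode="nearest")
    jxy = ndimage.gaussian_filter(fx * fy, window_sigma, mode="nearest")
    jyy = ndimage.gaussian_filter(fy * fy, window_sigma, mode="nearest")
    energy = jxx + jyy
    eps = 1e-12 * (float(np.var(img)) + 1.0)
    theta_raw = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = wrap_axial(90.0 - np.rad2deg(theta_raw))
    theta = np.where(energy > eps, theta, np.nan)
    return theta
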