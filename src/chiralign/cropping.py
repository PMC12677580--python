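"""Two-stage cropping of micropattern rectangles.

The analysis workflow picks up, for every rectangle on the tape, a
primary window of the rectangle plus half-gap margins (900 µm × 600 µm
at the default geometry), rotates vertical rectangles 90° clockwise so
all long axes are horizontal, detects the cell-attached area by its
fluorescence over background, drops rectangles whose attached area is
below 80% of the nominal pattern size, and finally crops a central
window (400 µm × 200 µm) centred on the attached area for orientation
analysis.  Registration and flip detection rely on the chiral "F"
fiducial at the tape centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes

from .errors import FiducialMissingError, ImageFlippedError, OutOfBoundsError
from .geometry import GridSpec, layout_rectangles, render_f_glyph

__all__ = [
    "RectangleROI",
    "CellRegion",
    "locate_grid",
    "primary_crop",
    "detect_cell_region",
    "secondary_crop",
    "PRIMARY_MARGIN_FACTOR",
    "SECONDARY_CROP_UM",
]

#: the primary window adds half a gap on every side: 600×300 → 900×600 µm
PRIMARY_MARGIN_FACTOR = 0.5
#: central secondary crop size (length, width) in µm
SECONDARY_CROP_UM = (400.0, 200.0)
#: minimum normalised cross-correlation for the fiducial to count as found
_F_MATCH_THRESHOLD = 0.5


@dataclass
class RectangleROI:
    """One micropattern rectangle's primary-crop window.

    ``bbox_px`` is (row0, col0, height, width), 0-based half-open.
    ``rotated`` is set once the 90° clockwise normalisation has been
    applied (vertical rectangles only).
    """

    rect_id: int
    native_orientation: Literal["horizontal", "vertical"]
    bbox_px: tuple[int, int, int, int]
    rotated: bool = False


@dataclass(frozen=True)
class CellRegion:
    """Detected cell-attached area within one primary crop."""

    center_px: tuple[float, float]
    area_fraction: float
    included: bool


def _match_fiducial(image: np.ndarray, grid: GridSpec):
    """Locate the "F" glyph; returns (left-top anchor px, straight corr,
    mirror corr)."""
    img = np.asarray(image, dtype=float)
    template = render_f_glyph(grid).astype(float)
    gh, gw = template.shape
    if grid.f_mark_anchor is not None:
        a0, a1 = grid.f_mark_anchor
        pad = max(gh, gw)
        r0, c0 = max(a0 - pad, 0), max(a1 - pad, 0)
        window = img[r0:a0 + gh + pad, c0:a1 + gw + pad]
    else:
        # the fiducial sits at the tape centre; search the central zone
        half = grid.to_px(2.0 * 700.0)
        cr, cc = (img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0
        r0 = max(int(cr) - half, 0)
        c0 = max(int(cc) - half, 0)
        window = img[r0:int(cr) + half, c0:int(cc) + half]
    if window.shape[0] <= gh or window.shape[1] <= gw:
        raise FiducialMissingError("image too small to contain the fiducial")
    straight = match_template(window, template)
    mirror = match_template(window, template[:, ::-1])
    s_peak = float(straight.max())
    m_peak = float(mirror.max())
    pos = np.unravel_index(int(np.argmax(straight)), straight.shape)
    anchor = (r0 + int(pos[0]), c0 + int(pos[1]))
    return anchor, s_peak, m_peak


def locate_grid(image, grid: GridSpec) -> list[RectangleROI]:
    """Register the rectangle lattice to the image via the "F" mark.

    The glyph is template-matched against itself and its mirror image;
    a better mirror match raises :class:`ImageFlippedError` (a flipped
    field of view would silently invert every CW/CCW call), no adequate
    match raises :class:`FiducialMissingError`.  On success one ROI per
    expected rectangle position is returned: the rectangle plus
    half-gap margins, referenced to the glyph anchor.
    """
    img = np.asarray(image)
    anchor, s_peak, m_peak = _match_fiducial(img, grid)
    if max(s_peak, m_peak) < _F_MATCH_THRESHOLD:
        raise FiducialMissingError(
            f"fiducial correlation {max(s_peak, m_peak):.2f} below "
            f"{_F_MATCH_THRESHOLD}; 'F' mark not found"
        )
    if m_peak > s_peak:
        raise ImageFlippedError(
            "the 'F' mark matches its mirror image better than itself: "
            "the image is flipped and all chirality calls would be inverted"
        )
    glyph = render_f_glyph(grid)
    centre = (anchor[0] + glyph.shape[0] / 2.0,
              anchor[1] + glyph.shape[1] / 2.0)

    margin = PRIMARY_MARGIN_FACTOR * grid.gap
    rois = []
    for _, rect in layout_rectangles(grid).iterrows():
        w_um = rect.w_um + 2 * margin
        h_um = rect.h_um + 2 * margin
        h_px, w_px = grid.to_px(h_um), grid.to_px(w_um)
        r0 = int(round(centre[0] + rect.cy_um / grid.um_per_px - h_px / 2.0))
        c0 = int(round(centre[1] + rect.cx_um / grid.um_per_px - w_px / 2.0))
        rois.append(RectangleROI(int(rect.rect_id), rect.orientation,
                                 (r0, c0, h_px, w_px)))
    return rois


def primary_crop(image, roi: RectangleROI) -> np.ndarray:
    """Extract the primary window; vertical rectangles are rotated 90°
    clockwise (display sense) so the long axis ends up horizontal, and
    ``roi.rotated`` is set."""
    img = np.asarray(image)
    r0, c0, h, w = roi.bbox_px
    if r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
        raise OutOfBoundsError(
            f"ROI {roi.rect_id} bbox {roi.bbox_px} exceeds image {img.shape}"
        )
    crop = img[r0:r0 + h, c0:c0 + w].copy()
    if roi.native_orientation == "vertical" and not roi.rotated:
        crop = np.rot90(crop, k=-1)  # clockwise as displayed (rows downward)
        roi.rotated = True
    return crop


def detect_cell_region(rect_image, grid: GridSpec,
                       inclusion_threshold: float = 0.8) -> CellRegion:
    """Segment the cell-attached area of a primary crop.

    Foreground is separated from background by Otsu's global threshold,
    holes smaller than (20 µm)² are closed, and the foreground centroid
    and area are measured.  ``area_fraction`` is foreground area over
    the *nominal pattern* area (rect_length × rect_width), not the
    larger crop window, matching the published exclusion rule; a crop
    with no genuine signal (the two Otsu classes are not separated
    beyond their spreads) scores 0 and is excluded, not an error.
    """
    img = np.asarray(rect_image, dtype=float)
    centre = ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
    nominal_px = (grid.rect_length / grid.um_per_px) * \
                 (grid.rect_width / grid.um_per_px)

    if float(np.ptp(img)) == 0.0:
        return CellRegion(centre, 0.0, False)
    t = threshold_otsu(img)
    fg = img > t
    if not fg.any() or fg.all():
        return CellRegion(centre, 0.0, False)
    # reject a split of pure background noise: the class means must be
    # separated well beyond the within-class spread
    mu_fg, mu_bg = float(img[fg].mean()), float(img[~fg].mean())
    sd = max(float(img[fg].std()), float(img[~fg].std()), 1e-12)
    if mu_fg - mu_bg < 3.0 * sd:
        return CellRegion(centre, 0.0, False)
    hole_px = max(int(round((20.0 / grid.um_per_px) ** 2)), 1)
    fg = remove_small_holes(fg, max_size=hole_px)
    area_fraction = float(fg.sum() / nominal_px)
    com = ndimage.center_of_mass(fg)
    return CellRegion((float(com[0]), float(com[1])), area_fraction,
                      area_fraction >= inclusion_threshold)


def secondary_crop(rect_image, region: CellRegion,
                   grid: GridSpec) -> np.ndarray:
    """Central crop (400 µm × 200 µm) centred on the cell-attached area.

    The window is clamped to stay inside the primary crop rather than
    padded, so no intensity data is fabricated at the edges.  Calling
    this on an excluded region is a precondition violation.
    """
    if not region.included:
        raise ValueError("secondary_crop called on an excluded region")
    img = np.asarray(rect_image)
    w_px = grid.to_px(SECONDARY_CROP_UM[0])
    h_px = grid.to_px(SECONDARY_CROP_UM[1])
    if h_px > img.shape[0] or w_px > img.shape[1]:
        raise OutOfBoundsError("secondary window larger than the primary crop")
    r0 = int(round(region.center_px[0] - h_px / 2.0))
    c0 = int(round(region.center_px[1] - w_px / 2.0))
    r0 = min(max(r0, 0), img.shape[0] - h_px)
    c0 = min(max(c0, 0), img.shape[1] - w_px)
    return img[r0:r0 + h_px, c0:c0 + w_px]
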