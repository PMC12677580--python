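"""Micropattern tape geometry: the rectangle lattice and the "F" fiducial.

The tape carries rectangular adhesion islands (600 µm × 300 µm by
default) laid out inside a 19 mm circle with 300 µm gaps, in a mix of
horizontal and vertical orientations, plus a chiral "F" glyph at the
tape centre.  The glyph serves two purposes: it anchors the pixel ↔
micrometre mapping, and — because "F" is not superimposable on its
mirror image — it detects accidental image flips that would invert
every chirality call.

Tape coordinates are micrometres with the origin at the tape centre,
x to the right and y downwards (matching array row order), so that a
point (x_um, y_um) maps to pixel (row, col) = centre_px + (y, x)/um_per_px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidGeometryError

__all__ = ["GridSpec", "layout_rectangles", "render_f_glyph"]

#: micrometre half-size of the exclusion zone kept clear for the fiducial
F_ZONE_RADIUS_UM = 700.0
#: glyph height in micrometres (width is 0.6 × height)
F_GLYPH_HEIGHT_UM = 400.0


@dataclass
class GridSpec:
    """Geometry of the micropattern tape layout and the image scale.

    Parameters
    ----------
    rect_length, rect_width : float
        Rectangle dimensions in µm (long and short axis).
    gap : float
        Minimum spacing between rectangles in µm, both directions.
    n_rectangles : int
        Number of rectangles placed (the closest-to-centre candidates of
        the lattice are kept).
    layout_diameter : float
        Diameter in µm of the circle every rectangle must fit inside.
    um_per_px : float
        Image scale.  The real microscope scale is configurable because
        it is instrument-dependent.
    f_mark_anchor : (row, col) or None
        Pixel coordinate of the left-top corner of the "F" glyph.
        Filled in by the scene generator; when None at analysis time the
        glyph is located by template matching.
    orientation_mix : float
        Target fraction of vertical rectangles in [0, 1]; realised by
        deterministic row-wise assignment.
    """

    rect_length: float = 600.0
    rect_width: float = 300.0
    gap: float = 300.0
    n_rectangles: int = 453
    layout_diameter: float = 19000.0
    um_per_px: float = 2.0
    f_mark_anchor: tuple[int, int] | None = None
    orientation_mix: float = 0.5

    def __post_init__(self):
        if min(self.rect_length, self.rect_width, self.gap,
               self.layout_diameter, self.um_per_px) <= 0:
            raise InvalidGeometryError("all lengths must be strictly positive")
        if self.rect_length <= self.rect_width:
            raise InvalidGeometryError("rect_length must exceed rect_width")
        if not (0.0 <= self.orientation_mix <= 1.0):
            raise InvalidGeometryError("orientation_mix must be in [0, 1]")
        diag = float(np.hypot(self.rect_length, self.rect_width))
        if diag > self.layout_diameter:
            raise InvalidGeometryError(
                "a single rectangle does not fit inside the layout circle"
            )
        if self.n_rectangles < 1:
            raise InvalidGeometryError("n_rectangles must be >= 1")

    # -- pixel helpers ----------------------------------------------------
    def to_px(self, um: float) -> int:
        return int(round(um / self.um_per_px))

    @property
    def canvas_margin_um(self) -> float:
        # room for the half-gap crop margins of boundary rectangles
        return max(self.gap, 200.0)

    @property
    def canvas_shape(self) -> tuple[int, int]:
        side = self.to_px(self.layout_diameter + 2 * self.canvas_margin_um)
        return (side, side)

    @property
    def centre_px(self) -> tuple[float, float]:
        s = self.canvas_shape
        return ((s[0] - 1) / 2.0, (s[1] - 1) / 2.0)


def _row_is_vertical(i: int, mix: float) -> bool:
    """Deterministic row orientation pattern realising a vertical fraction
    ~``mix`` (cumulative rounding, so mix=0.5 alternates H,V,H,V…)."""
    return int(np.floor((i + 1) * mix)) > int(np.floor(i * mix))


def layout_rectangles(grid: GridSpec) -> pd.DataFrame:
    """Deterministic rectangle placement table in tape coordinates.

    Rectangles are packed in rows of alternating orientation (row
    pattern set by ``orientation_mix``): horizontal rows are
    ``rect_width`` tall with an x-pitch of ``rect_length + gap``,
    vertical rows ``rect_length`` tall with an x-pitch of
    ``rect_width + gap``; consecutive rows are separated by ``gap``.
    Only rectangles fully inside the layout circle and clear of the
    central fiducial zone are candidates; the ``n_rectangles`` closest
    to the centre are kept and numbered row-major.

    Returns a DataFrame with columns rect_id, orientation, cx_um, cy_um,
    w_um, h_um (w/h are the axis-aligned footprint of the rectangle).
    """
    R = grid.layout_diameter / 2.0
    rows = []
    y_top = -R
    i = 0
    while y_top < R:
        vertical = _row_is_vertical(i, grid.orientation_mix)
        h = grid.rect_length if vertical else grid.rect_width
        w = grid.rect_width if vertical else grid.rect_length
        pitch = w + grid.gap
        cy = y_top + h / 2.0
        if cy - h / 2.0 > R:
            break
        k_max = int(np.ceil(R / pitch)) + 1
        for k in range(-k_max, k_max + 1):
            cx = k * pitch
            corner = np.hypot(abs(cx) + w / 2.0, abs(cy) + h / 2.0)
            if corner > R:
                continue
            if np.hypot(cx, cy) < F_ZONE_RADIUS_UM + np.hypot(w, h) / 2.0:
                continue  # keep the fiducial zone clear
            rows.append((vertical, cx, cy, w, h))
        y_top += h + grid.gap
        i += 1

    if len(rows) < grid.n_rectangles:
        raise InvalidGeometryError(
            f"only {len(rows)} rectangles fit the layout; "
            f"{grid.n_rectangles} requested"
        )
    df = pd.DataFrame(rows, columns=["vertical", "cx_um", "cy_um", "w_um", "h_um"])
    dist = np.hypot(df.cx_um, df.cy_um)
    keep = np.argsort(dist, kind="stable")[: grid.n_rectangles]
    df = df.iloc[np.sort(keep)].reset_index(drop=True)
    df = df.sort_values(["cy_um", "cx_um"], kind="stable").reset_index(drop=True)
    df.insert(0, "rect_id", np.arange(len(df)))
    df.insert(1, "orientation",
              np.where(df.pop("vertical"), "vertical", "horizontal"))
    return df


def render_f_glyph(grid: GridSpec, mirrored: bool = False) -> np.ndarray:
    """Binary mask of the "F" fiducial at the grid's pixel scale.

    The glyph is drawn stroke-wise (stem plus two arms) so its chirality
    is explicit; ``mirrored`` renders the left-right flipped glyph used
    by tests of the flip detector.
    """
    h = max(grid.to_px(F_GLYPH_HEIGHT_UM), 24)
    w = max(int(round(0.6 * h)), 14)
    mask = np.zeros((h, w), dtype=bool)
    stem_w = max(int(round(0.22 * w)), 3)
    bar_h = max(int(round(0.18 * h)), 3)
    mask[:, :stem_w] = True                      # stem
    mask[:bar_h, :] = True                       # top arm, full width
    mid = int(round(0.42 * h))
    mask[mid:mid + bar_h, : int(round(0.75 * w))] = True  # middle arm
    if mirrored:
        mask = mask[:, ::-1]
    return mask
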