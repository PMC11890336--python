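"""Transfer of the histopathological tumor annotation into the US frame.

Annotations are carried as polygons in physical mm and rasterized only
when a mask is needed, so the high-resolution pathologist contour is
never resampled twice.
"""

from __future__ import annotations

import warnings

import numpy as np
from matplotlib.path import Path
from skimage import measure

from .core import AnnotationContour, GridSpec, Transform2D

__all__ = [
    "transform_contour",
    "rasterize_contour",
    "contour_from_mask",
]

_BOUNDARY_EPS = 1e-9  # half-open tie-break: nudge test points right/down so
# a centre on the left/top boundary counts as inside


def transform_contour(
    contour: AnnotationContour,
    transform: Transform2D,
    inverse: bool = False,
    source: str | None = None,
    frame: str | None = None,
) -> AnnotationContour:
    """Map every vertex of a contour through an affine transform.

    ``inverse=True`` applies the transform's inverse — the usual path
    when carrying the pathologist annotation (defined in the WSI frame)
    back into the US frame with a US→WSI registration transform.
    Simplicity of the polygon is preserved by any invertible affine map.
    """
    t = transform.inverse() if inverse else transform
    verts = t.apply(contour.vertices)
    return AnnotationContour(
        vertices=verts,
        source=source if source is not None else contour.source,
        frame=frame if frame is not None else contour.frame,
    )


def rasterize_contour(contour: AnnotationContour, grid: GridSpec) -> np.ndarray:
    """Binary mask of pixels whose centre lies inside the polygon.

    Even-odd rule on pixel centres; centres exactly on the boundary are
    resolved by a half-open (left/top inside) convention.  A contour
    entirely outside the grid yields an empty mask with a warning.
    """
    poly = np.asarray(contour.vertices, dtype=float)
    if abs(_signed_area(poly)) < 1e-12:
        warnings.warn("degenerate (zero-area) contour rasterizes to an empty mask")
        return np.zeros(grid.shape, dtype=np.uint8)
    path = Path(poly, closed=False)
    centers = grid.pixel_centers() + _BOUNDARY_EPS
    inside = path.contains_points(centers)
    mask = inside.reshape(grid.shape).astype(np.uint8)
    if not mask.any():
        warnings.warn("contour lies outside the raster grid; mask is empty")
    return mask


def contour_from_mask(
    mask: np.ndarray,
    grid: GridSpec,
    source: str = "truth",
    frame: str = "US",
    smooth_window: int = 5,
) -> AnnotationContour:
    """Sub-pixel boundary of a binary mask as a closed polygon in mm.

    Marching squares at the 0.5 level; the longest contour is taken
    (single-region masks have exactly one).  A short circular moving
    average over the vertices suppresses the staircase oscillation of
    the digitized boundary, which would otherwise inflate perimeter
    measurements by several percent.
    """
    mask = np.asarray(mask).astype(float)
    if not mask.any():
        raise ValueError("cannot extract a contour from an empty mask")
    contours = measure.find_contours(mask, 0.5)
    if not contours:
        raise ValueError("no 0.5-level contour found in mask")
    longest = max(contours, key=len)
    # drop duplicated closing vertex before wrap-around smoothing
    if np.allclose(longest[0], longest[-1]):
        longest = longest[:-1]
    if smooth_window > 1 and len(longest) > 2 * smooth_window:
        from scipy.ndimage import uniform_filter1d

        longest = uniform_filter1d(longest, smooth_window, axis=0, mode="wrap")
    verts = grid.index_to_mm(longest)
    return AnnotationContour(vertices=verts, source=source, frame=frame)


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
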