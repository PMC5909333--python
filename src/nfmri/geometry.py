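"""Shared raster/world geometry conventions.

World coordinates are millimetres with the origin at the image corner; the
centre of pixel (row, col) sits at ((col + 0.5) * col_spacing,
(row + 0.5) * row_spacing).  A pixel belongs to a polygon iff its centre lies
inside (even-odd rule for simple polygons); points exactly on the boundary are
not relied upon anywhere.
"""

from __future__ import annotations

import numpy as np
import shapely


def pixel_centers_mm(n_rows: int, n_cols: int, row_spacing_mm: float, col_spacing_mm: float):
    """Return (x_mm, y_mm) arrays of shape (n_rows, n_cols) for all pixel centres."""
    rows = (np.arange(n_rows) + 0.5) * row_spacing_mm
    cols = (np.arange(n_cols) + 0.5) * col_spacing_mm
    y, x = np.meshgrid(rows, cols, indexing="ij")
    return x, y


def rasterize_polygon(vertices_mm: np.ndarray, n_rows: int, n_cols: int,
                      row_spacing_mm: float, col_spacing_mm: float) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside a simple polygon.

    ``vertices_mm`` is an (N, 2) array of [x_mm, y_mm] vertices (closing edge
    implicit).
    """
    vertices_mm = np.asarray(vertices_mm, dtype=float)
    if vertices_mm.ndim != 2 or vertices_mm.shape[1] != 2 or len(vertices_mm) < 3:
        raise ValueError("polygon needs an (N, 2) vertex array with N >= 3")
    poly = shapely.Polygon(vertices_mm)
    x, y = pixel_centers_mm(n_rows, n_cols, row_spacing_mm, col_spacing_mm)
    inside = shapely.contains_xy(poly, x.ravel(), y.ravel())
    return inside.reshape(n_rows, n_cols)


def circle_polygon(center_mm, radius_mm: float, n_vertices: int = 64) -> np.ndarray:
    """Regular n-gon approximation of a circle, counter-clockwise, [x, y] in mm."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    cx, cy = center_mm
    return np.column_stack([cx + radius_mm * np.cos(theta), cy + radius_mm * np.sin(theta)])


def polygon_area_correction(n_vertices: int) -> float:
    """Area ratio of a regular n-gon to its circumscribed circle.

    Used when sizing circular contours so the polygon (the object that is
    actually rasterised) carries the intended area.
    """
    return n_vertices * np.sin(2.0 * np.pi / n_vertices) / (2.0 * np.pi)


def annular_sector_polygon(center_mm, r_inner_mm: float, r_outer_mm: float,
                           angle_center_rad: float, half_width_rad: float,
                           n_arc: int = 32) -> np.ndarray:
    """Polygon tracing an annular sector (outer arc forward, inner arc back)."""
    if not (0 < r_inner_mm < r_outer_mm):
        raise ValueError("need 0 < r_inner < r_outer")
    cx, cy = center_mm
    th = np.linspace(angle_center_rad - half_width_rad, angle_center_rad + half_width_rad, n_arc)
    outer = np.column_stack([cx + r_outer_mm * np.cos(th), cy + r_outer_mm * np.sin(th)])
    inner = np.column_stack([cx + r_inner_mm * np.cos(th[::-1]), cy + r_inner_mm * np.sin(th[::-1])])
    return np.vstack([outer, inner])


def wrapped_angle_distance(theta: np.ndarray, reference_rad: float) -> np.ndarray:
    """Absolute angular distance on the circle, in [0, pi]."""
    d = np.mod(theta - reference_rad + np.pi, 2.0 * np.pi) - np.pi
    return np.abs(d)


def mask_to_contours_mm(mask2d: np.ndarray, row_spacing_mm: float, col_spacing_mm: float):
    """Iso-contours of a boolean mask at the 0.5 level, in mm pixel-centre coords.

    Returns a list of (N, 2) [x_mm, y_mm] polygons.  Rasterising them back with
    the pixel-centre rule recovers the mask up to a one-pixel boundary band.
    """
    from skimage import measure

    padded = np.pad(mask2d.astype(float), 1)
    out = []
    for rc in measure.find_contours(padded, 0.5):
        rc = rc - 1.0  # undo padding
        x = (rc[:, 1] + 0.5) * col_spacing_mm
        y = (rc[:, 0] + 0.5) * row_spacing_mm
        out.append(np.column_stack([x, y]))
    return out
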