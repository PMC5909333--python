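"""Threshold-based infarct delineation and indirect no-flow measurement.

The enhancement threshold is remote-referenced: the mean signal of a remote
myocardial region of interest (at least 100 pixels) plus k standard
deviations, k = 5 by default.  Myocardial pixels with signal strictly over
the threshold are "MI pixels"; the no-flow core is recovered indirectly as
the sub-threshold islands fully enclosed in-plane by enhanced tissue, so
that total MI = enhanced U NF and the NF area equals total minus enhanced
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ContourSet, GeometryError, ImageSeries

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
EIGHT_CONN = np.ones((3, 3), dtype=bool)


class MaskInvariantError(ValueError):
    """RegionMasks set-algebra invariant violated at assembly."""


def myocardium_mask(contours: ContourSet, grid_shape, pixel_spacing_mm,
                    n_slices: int | None = None) -> np.ndarray:
    """Pixels with centres inside the epicardial and outside the endocardial contour."""
    n_slices = contours.n_slices if n_slices is None else n_slices
    if n_slices != contours.n_slices:
        raise ValueError(f"contour set has {contours.n_slices} slices, series {n_slices}")
    out = np.zeros((n_slices,) + tuple(grid_shape), dtype=bool)
    for s in range(n_slices):
        contours.require("endo", s)
        contours.require("epi", s)
        endo = contours.rasterize("endo", s, grid_shape, pixel_spacing_mm)
        epi = contours.rasterize("epi", s, grid_shape, pixel_spacing_mm)
        out[s] = epi & ~endo
    return out


def remote_stats(image2d: np.ndarray, remote_mask2d: np.ndarray):
    """(mean, sample SD, n) over the remote ROI; the ROI must hold >= 100 pixels."""
    image2d = np.asarray(image2d, dtype=float)
    remote_mask2d = np.asarray(remote_mask2d, dtype=bool)
    if image2d.shape != remote_mask2d.shape:
        raise GeometryError("image and remote mask shapes differ")
    n = int(remote_mask2d.sum())
    if n < 100:
        raise ValueError(f"remote ROI holds {n} pixels; at least 100 are required")
    vals = image2d[remote_mask2d]
    return float(vals.mean()), float(np.std(vals, ddof=1)), n


def enhancement_threshold(mean: float, sd: float, k: float = 5.0) -> float:
    """Remote mean + k * SD (k = 5 in the reference protocol)."""
    if sd < 0:
        raise ValueError("SD must be non-negative")
    return float(mean) + float(k) * float(sd)


def classify_enhanced(image2d: np.ndarray, myo_mask2d: np.ndarray,
                      threshold: float) -> np.ndarray:
    """Myocardial pixels with signal strictly over the threshold.

    A pixel exactly at the threshold is not enhanced ("over" is strict).
    """
    image2d = np.asarray(image2d, dtype=float)
    myo_mask2d = np.asarray(myo_mask2d, dtype=bool)
    if image2d.shape != myo_mask2d.shape:
        raise GeometryError("image and myocardium mask shapes differ")
    return myo_mask2d & (image2d > threshold)


def detect_nf(image2d: np.ndarray, myo_mask2d: np.ndarray,
              enhanced_mask2d: np.ndarray, threshold: float) -> np.ndarray:
    """Sub-threshold islands fully enclosed in-plane by enhanced tissue.

    Sub-threshold myocardium is labelled with 4-connectivity while enhanced
    tissue separates with 8-connectivity (the standard foreground/background
    duality).  "Enclosed" is the fixpoint of: a component is *outside* if any
    of its in-plane 8-neighbours lies off the myocardium (cavity, background,
    image border) or belongs to an outside component — i.e. it touches
    remote, non-enclosed myocardium.  The no-flow core is the union of the
    components that are not outside, so every island is walled in by
    enhanced tissue (possibly via other enclosed islands).  An empty result
    is valid: not every infarct has a no-flow core.
    """
    myo_mask2d = np.asarray(myo_mask2d, dtype=bool)
    enhanced_mask2d = np.asarray(enhanced_mask2d, dtype=bool)
    if np.any(enhanced_mask2d & ~myo_mask2d):
        raise ValueError("enhanced mask must lie within the myocardium")
    sub = myo_mask2d & ~enhanced_mask2d
    labels, n_comp = ndimage.label(sub, structure=FOUR_CONN)
    if n_comp == 0:
        return np.zeros_like(sub)
    rings = {}
    outside = set()
    edge = np.zeros_like(sub)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    for comp in range(1, n_comp + 1):
        m = labels == comp
        rings[comp] = ndimage.binary_dilation(m, structure=EIGHT_CONN) & ~m
        if np.any(rings[comp] & ~myo_mask2d) or np.any(m & edge):
            outside.add(comp)
    changed = True
    while changed:
        changed = False
        out_mask = np.isin(labels, sorted(outside)) & (labels > 0)
        for comp in range(1, n_comp + 1):
            if comp not in outside and np.any(rings[comp] & out_mask):
                outside.add(comp)
                changed = True
    nf = (labels > 0) & ~np.isin(labels, sorted(outside))
    return nf


@dataclass
class RegionMasks:
    """Per-slice boolean partitions with their thresholds and remote statistics."""

    myocardium: np.ndarray       # (slice, row, col)
    remote: np.ndarray
    enhanced: np.ndarray
    nf: np.ndarray
    remote_mean: np.ndarray      # per slice, a.u.
    remote_sd: np.ndarray
    threshold: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float

    def __post_init__(self):
        for name, m in (("remote", self.remote), ("enhanced", self.enhanced),
                        ("nf", self.nf)):
            if np.any(m & ~self.myocardium):
                raise MaskInvariantError(f"{name} mask extends outside the myocardium")
        if np.any(self.enhanced & self.nf):
            raise MaskInvariantError("enhanced and NF masks must be disjoint")
        if np.any(self.remote & self.total_mi):
            raise MaskInvariantError("remote ROI overlaps the infarct")
        for s in range(self.myocardium.shape[0]):
            n = int(self.remote[s].sum())
            if n < 100:
                raise MaskInvariantError(
                    f"remote ROI on slice {s} holds {n} pixels; at least 100 required")

    @property
    def total_mi(self) -> np.ndarray:
        return self.enhanced | self.nf

    @property
    def n_slices(self) -> int:
        return self.myocardium.shape[0]

    def report(self) -> pd.DataFrame:
        """Per-slice CSV-ready summary (areas in mm^2)."""
        sr, sc = self.pixel_spacing_mm
        px_mm2 = sr * sc
        rows = []
        for s in range(self.n_slices):
            rows.append({
                "slice": s,
                "remote_mean_au": self.remote_mean[s],
                "remote_sd_au": self.remote_sd[s],
                "threshold_au": self.threshold[s],
                "myocardium_area_mm2": self.myocardium[s].sum() * px_mm2,
                "enhanced_area_mm2": self.enhanced[s].sum() * px_mm2,
                "nf_area_mm2": self.nf[s].sum() * px_mm2,
                "total_mi_area_mm2": self.total_mi[s].sum() * px_mm2,
            })
        return pd.DataFrame(rows)


def nf_from_manual_contour(contours: ContourSet, slice_index: int, grid_shape,
                           pixel_spacing_mm, myo_mask2d: np.ndarray,
                           enhanced_mask2d: np.ndarray) -> np.ndarray:
    """No-flow mask from a manually drawn contour (the "MVO"-style path).

    Pixels of the contour that fall on enhanced tissue are clipped out of the
    no-flow mask (with a warning) so that enhanced and NF stay disjoint and
    total MI remains their union.
    """
    sl = contours.slices[slice_index]
    if "nf" not in sl:
        return np.zeros_like(myo_mask2d)
    nf = contours.rasterize("nf", slice_index, grid_shape, pixel_spacing_mm)
    nf &= myo_mask2d
    overlap = int((nf & enhanced_mask2d).sum())
    if overlap:
        warnings.warn(
            f"slice {slice_index}: manual NF contour overlaps {overlap} enhanced "
            "pixels; overlap assigned to the enhanced class", stacklevel=2)
        nf &= ~enhanced_mask2d
    return nf


def segment_lge(series: ImageSeries, contours: ContourSet, k: float = 5.0,
                manual_nf: bool = False) -> RegionMasks:
    """Full threshold pipeline on an IR post-contrast stack.

    Thresholds are per slice, from each slice's own remote ROI (inversion
    nulling and coil shading vary slice to slice).
    """
    grid = series.grid_shape
    spacing = series.pixel_spacing_mm
    myo = myocardium_mask(contours, grid, spacing, n_slices=series.n_slices)
    remote = np.zeros_like(myo)
    enhanced = np.zeros_like(myo)
    nf = np.zeros_like(myo)
    means = np.zeros(series.n_slices)
    sds = np.zeros(series.n_slices)
    thresholds = np.zeros(series.n_slices)
    for s in range(series.n_slices):
        img = series.voxels[s]
        remote[s] = contours.rasterize("remote", s, grid, spacing) & myo[s]
        means[s], sds[s], _ = remote_stats(img, remote[s])
        thresholds[s] = enhancement_threshold(means[s], sds[s], k)
        enhanced[s] = classify_enhanced(img, myo[s], thresholds[s])
        if manual_nf:
            nf[s] = nf_from_manual_contour(contours, s, grid, spacing, myo[s], enhanced[s])
        else:
            nf[s] = detect_nf(img, myo[s], enhanced[s], thresholds[s])
        remote[s] &= ~(enhanced[s] | nf[s])
    return RegionMasks(
        myocardium=myo, remote=remote, enhanced=enhanced, nf=nf,
        remote_mean=means, remote_sd=sds, threshold=thresholds,
        pixel_spacing_mm=spacing, slice_thickness_mm=series.slice_thickness_mm)
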