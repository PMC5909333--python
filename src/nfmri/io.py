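"""Image and contour I/O.

Image stacks travel as NIfTI (.nii/.nii.gz) with a JSON sidecar holding the
sequence metadata NIfTI has no slot for (series kind, echo times or inversion
time + post-contrast minute).  Contours travel as JSON with per-slice named
polygons in millimetre world coordinates, so they survive resampling; the
pixel-centre conversion convention lives in :mod:`nfmri.geometry`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import shapely

from .geometry import rasterize_polygon

T2_MULTI_ECHO = "t2-multi-echo"
IR_LGE = "ir-lge"


class FormatError(ValueError):
    """Missing or inconsistent file-format metadata."""


class GeometryError(ValueError):
    """Voxel-geometry metadata disagrees with the data."""


class ContourValidationError(ValueError):
    """A contour set violates its structural invariants."""


@dataclass
class ImageSeries:
    """A short-axis stack with voxel geometry and acquisition metadata.

    ``voxels`` is (slice, row, col) for single-contrast series or
    (slice, echo, row, col) for the multi-echo T2 series.
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float]  # (row, col)
    slice_thickness_mm: float
    kind: str
    echo_times_ms: tuple[float, ...] | None = None
    ti_ms: float | None = None
    post_contrast_min: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        sp = tuple(float(s) for s in self.pixel_spacing_mm)
        if len(sp) != 2 or min(sp) <= 0 or self.slice_thickness_mm <= 0:
            raise GeometryError("pixel spacing and slice thickness must be positive")
        self.pixel_spacing_mm = sp
        if self.kind == T2_MULTI_ECHO:
            if self.echo_times_ms is None:
                raise FormatError("t2-multi-echo series requires echo_times_ms")
            te = tuple(float(t) for t in self.echo_times_ms)
            if len(te) != self.voxels.shape[1] or self.voxels.ndim != 4:
                raise FormatError("echo axis must match echo_times_ms on a 4-D stack")
            if any(b <= a for a, b in zip(te, te[1:])):
                raise FormatError("echo times must be strictly increasing")
            self.echo_times_ms = te
        elif self.kind == IR_LGE:
            if self.ti_ms is None or self.post_contrast_min is None:
                raise FormatError("ir-lge series requires ti_ms and post_contrast_min")
            if self.voxels.ndim != 3:
                raise FormatError("ir-lge stack must be 3-D (slice, row, col)")
        else:
            raise FormatError(f"unknown series kind {self.kind!r}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.voxels.shape[-2], self.voxels.shape[-1]


def write_series(series: ImageSeries, path) -> Path:
    """Write NIfTI + sidecar JSON; returns the NIfTI path."""
    path = Path(path)
    # nibabel axis order (i, j, k[, t]) = (col, row, slice[, echo])
    if series.voxels.ndim == 4:
        data = np.transpose(series.voxels, (3, 2, 0, 1))
    else:
        data = np.transpose(series.voxels, (2, 1, 0))
    sr, sc = series.pixel_spacing_mm
    affine = np.diag([sc, sr, series.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header.set_zooms((sc, sr, series.slice_thickness_mm) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, path)
    meta = {
        "kind": series.kind,
        "pixel_spacing_mm": list(series.pixel_spacing_mm),
        "slice_thickness_mm": series.slice_thickness_mm,
        "echo_times_ms": list(series.echo_times_ms) if series.echo_times_ms else None,
        "ti_ms": series.ti_ms,
        "post_contrast_min": series.post_contrast_min,
        "extra": series.extra,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_series(path) -> ImageSeries:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    # undo the (col, row, slice[, echo]) on-disk ordering
    voxels = np.transpose(data, (2, 3, 1, 0) if data.ndim == 4 else (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    sp = meta.get("pixel_spacing_mm")
    if sp is None or meta.get("slice_thickness_mm") is None:
        raise FormatError("sidecar lacks voxel geometry")
    if not np.allclose([sp[1], sp[0], meta["slice_thickness_mm"]], zooms, rtol=1e-5):
        raise GeometryError(f"sidecar spacing {sp} disagrees with NIfTI zooms {zooms}")
    return ImageSeries(
        voxels=voxels,
        pixel_spacing_mm=tuple(sp),
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
        kind=meta.get("kind", ""),
        echo_times_ms=tuple(meta["echo_times_ms"]) if meta.get("echo_times_ms") else None,
        ti_ms=meta.get("ti_ms"),
        post_contrast_min=meta.get("post_contrast_min"),
        extra=meta.get("extra", {}),
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


@dataclass
class ContourSet:
    """Per-slice named polygons ("endo", "epi", "remote", optional "nf").

    ``slices[i]`` maps name -> (N, 2) array of [x_mm, y_mm] vertices.  The
    "nf" entry may hold a list of polygons (the no-flow core can split).
    """

    slices: list[dict]

    REQUIRED = ("endo", "epi", "remote")

    def __post_init__(self):
        for i, sl in enumerate(self.slices):
            for name, poly in sl.items():
                for j, p in enumerate(_as_polygon_list(poly)):
                    arr = np.asarray(p, dtype=float)
                    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
                        raise ContourValidationError(
                            f"slice {i} contour {name!r}: need an (N>=3, 2) vertex array")
                    ring = shapely.LinearRing(arr)
                    if not ring.is_simple:
                        raise ContourValidationError(
                            f"slice {i} contour {name!r} (part {j}) is self-intersecting")
            if "endo" in sl and "epi" in sl:
                endo = shapely.Polygon(np.asarray(sl["endo"], dtype=float))
                epi = shapely.Polygon(np.asarray(sl["epi"], dtype=float))
                if not epi.contains(endo):
                    raise ContourValidationError(
                        f"slice {i}: endo contour is not strictly inside epi")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def require(self, name: str, slice_index: int) -> np.ndarray:
        sl = self.slices[slice_index]
        if name not in sl:
            raise ContourValidationError(f"slice {slice_index} lacks contour {name!r}")
        return np.asarray(sl[name], dtype=float)

    def rasterize(self, name: str, slice_index: int, grid_shape, pixel_spacing_mm) -> np.ndarray:
        """Pixel-centre mask of one named contour on one slice."""
        sl = self.slices[slice_index]
        if name not in sl:
            raise ContourValidationError(f"slice {slice_index} lacks contour {name!r}")
        n_rows, n_cols = grid_shape
        sr, sc = pixel_spacing_mm
        mask = np.zeros(grid_shape, dtype=bool)
        for poly in _as_polygon_list(sl[name]):
            mask |= rasterize_polygon(np.asarray(poly, dtype=float), n_rows, n_cols, sr, sc)
        return mask


def _as_polygon_list(poly_or_list):
    if isinstance(poly_or_list, (list, tuple)) and len(poly_or_list) and np.ndim(poly_or_list[0]) == 2:
        return list(poly_or_list)
    return [poly_or_list]


def write_contours(cs: ContourSet, path) -> Path:
    path = Path(path)
    payload = []
    for sl in cs.slices:
        entry = {}
        for name, poly in sl.items():
            parts = [np.asarray(p, dtype=float).tolist() for p in _as_polygon_list(poly)]
            entry[name] = parts if len(parts) > 1 else parts[0]
        payload.append(entry)
    path.write_text(json.dumps({"slices": payload}, sort_keys=True))
    return path


def read_contours(path) -> ContourSet:
    payload = json.loads(Path(path).read_text())
    if "slices" not in payload:
        raise FormatError("contour file lacks a 'slices' list")
    slices = []
    for entry in payload["slices"]:
        sl = {}
        for name, poly in entry.items():
            if len(poly) and np.ndim(poly[0]) == 2:
                sl[name] = [np.asarray(p, dtype=float) for p in poly]
            else:
                sl[name] = np.asarray(poly, dtype=float)
        slices.append(sl)
    return ContourSet(slices=slices)
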