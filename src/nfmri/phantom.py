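"""Synthetic short-axis cardiac phantom with exact ground truth.

The phantom is a left-ventricular annulus (endo/epi circles) carrying a
transmural infarct sector whose core is a no-flow (NF) region: on
inversion-recovery post-contrast images the infarct rim enhances brightly
while the NF core stays at or below the nulled remote myocardium, and the
true NF volume shrinks over the post-contrast period.  Tissue signal follows
two textbook signal equations only:

* spin-echo decay        SI = SI0 * exp(-TE / T2)
* magnitude IR recovery  SI = M0 * |1 - 2 * exp(-TI / T1)|

Contrast kinetics are not mechanistically simulated; the PhantomSpec dictates the
true NF volume at each post-contrast minute and the generator realises it by
eroding the initial core along its internal distance transform, so parameter
recovery can be judged against exact voxel-count ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import ndimage

from .geometry import (
    annular_sector_polygon,
    circle_polygon,
    mask_to_contours_mm,
    pixel_centers_mm,
    polygon_area_correction,
    rasterize_polygon,
    wrapped_angle_distance,
)
from .io import IR_LGE, T2_MULTI_ECHO, ContourSet, ImageSeries

# tissue class labels
BACKGROUND, BLOOD, REMOTE, ENHANCED, NF = 0, 1, 2, 3, 4
CLASS_NAMES = {BACKGROUND: "background", BLOOD: "blood", REMOTE: "remote",
               ENHANCED: "enhanced", NF: "nf"}

DEFAULT_ECHO_TIMES_MS = (12.0, 20.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0)
DEFAULT_TIMEPOINTS_MIN = (2.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0)


class SizingError(ValueError):
    """A requested target volume cannot be realised within the geometry."""


# ---------------------------------------------------------------------------
# signal models


def t2_signal(si0, te_ms, t2_ms):
    """Mono-exponential spin-echo signal SI0 * exp(-TE / T2)."""
    si0 = np.asarray(si0, dtype=float)
    te_ms = np.asarray(te_ms, dtype=float)
    t2_ms = np.asarray(t2_ms, dtype=float)
    if np.any(t2_ms <= 0):
        raise ValueError("T2 must be positive")
    if np.any(si0 < 0) or np.any(te_ms < 0):
        raise ValueError("SI0 and TE must be non-negative")
    return si0 * np.exp(-te_ms / t2_ms)


def ir_signal(m0, ti_ms, t1_ms):
    """Magnitude inversion-recovery signal M0 * |1 - 2 exp(-TI / T1)|.

    The recovery term over the repetition interval is neglected (long
    effective TR between inversions); TR and flip angle are carried as
    acquisition metadata only.
    """
    m0 = np.asarray(m0, dtype=float)
    ti_ms = np.asarray(ti_ms, dtype=float)
    t1_ms = np.asarray(t1_ms, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("T1 must be positive")
    if np.any(m0 < 0) or np.any(ti_ms <= 0):
        raise ValueError("M0 must be non-negative and TI positive")
    return m0 * np.abs(1.0 - 2.0 * np.exp(-ti_ms / t1_ms))


def nulling_ti(t1_ms):
    """Inversion time that nulls a tissue of the given T1: TI = T1 * ln 2."""
    t1_ms = np.asarray(t1_ms, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("T1 must be positive")
    return t1_ms * math.log(2.0)


# ---------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class TissueParams:
    """Per-class relaxation and signal-scale parameters."""

    t2_ms: float
    t1_pre_ms: float
    proton_scale: float


@dataclass(frozen=True)
class Washout:
    """Mono-exponential contrast concentration C(t) = amp * exp(-t / tau) [mM].

    ``tau_min=None`` means a constant concentration.
    """

    amplitude_mM: float
    tau_min: float | None = None

    def concentration(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        if self.tau_min is None:
            return np.full_like(t, self.amplitude_mM, dtype=float)
        return self.amplitude_mM * np.exp(-t / self.tau_min)


def _default_tissue():
    # T2 values: reperfused-group regional means; pre-contrast T1 values are
    # phantom assumptions (not reported measurements) — see docs/methods.md.
    return {
        "remote": TissueParams(t2_ms=57.0, t1_pre_ms=900.0, proton_scale=1000.0),
        "enhanced": TissueParams(t2_ms=94.0, t1_pre_ms=1200.0, proton_scale=1000.0),
        "nf": TissueParams(t2_ms=56.0, t1_pre_ms=900.0, proton_scale=1000.0),
        "blood": TissueParams(t2_ms=250.0, t1_pre_ms=1400.0, proton_scale=1100.0),
    }


def _default_washout():
    # NF tracks 0.95 x remote concentration so its post-contrast T1 sits just
    # past the remote null point: dark at every TI, below the 5-SD threshold.
    return {
        "remote": Washout(0.30, 60.0),
        "enhanced": Washout(1.00, None),
        "nf": Washout(0.285, 60.0),
        "blood": Washout(1.30, 45.0),
    }


def _reperfused_nf_curve():
    return {2.0: 7.7, 10.0: 7.62, 15.0: 7.53, 20.0: 6.2, 25.0: 5.2,
            30.0: 4.2, 35.0: 3.2, 40.0: 2.5, 45.0: 1.82}


def _non_reperfused_nf_curve():
    return {2.0: 8.1, 10.0: 8.02, 15.0: 7.95, 20.0: 7.87, 25.0: 6.5,
            30.0: 5.4, 35.0: 4.4, 40.0: 3.6, 45.0: 3.05}


@dataclass
class PhantomSpec:
    """Parametric description of the phantom; defaults are the reperfused group.

    Voxel geometry follows a typical short-axis protocol: 300-mm field of view on a
    256x256 matrix (1.171875-mm pixels) and 10-mm slices.
    """

    n_rows: int = 256
    n_cols: int = 256
    fov_mm: float = 300.0
    slice_thickness_mm: float = 10.0
    n_slices: int = 6
    lv_center_mm: tuple[float, float] = (150.0, 150.0)
    endo_radius_mm: float = 15.0
    epi_radius_mm: float = 24.0053
    sector_center_rad: float = 0.0
    transmurality: float = 1.0
    target_mi_volume_ml: float = 17.1
    nf_volume_ml_by_time: dict = field(default_factory=_reperfused_nf_curve)
    remote_center_rad: float = math.pi
    remote_halfwidth_rad: float = 0.61
    tissue: dict = field(default_factory=_default_tissue)
    washout: dict = field(default_factory=_default_washout)
    r1_relaxivity: float = 4.5  # L mmol^-1 s^-1
    echo_times_ms: tuple = DEFAULT_ECHO_TIMES_MS
    timepoints_min: tuple = DEFAULT_TIMEPOINTS_MIN
    ege_timepoint_min: float = 2.0
    ege_ti_ms: float = 500.0
    snr_t2: float = 20.0     # image SNR: remote first-echo signal / noise SD
    sigma_t2: float | None = None  # explicit noise SD overrides snr_t2
    sigma_lge: float = 12.0
    noise_model: str = "rician"
    seed: int = 20170629
    contour_vertices: int = 64
    group: str = "reperfused"
    # recorded acquisition metadata, not simulated
    acquisition_metadata: dict = field(default_factory=lambda: {
        "flip_angle_deg": 25.0, "tr_ms": 5.5, "views_per_segment": 16})

    def __post_init__(self):
        if not (self.epi_radius_mm > self.endo_radius_mm > 0):
            raise ValueError("need epi_radius > endo_radius > 0")
        if self.n_rows <= 0 or self.n_cols <= 0 or self.fov_mm <= 0:
            raise ValueError("grid and field of view must be positive")
        if not 0 < self.transmurality <= 1:
            raise ValueError("transmurality must be in (0, 1]")
        te = tuple(float(t) for t in self.echo_times_ms)
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("echo times must be strictly increasing")
        self.echo_times_ms = te
        self.sector_center_rad = float(np.mod(self.sector_center_rad, 2 * math.pi))
        self.remote_center_rad = float(np.mod(self.remote_center_rad, 2 * math.pi))
        curve = {float(k): float(v) for k, v in self.nf_volume_ml_by_time.items()}
        ts = sorted(curve)
        vols = [curve[t] for t in ts]
        if any(b > a + 1e-9 for a, b in zip(vols, vols[1:])):
            raise ValueError("NF volume map must be non-increasing in time")
        if any(v < 0 for v in vols):
            raise ValueError("NF volumes must be non-negative")
        if vols and vols[0] > self.target_mi_volume_ml + 1e-9:
            raise ValueError("target NF volume exceeds target MI volume")
        self.nf_volume_ml_by_time = curve
        self.timepoints_min = tuple(float(t) for t in self.timepoints_min)
        missing = [t for t in self.timepoints_min if t not in curve]
        if missing:
            raise ValueError(f"NF volume map lacks timepoints {missing}")
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValueError("noise_model must be rician, gaussian or none")

    @property
    def effective_sigma_t2(self) -> float:
        """Noise SD of the T2 series.

        Unless overridden, derived from ``snr_t2`` with the conventional
        image-SNR definition: the remote-myocardium signal on the first
        (shortest-TE) echo divided by the noise SD.
        """
        if self.sigma_t2 is not None:
            return self.sigma_t2
        remote = self.tissue["remote"]
        first_echo = remote.proton_scale * math.exp(-self.echo_times_ms[0] / remote.t2_ms)
        return first_echo / self.snr_t2

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        return (self.fov_mm / self.n_rows, self.fov_mm / self.n_cols)

    @property
    def voxel_volume_ml(self) -> float:
        sr, sc = self.pixel_spacing_mm
        return sr * sc * self.slice_thickness_mm / 1000.0

    @classmethod
    def reperfused(cls, **overrides) -> "PhantomSpec":
        """Defaults: LVM 69.4 g, MI 17.1 ml, NF 7.7 -> 1.82 ml over 2-45 min."""
        overrides.setdefault("epi_radius_mm", epi_radius_for_mass(69.4, endo_radius_mm=15.0))
        return replace(cls(), **overrides)

    @classmethod
    def non_reperfused(cls, **overrides) -> "PhantomSpec":
        """LVM 80.2 g, MI 19.4 ml, NF 8.1 -> 3.05 ml; regional T2 63/96/60 ms."""
        tissue = _default_tissue()
        tissue["remote"] = replace(tissue["remote"], t2_ms=63.0)
        tissue["enhanced"] = replace(tissue["enhanced"], t2_ms=96.0)
        tissue["nf"] = replace(tissue["nf"], t2_ms=60.0)
        spec = cls(
            epi_radius_mm=epi_radius_for_mass(80.2, endo_radius_mm=15.0),
            target_mi_volume_ml=19.4,
            nf_volume_ml_by_time=_non_reperfused_nf_curve(),
            tissue=tissue,
            group="non-reperfused",
        )
        return replace(spec, **overrides) if overrides else spec

    def t1_post_ms(self, tissue_class: str, t_min: float) -> float:
        """Post-contrast T1 from fast-exchange relaxivity: R1 = R1_pre + r1*C."""
        params = self.tissue[tissue_class]
        c = float(self.washout[tissue_class].concentration(t_min))
        r1 = 1000.0 / params.t1_pre_ms + self.r1_relaxivity * c
        return 1000.0 / r1

    def ti_for_timepoint(self, t_min: float) -> float:
        """EGE uses the fixed 500-ms TI; LGE nulls the remote myocardium."""
        if t_min == self.ege_timepoint_min:
            return self.ege_ti_ms
        return float(nulling_ti(self.t1_post_ms("remote", t_min)))


def _analytic_epi_radius(lvm_g: float, endo_radius_mm: float, n_slices: int,
                         slice_thickness_mm: float, specific_gravity: float,
                         contour_vertices: int) -> float:
    myo_volume_mm3 = lvm_g / specific_gravity * 1000.0
    slice_area = myo_volume_mm3 / (n_slices * slice_thickness_mm)
    c = polygon_area_correction(contour_vertices)
    return math.sqrt(endo_radius_mm**2 + slice_area / (math.pi * c))


@lru_cache(maxsize=32)
def epi_radius_for_mass(lvm_g: float, endo_radius_mm: float = 15.0,
                        n_slices: int = 6, slice_thickness_mm: float = 10.0,
                        specific_gravity: float = 1.05,
                        contour_vertices: int = 64,
                        grid: tuple[int, int] = (256, 256),
                        fov_mm: float = 300.0,
                        lv_center_mm: tuple[float, float] = (150.0, 150.0)) -> float:
    """Epicardial radius whose *rasterised* annulus carries a target mass.

    Starts from the continuous (polygon-area) solution and then bisects on
    the rasterised voxel count, because lattice fluctuations in the
    pixel-centre count of a near-circular polygon are worth a few percent at
    this resolution.  Deterministic; the result lands within a few voxels of
    the target.
    """
    if lvm_g <= 0:
        raise ValueError("mass must be positive")
    n_rows, n_cols = grid
    sr, sc = fov_mm / n_rows, fov_mm / n_cols
    vox_mm3 = sr * sc * slice_thickness_mm
    n_target = lvm_g / specific_gravity * 1000.0 / (vox_mm3 * n_slices)  # per slice
    endo_poly = circle_polygon(lv_center_mm, endo_radius_mm, contour_vertices)
    n_endo = int(rasterize_polygon(endo_poly, n_rows, n_cols, sr, sc).sum())

    def count(r: float) -> int:
        poly = circle_polygon(lv_center_mm, r, contour_vertices)
        return int(rasterize_polygon(poly, n_rows, n_cols, sr, sc).sum()) - n_endo

    r0 = _analytic_epi_radius(lvm_g, endo_radius_mm, n_slices, slice_thickness_mm,
                              specific_gravity, contour_vertices)
    lo, hi = 0.9 * r0, 1.1 * r0
    while count(lo) > n_target:
        lo = endo_radius_mm + 0.5 * (lo - endo_radius_mm)
    while count(hi) < n_target:
        hi *= 1.05
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if count(mid) < n_target:
            lo = mid
        else:
            hi = mid
    return hi if abs(count(hi) - n_target) <= abs(count(lo) - n_target) else lo


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class PhantomTruth:
    """Exact per-timepoint masks, volumes and contours for a built phantom."""

    spec: PhantomSpec
    contours: ContourSet
    blood_mask: np.ndarray        # (slice, row, col) boolean
    myocardium_mask: np.ndarray
    mi_mask: np.ndarray
    remote_roi_mask: np.ndarray
    nf_masks: dict                # timepoint_min -> boolean mask
    regional_t2_ms: dict          # class name -> true T2

    def __post_init__(self):
        ts = sorted(self.nf_masks)
        for a, b in zip(ts, ts[1:]):
            if np.any(self.nf_masks[b] & ~self.nf_masks[a]):
                raise AssertionError("NF masks must be nested over time")

    @property
    def reference_timepoint_min(self) -> float:
        return min(self.nf_masks)

    def nf_mask(self, t_min: float) -> np.ndarray:
        return self.nf_masks[float(t_min)]

    def class_map(self, t_min: float | None = None) -> np.ndarray:
        """Integer label map; ``t_min=None`` uses the earliest (largest) NF."""
        nf = self.nf_masks[self.reference_timepoint_min if t_min is None else float(t_min)]
        labels = np.full(self.myocardium_mask.shape, BACKGROUND, dtype=np.int8)
        labels[self.blood_mask] = BLOOD
        labels[self.myocardium_mask] = REMOTE
        labels[self.mi_mask] = ENHANCED
        labels[nf] = NF
        return labels

    def volume_ml(self, mask: np.ndarray) -> float:
        return int(mask.sum()) * self.spec.voxel_volume_ml

    @property
    def myocardial_volume_ml(self) -> float:
        return self.volume_ml(self.myocardium_mask)

    @property
    def lvm_g(self) -> float:
        return self.myocardial_volume_ml * 1.05

    @property
    def mi_volume_ml(self) -> float:
        return self.volume_ml(self.mi_mask)

    def nf_volume_ml(self, t_min: float) -> float:
        return self.volume_ml(self.nf_masks[float(t_min)])

    def truth_table(self):
        """Long-form volumes table (timepoint_min, region, volume_ml)."""
        import pandas as pd

        rows = [(float("nan"), "myocardium", self.myocardial_volume_ml),
                (float("nan"), "lvm_g", self.lvm_g)]
        for t in sorted(self.nf_masks):
            rows.append((t, "total_mi", self.mi_volume_ml))
            rows.append((t, "nf", self.nf_volume_ml(t)))
        return pd.DataFrame(rows, columns=["timepoint_min", "region", "volume_ml"])


def build_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterise the geometry and realise the volume targets in voxel counts.

    The MI mask is the ``round(target / voxel)`` myocardial pixels nearest in
    wrapped angle to the sector centre; NF(t) keeps the top-n pixels of the
    one-pixel-eroded MI mask ranked by internal distance transform.  Ties in
    either ordering break lexicographically on (slice, row, col), which makes
    the NF masks nested prefixes of one fixed ordering.
    """
    sr, sc = spec.pixel_spacing_mm
    shape = (spec.n_slices, spec.n_rows, spec.n_cols)
    vox_ml = spec.voxel_volume_ml

    endo_poly = circle_polygon(spec.lv_center_mm, spec.endo_radius_mm, spec.contour_vertices)
    epi_poly = circle_polygon(spec.lv_center_mm, spec.epi_radius_mm, spec.contour_vertices)
    remote_poly = annular_sector_polygon(
        spec.lv_center_mm, spec.endo_radius_mm, spec.epi_radius_mm,
        spec.remote_center_rad, spec.remote_halfwidth_rad)

    endo2d = rasterize_polygon(endo_poly, spec.n_rows, spec.n_cols, sr, sc)
    epi2d = rasterize_polygon(epi_poly, spec.n_rows, spec.n_cols, sr, sc)
    remote2d = rasterize_polygon(remote_poly, spec.n_rows, spec.n_cols, sr, sc)
    myo2d = epi2d & ~endo2d

    blood = np.broadcast_to(endo2d, shape).copy()
    myo = np.broadcast_to(myo2d, shape).copy()

    # --- MI sector by angular proximity, exact voxel count -----------------
    x, y = pixel_centers_mm(spec.n_rows, spec.n_cols, sr, sc)
    cx, cy = spec.lv_center_mm
    theta = np.mod(np.arctan2(y - cy, x - cx), 2 * math.pi)
    radius = np.hypot(x - cx, y - cy)
    wall = spec.epi_radius_mm - spec.endo_radius_mm
    band2d = myo2d & (radius <= spec.endo_radius_mm + spec.transmurality * wall + 1e-9)
    band = np.broadcast_to(band2d, shape)

    n_mi = int(round(spec.target_mi_volume_ml / vox_ml))
    cand = np.argwhere(band)
    if n_mi > len(cand):
        raise SizingError(
            f"target_mi_volume_ml={spec.target_mi_volume_ml} needs {n_mi} voxels but the "
            f"myocardial band holds only {len(cand)}")
    ang = wrapped_angle_distance(theta[cand[:, 1], cand[:, 2]], spec.sector_center_rad)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], ang))
    chosen = cand[order[:n_mi]]
    mi = np.zeros(shape, dtype=bool)
    mi[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True

    remote_roi = np.broadcast_to(remote2d, shape) & myo & ~mi
    for s in range(spec.n_slices):
        n = int(remote_roi[s].sum())
        if n < 100:
            raise SizingError(
                f"remote ROI on slice {s} holds {n} pixels; the threshold method "
                "requires at least 100 — widen remote_halfwidth_rad")

    # --- NF core: eroded MI ranked by internal EDT -------------------------
    base = np.zeros(shape, dtype=bool)
    dist = np.zeros(shape, dtype=float)
    for s in range(spec.n_slices):
        base[s] = ndimage.binary_erosion(mi[s], structure=np.ones((3, 3), dtype=bool))
        dist[s] = ndimage.distance_transform_edt(base[s], sampling=(sr, sc))
    bidx = np.argwhere(base)
    bdist = dist[bidx[:, 0], bidx[:, 1], bidx[:, 2]]
    border = np.lexsort((bidx[:, 2], bidx[:, 1], bidx[:, 0], -bdist))
    ranked = bidx[border]

    nf_masks = {}
    for t, target in sorted(spec.nf_volume_ml_by_time.items()):
        n_nf = int(round(target / vox_ml))
        if n_nf > len(ranked):
            raise SizingError(
                f"nf_volume_ml_by_time[{t}]={target} needs {n_nf} voxels but the eroded "
                f"infarct core holds only {len(ranked)}")
        m = np.zeros(shape, dtype=bool)
        if n_nf:
            sel = ranked[:n_nf]
            m[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        nf_masks[float(t)] = m

    # --- contours ----------------------------------------------------------
    t_ref = min(nf_masks)
    slices = []
    for s in range(spec.n_slices):
        entry = {"endo": endo_poly, "epi": epi_poly, "remote": remote_poly}
        nf_polys = mask_to_contours_mm(nf_masks[t_ref][s], sr, sc)
        if nf_polys:
            entry["nf"] = nf_polys if len(nf_polys) > 1 else nf_polys[0]
        slices.append(entry)
    contours = ContourSet(slices=slices)

    regional_t2 = {name: spec.tissue[name].t2_ms for name in ("remote", "enhanced", "nf", "blood")}
    return PhantomTruth(
        spec=spec, contours=contours, blood_mask=blood, myocardium_mask=myo,
        mi_mask=mi, remote_roi_mask=remote_roi, nf_masks=nf_masks,
        regional_t2_ms=regional_t2)


# ---------------------------------------------------------------------------
# rendering


def _add_noise(noiseless: np.ndarray, sigma: float, model: str,
               rng: np.random.Generator) -> np.ndarray:
    if model == "none" or sigma == 0:
        return noiseless.copy()
    if model == "gaussian":
        return noiseless + rng.normal(0.0, sigma, noiseless.shape)
    if model == "rician":
        re = noiseless + rng.normal(0.0, sigma, noiseless.shape)
        im = rng.normal(0.0, sigma, noiseless.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")


def _class_values(labels: np.ndarray, values: Mapping[int, float]) -> np.ndarray:
    out = np.zeros(labels.shape, dtype=float)
    for label, v in values.items():
        out[labels == label] = v
    return out


def render_t2_series(truth: PhantomTruth, sigma: float | None = None,
                     rng: np.random.Generator | None = None) -> ImageSeries:
    """Multi-echo T2-weighted stack: per-pixel mono-exponential decay + noise."""
    spec = truth.spec
    sigma = spec.effective_sigma_t2 if sigma is None else sigma
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    labels = truth.class_map()
    si0 = _class_values(labels, {BLOOD: spec.tissue["blood"].proton_scale,
                                 REMOTE: spec.tissue["remote"].proton_scale,
                                 ENHANCED: spec.tissue["enhanced"].proton_scale,
                                 NF: spec.tissue["nf"].proton_scale})
    t2 = _class_values(labels, {BLOOD: spec.tissue["blood"].t2_ms,
                                REMOTE: spec.tissue["remote"].t2_ms,
                                ENHANCED: spec.tissue["enhanced"].t2_ms,
                                NF: spec.tissue["nf"].t2_ms})
    t2 = np.where(t2 > 0, t2, 1.0)  # background placeholder; SI0 = 0 there
    te = np.asarray(spec.echo_times_ms)
    noiseless = si0[:, None] * np.exp(-te[None, :, None, None] / t2[:, None])
    voxels = _add_noise(noiseless, sigma, spec.noise_model, rng)
    return ImageSeries(
        voxels=voxels, pixel_spacing_mm=spec.pixel_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm, kind=T2_MULTI_ECHO,
        echo_times_ms=spec.echo_times_ms,
        extra={"group": spec.group, **spec.acquisition_metadata})


def render_lge_series(truth: PhantomTruth, timepoint_min: float,
                      sigma: float | None = None,
                      rng: np.random.Generator | None = None) -> ImageSeries:
    """IR post-contrast stack at one timepoint (EGE at 2 min, LGE thereafter)."""
    spec = truth.spec
    t = float(timepoint_min)
    if t not in spec.nf_volume_ml_by_time:
        raise ValueError(f"timepoint {t} min is not in the acquisition schedule")
    sigma = spec.sigma_lge if sigma is None else sigma
    rng = np.random.default_rng(spec.seed + int(round(10 * t))) if rng is None else rng
    labels = truth.class_map(t)
    ti = spec.ti_for_timepoint(t)
    m0 = _class_values(labels, {c: spec.tissue[CLASS_NAMES[c]].proton_scale
                                for c in (BLOOD, REMOTE, ENHANCED, NF)})
    t1 = _class_values(labels, {c: spec.t1_post_ms(CLASS_NAMES[c], t)
                                for c in (BLOOD, REMOTE, ENHANCED, NF)})
    t1 = np.where(t1 > 0, t1, 1.0)
    noiseless = ir_signal(m0, ti, t1)
    voxels = _add_noise(noiseless, sigma, spec.noise_model, rng)
    return ImageSeries(
        voxels=voxels, pixel_spacing_mm=spec.pixel_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm, kind=IR_LGE,
        ti_ms=ti, post_contrast_min=t,
        extra={"group": spec.group, **spec.acquisition_metadata})


# ---------------------------------------------------------------------------
# volume-level cohort simulation (for the serial-statistics analyses)


def simulate_cohort_volumes(curve: Mapping[float, float], n_subjects: int = 7,
                            subject_scale_sd: float = 0.31,
                            noise_sd_ml: float = 0.25,
                            rng: np.random.Generator | int | None = None):
    """Simulate per-subject NF volume series around a group kinetics curve.

    Each subject scales the whole curve by a lognormal-free multiplicative
    factor N(1, subject_scale_sd) — matching the reported between-animal
    coefficient of variation of NF size (2.4/7.7 ~ 0.31) — plus independent
    per-measurement noise (``noise_sd_ml``, a repeatability assumption).
    Returns (timepoints, matrix) with matrix shaped (subjects, timepoints).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ts = np.array(sorted(curve), dtype=float)
    base = np.array([curve[t] for t in ts], dtype=float)
    scale = rng.normal(1.0, subject_scale_sd, size=(n_subjects, 1))
    noise = rng.normal(0.0, noise_sd_ml, size=(n_subjects, len(ts)))
    return ts, np.clip(base[None, :] * scale + noise, 0.0, None)
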