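"""Volume, mass and fraction metrics from region masks.

Myocardial mass uses the specific gravity of 1.05 g/ml.  The %LVM fractions
(infarct fraction MIF, no-flow fraction NFF) are computed on a volume basis
— the numerator volume over the myocardial volume LVM/1.05 — so numerator
and denominator share units; the literal ml-per-gram ratio differs by the
constant 1.05 and is emitted alongside under an explicit column name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import RegionMasks

MYOCARDIAL_SPECIFIC_GRAVITY_G_PER_ML = 1.05


def mask_volume(mask: np.ndarray, pixel_spacing_mm, slice_thickness_mm: float) -> float:
    """Mask volume in ml: pixel count x row spacing x col spacing x thickness."""
    sr, sc = (float(s) for s in pixel_spacing_mm)
    if sr <= 0 or sc <= 0 or slice_thickness_mm <= 0:
        raise ValueError("spacing and thickness must be positive")
    return float(np.asarray(mask, dtype=bool).sum()) * sr * sc * slice_thickness_mm / 1000.0


def lv_mass(myo_volume_ml: float) -> float:
    """Myocardial mass in g from volume in ml (specific gravity 1.05 g/ml)."""
    if myo_volume_ml < 0:
        raise ValueError("volume must be non-negative")
    return myo_volume_ml * MYOCARDIAL_SPECIFIC_GRAVITY_G_PER_ML


def fractions(mi_ml: float, nf_ml: float, lvm_g: float):
    """(MIF %LVM, NFF %LVM, NFF %MI) on the volume basis.

    With no infarct the %MI fraction is undefined and reported as NaN
    (missing), never as zero.
    """
    if lvm_g <= 0:
        raise ValueError("LVM must be positive")
    if nf_ml > mi_ml + 1e-12:
        raise ValueError("NF volume cannot exceed MI volume")
    if mi_ml == 0 and nf_ml > 0:
        raise ValueError("no-flow volume without infarct volume")
    myo_ml = lvm_g / MYOCARDIAL_SPECIFIC_GRAVITY_G_PER_ML
    mif = 100.0 * mi_ml / myo_ml
    nff_lvm = 100.0 * nf_ml / myo_ml
    nff_mi = 100.0 * nf_ml / mi_ml if mi_ml > 0 else float("nan")
    return mif, nff_lvm, nff_mi


@dataclass
class QuantResult:
    """Volume/mass/fraction metrics for one segmented stack."""

    lv_myocardial_volume_ml: float
    lvm_g: float
    mi_volume_ml: float
    nf_volume_ml: float
    enhanced_volume_ml: float
    mif_pct_lvm: float
    nff_pct_lvm: float
    nff_pct_mi: float
    per_slice: pd.DataFrame

    def __post_init__(self):
        if not (self.nf_volume_ml <= self.mi_volume_ml + 1e-9
                <= self.lv_myocardial_volume_ml + 2e-9):
            raise ValueError("expected nf <= mi <= myocardial volume")

    @property
    def mif_ml_per_g_pct(self) -> float:
        """Literal MI-volume / LVM ratio in ml/g, as a percentage."""
        return 100.0 * self.mi_volume_ml / self.lvm_g

    @property
    def nff_ml_per_g_pct(self) -> float:
        return 100.0 * self.nf_volume_ml / self.lvm_g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "lv_myocardial_volume_ml": self.lv_myocardial_volume_ml,
            "lvm_g": self.lvm_g,
            "mi_volume_ml": self.mi_volume_ml,
            "nf_volume_ml": self.nf_volume_ml,
            "enhanced_volume_ml": self.enhanced_volume_ml,
            "mif_pct_lvm_volume_basis": self.mif_pct_lvm,
            "nff_pct_lvm_volume_basis": self.nff_pct_lvm,
            "nff_pct_mi": self.nff_pct_mi,
            "mif_pct_ml_per_g": self.mif_ml_per_g_pct,
            "nff_pct_ml_per_g": self.nff_ml_per_g_pct,
        }])


def quantify(masks: RegionMasks) -> QuantResult:
    """Convert a RegionMasks partition into volume, mass and fraction metrics."""
    spacing = masks.pixel_spacing_mm
    th = masks.slice_thickness_mm
    myo_ml = mask_volume(masks.myocardium, spacing, th)
    mi_ml = mask_volume(masks.total_mi, spacing, th)
    nf_ml = mask_volume(masks.nf, spacing, th)
    enh_ml = mask_volume(masks.enhanced, spacing, th)
    lvm = lv_mass(myo_ml)
    mif, nff_lvm, nff_mi = fractions(mi_ml, nf_ml, lvm)
    per_slice = masks.report()
    per_slice["myocardium_volume_ml"] = per_slice["myocardium_area_mm2"] * th / 1000.0
    per_slice["total_mi_volume_ml"] = per_slice["total_mi_area_mm2"] * th / 1000.0
    per_slice["nf_volume_ml"] = per_slice["nf_area_mm2"] * th / 1000.0
    return QuantResult(
        lv_myocardial_volume_ml=myo_ml, lvm_g=lvm, mi_volume_ml=mi_ml,
        nf_volume_ml=nf_ml, enhanced_volume_ml=enh_ml, mif_pct_lvm=mif,
        nff_pct_lvm=nff_lvm, nff_pct_mi=nff_mi, per_slice=per_slice)
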