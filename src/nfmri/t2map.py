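"""Pixel-wise two-parameter mono-exponential T2 fitting.

The fit minimises the sum of squared residuals of SI = SI0 * exp(-TE / T2)
in the signal (nonlinear) domain, initialised from a log-linear regression of
ln(SI) on TE over the positive samples.  T2 is constrained to [1, 2000] ms;
pixels that hit a bound, have fewer than three positive samples, or fail to
converge are flagged and excluded from regional statistics.  No Rician
noise-floor correction is applied (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import T2_MULTI_ECHO, GeometryError, ImageSeries

T2_FLOOR_MS = 1.0
T2_CAP_MS = 2000.0

FLAG_OUTSIDE, FLAG_OK, FLAG_FAIL, FLAG_CAPPED = 0, 1, 2, 3


@dataclass
class PixelFit:
    si0: float
    t2_ms: float
    residual: float  # 2-norm of signal-domain residuals
    flag: int

    @property
    def ok(self) -> bool:
        return self.flag == FLAG_OK


def _loglinear_init(si: np.ndarray, te: np.ndarray):
    """Slope/intercept seed from ln(SI) over the positive samples."""
    pos = si > 0
    slope, intercept = np.polyfit(te[pos], np.log(si[pos]), 1)
    si0 = float(np.exp(intercept))
    t2 = -1.0 / slope if slope < 0 else T2_CAP_MS
    return si0, float(np.clip(t2, T2_FLOOR_MS, T2_CAP_MS))


def fit_monoexp(si, te_ms) -> PixelFit:
    """Fit (SI0, T2) to one pixel's echo train.

    Degenerate inputs are contracts, not crashes: an all-zero or
    nearly-all-negative train yields ``flag=FLAG_FAIL``; a non-decaying train
    pegs T2 at the 2000-ms cap and is flagged, never returned as a silent
    huge value.
    """
    si = np.asarray(si, dtype=float).ravel()
    te = np.asarray(te_ms, dtype=float).ravel()
    if si.shape != te.shape or len(te) < 3:
        raise ValueError("need matching SI/TE vectors with at least 3 echoes")
    order = np.argsort(te, kind="stable")  # echo order is irrelevant to the fit
    si, te = si[order], te[order]
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be distinct")
    if int((si > 0).sum()) < 3:
        return PixelFit(np.nan, np.nan, np.nan, FLAG_FAIL)

    x0 = _loglinear_init(si, te)

    def resid(p):
        return p[0] * np.exp(-te / p[1]) - si

    def jac(p):
        e = np.exp(-te / p[1])
        return np.column_stack([e, p[0] * te / p[1] ** 2 * e])

    try:
        sol = least_squares(resid, x0=x0, jac=jac,
                            bounds=([0.0, T2_FLOOR_MS], [np.inf, T2_CAP_MS]),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except Exception:
        return PixelFit(np.nan, np.nan, np.nan, FLAG_FAIL)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return PixelFit(np.nan, np.nan, np.nan, FLAG_FAIL)
    si0, t2 = float(sol.x[0]), float(sol.x[1])
    residual = float(np.linalg.norm(resid(sol.x)))
    eps = 1e-9
    if t2 >= T2_CAP_MS - eps or t2 <= T2_FLOOR_MS + eps or si0 <= 0:
        return PixelFit(si0, t2, residual, FLAG_CAPPED)
    return PixelFit(si0, t2, residual, FLAG_OK)


@dataclass
class T2Map:
    """Per-pixel (SI0, T2) over a mask, with residuals and fit flags."""

    si0: np.ndarray
    t2_ms: np.ndarray
    residual: np.ndarray
    flags: np.ndarray          # FLAG_* codes, FLAG_OUTSIDE off-mask
    mask: np.ndarray
    echo_times_ms: tuple

    @property
    def ok_mask(self) -> np.ndarray:
        return self.flags == FLAG_OK

    @property
    def failure_rate(self) -> float:
        n = int(self.mask.sum())
        return float((self.flags[self.mask] != FLAG_OK).mean()) if n else 0.0


def compute_t2_map(series: ImageSeries, mask: np.ndarray) -> T2Map:
    """Apply :func:`fit_monoexp` to every masked pixel of a multi-echo stack."""
    if series.kind != T2_MULTI_ECHO:
        raise ValueError(f"T2 mapping needs a {T2_MULTI_ECHO} series, got {series.kind!r}")
    mask = np.asarray(mask, dtype=bool)
    expected = (series.n_slices,) + series.grid_shape
    if mask.shape != expected:
        raise GeometryError(f"mask shape {mask.shape} does not match series {expected}")
    te = np.asarray(series.echo_times_ms)
    si0 = np.full(mask.shape, np.nan)
    t2 = np.full(mask.shape, np.nan)
    residual = np.full(mask.shape, np.nan)
    flags = np.full(mask.shape, FLAG_OUTSIDE, dtype=np.int8)
    for s, r, c in np.argwhere(mask):
        fit = fit_monoexp(series.voxels[s, :, r, c], te)
        si0[s, r, c], t2[s, r, c] = fit.si0, fit.t2_ms
        residual[s, r, c], flags[s, r, c] = fit.residual, fit.flag
    return T2Map(si0=si0, t2_ms=t2, residual=residual, flags=flags,
                 mask=mask, echo_times_ms=tuple(series.echo_times_ms))


def region_t2(t2map: T2Map, region_mask: np.ndarray):
    """Regional (mean, sample SD, n) of T2 over successfully fitted pixels."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != t2map.mask.shape:
        raise GeometryError("region mask shape does not match the T2 map")
    if np.any(region_mask & ~t2map.mask):
        raise ValueError("region extends outside the fitted mask")
    sel = region_mask & t2map.ok_mask
    n = int(sel.sum())
    if n < 1:
        raise ValueError("region holds no successfully fitted pixels")
    vals = t2map.t2_ms[sel]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return float(vals.mean()), sd, n
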