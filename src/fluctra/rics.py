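"""Raster-image correlation spectroscopy: model, fitting, ROI pipeline.

The spatial ACF of freely diffusing molecules under raster scanning
factorizes into a diffusion term and a scanning-offset Gaussian:

    G(xi, psi) = gamma/N
               * (1 + 4 D tau / omega_r^2)^-1 (1 + 4 D tau / omega_z^2)^-1/2
               * exp(-((xi dx)^2 + (psi dy)^2)
                      / (omega_r^2 (1 + 4 D tau / omega_r^2)))

with tau = |tau_p xi + tau_l psi| the time lag between the two pixels
(pixel dwell tau_p, line time tau_l) and dx, dy the pixel sizes.  The
scanning term is what couples the pixel size into the decay; without it
the correlation would not depend on the scan geometry at all.

The localized-ROI pipeline mirrors live-cell practice: crop a small ROI
away from bright immobile features, moving-average detrend, spatial ACF,
weighted fit for (D, N), concentration from N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

from .containers import ImageStack, ScanProtocol
from .correlation import SpatialACF, detrend_stack, spatial_acf
from .errors import ImmobileFeatureWarning
from .fcs import FitResult, concentration_from_n
from .psf import GAMMA_1P, PSFModel

__all__ = [
    "RICSModel",
    "RoiSelection",
    "RoiResult",
    "eval_rics_model",
    "fit_rics",
    "localized_roi_analysis",
]


@dataclass(frozen=True)
class RICSModel:
    """RICS correlation model parameters."""

    d: float  # um^2/s
    n: float  # particles in the observation volume (amplitude gamma/N)
    psf: PSFModel
    scan: ScanProtocol

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("D must be >= 0")
        if self.n <= 0:
            raise ValueError("N must be positive")


@dataclass(frozen=True)
class RoiSelection:
    """Rectangular pixel ROI; default 64 x 64 pixels (3.2 x 3.2 um at
    0.05 um/pixel), the size used for localized analysis at the cell
    periphery."""

    x: int
    y: int
    width: int = 64
    height: int = 64

    def physical_size(self, pixel_size: float) -> tuple[float, float]:
        return self.height * pixel_size, self.width * pixel_size

    def as_tuple(self) -> tuple[int, int, int, int]:
        return self.x, self.y, self.width, self.height


@dataclass
class RoiResult:
    """Localized RICS analysis output."""

    fit: FitResult
    sacf: SpatialACF
    mean_image: np.ndarray
    roi: RoiSelection
    warnings: list = field(default_factory=list)


def eval_rics_model(model: RICSModel, xi, psi) -> np.ndarray:
    """Evaluate G(xi, psi) for pixel shifts xi (fast axis) and line shifts
    psi (slow axis); scalars or broadcastable arrays."""
    xi = np.asarray(xi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    scan = model.scan
    psf = model.psf
    tau = np.abs(scan.pixel_dwell * xi + scan.line_time * psi)
    a = 1.0 + 4.0 * model.d * tau / psf.omega_r**2
    b = 1.0 + 4.0 * model.d * tau / psf.omega_z**2
    dx = scan.pixel_size
    spatial = np.exp(-((xi * dx) ** 2 + (psi * dx) ** 2) / (psf.omega_r**2 * a))
    return (GAMMA_1P / model.n) / a / np.sqrt(b) * spatial


def fit_rics(
    sacf: SpatialACF,
    scan: ScanProtocol,
    psf: PSFModel,
    max_xi: int = 16,
    max_psi: int = 8,
    exclude_zero: bool = True,
    fit_baseline: bool = True,
) -> FitResult:
    """Weighted least-squares fit of (D, N) to a spatial ACF.

    PSF and scan timing are fixed.  The (0, 0) point is excluded (its
    shot-noise spike is not described by the diffusion model) and the fit
    region is limited to |xi| <= max_xi, |psi| <= max_psi where the
    correlation carries signal.  A small additive baseline absorbs the
    negative bias that mean subtraction imprints on a finite ROI.
    """
    sel_x = np.abs(sacf.xi) <= max_xi
    sel_y = np.abs(sacf.psi) <= max_psi
    g = sacf.g[np.ix_(sel_y, sel_x)]
    xi = sacf.xi[sel_x]
    psi = sacf.psi[sel_y]
    xx, yy = np.meshgrid(xi, psi)
    mask = np.ones_like(g, dtype=bool)
    if exclude_zero:
        mask &= ~((xx == 0) & (yy == 0))
    weights = None
    if sacf.se is not None:
        se = sacf.se[np.ix_(sel_y, sel_x)]
        floor = np.percentile(se[se > 0], 5) if np.any(se > 0) else 1.0
        weights = 1.0 / np.clip(se, floor, None)

    xf, yf, gf = xx[mask], yy[mask], g[mask]
    wf = weights[mask] if weights is not None else None

    amp0 = float(max(np.max(gf), 1e-6))
    n0 = GAMMA_1P / amp0

    def model_values(d, n, base):
        m = RICSModel(d=max(d, 0.0), n=n, psf=psf, scan=scan)
        return eval_rics_model(m, xf, yf) + base

    # coarse log-spaced scan for a robust D initialization
    d_grid = np.logspace(-2, 3, 26)
    chi = [
        float(np.sum(((model_values(d, n0, 0.0) - gf) * (wf if wf is not None else 1.0)) ** 2))
        for d in d_grid
    ]
    d0 = float(d_grid[int(np.argmin(chi))])

    params = lmfit.Parameters()
    params.add("log10_d", value=np.log10(d0), min=-3.0, max=4.0)
    params.add("n", value=n0, min=1e-6)
    params.add("baseline", value=0.0, vary=fit_baseline)

    def residual(p):
        r = model_values(10.0 ** p["log10_d"].value, p["n"].value, p["baseline"].value) - gf
        return r * wf if wf is not None else r

    out = lmfit.minimize(residual, params, method="leastsq")
    p = out.params
    d_fit = float(10.0 ** p["log10_d"].value)
    n_fit = float(p["n"].value)
    d_err = 0.0
    if p["log10_d"].stderr:
        d_err = abs(d_fit * np.log(10.0) * p["log10_d"].stderr)
    at_bound = (
        abs(p["log10_d"].value - p["log10_d"].min) < 1e-6
        or abs(p["log10_d"].value - p["log10_d"].max) < 1e-6
    )
    if at_bound:
        warnings.warn("fitted D at parameter bound", UserWarning, stacklevel=2)
    derived = {
        "D": d_fit,
        "D_err": d_err,
        "N": n_fit,
        "concentration_nM": concentration_from_n(n_fit, psf),
        "g0": GAMMA_1P / n_fit,
    }
    return FitResult(
        params={"d": d_fit, "n": n_fit, "baseline": float(p["baseline"].value)},
        stderr={
            "d": d_err,
            "n": float(p["n"].stderr) if p["n"].stderr else 0.0,
        },
        redchi=float(out.redchi) if out.redchi is not None else float("nan"),
        residuals=np.asarray(out.residual),
        success=bool(out.success),
        message=str(out.message),
        derived=derived,
        model="rics_2d",
    )


def _immobile_feature_check(crop: np.ndarray, saturation_level: Optional[float]) -> list[str]:
    """Heuristic guard: bright pixels with suppressed temporal fluctuations
    (stuck puncta) or saturated codes corrupt the fluctuation statistics."""
    msgs = []
    mean = crop.mean(axis=0)
    var = crop.var(axis=0)
    med = float(np.median(mean))
    if med > 0:
        bright = mean > 5.0 * med
        still = var < 0.25 * np.maximum(mean, 1e-12)
        if np.any(bright & still):
            msgs.append(
                f"{int(np.sum(bright & still))} bright low-fluctuation pixels in ROI "
                "(immobile feature?); consider relocating the ROI"
            )
    if saturation_level is not None and np.any(crop >= saturation_level):
        msgs.append("saturated pixels in ROI")
    elif np.issubdtype(crop.dtype, np.integer):
        top = np.iinfo(crop.dtype).max
        if np.any(crop >= top):
            msgs.append("saturated pixels in ROI")
    return msgs


def localized_roi_analysis(
    stack: ImageStack,
    roi: RoiSelection,
    psf: PSFModel,
    detrend_window: Optional[int] = 10,
    detector_offset: float = 0.0,
    saturation_level: Optional[float] = None,
    **fit_kwargs,
) -> RoiResult:
    """Localized RICS: crop -> detrend -> spatial ACF -> fit (D, N, C).

    Emits :class:`ImmobileFeatureWarning` if the ROI overlaps bright
    immobile or saturated pixels.  The mean-intensity image of the ROI is
    returned alongside the fit for visual placement control.
    """
    if stack.n_frames < 20:
        raise ValueError("need >= 20 frames")
    crop = stack.crop(*roi.as_tuple())
    msgs = _immobile_feature_check(crop.data, saturation_level)
    for m in msgs:
        warnings.warn(m, ImmobileFeatureWarning, stacklevel=2)
    work = crop
    if detrend_window is not None:
        work = detrend_stack(crop, detrend_window)
    sacf = spatial_acf(work, offset=detector_offset)
    fit = fit_rics(sacf, stack.scan, psf, **fit_kwargs)
    return RoiResult(
        fit=fit,
        sacf=sacf,
        mean_image=crop.data.mean(axis=0),
        roi=roi,
        warnings=msgs,
    )
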