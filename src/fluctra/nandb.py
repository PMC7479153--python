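"""Number & brightness moment analysis.

Per pixel, over the frame axis of a detrended stack:

    N = (<I> - offset)^2 / (sigma^2 - sigma0^2) = eps n / (eps + 1)
    B = (sigma^2 - sigma0^2) / (<I> - offset)   = S (eps + 1)

where eps is the true molecular brightness (counts per molecule per
dwell), n the true particle number, and (S, offset, sigma0^2) the analog
detector calibration.  B is reported on the photon-count scale (divided by
S), where a monomer population sits at B = 1 + eps and oligomer brightness
is additive in subunit count; the subunit count of a complex follows from
the monomeric reference by

    eps_norm = (B_complex - 1) / (B_reference - 1).

The moving-average detrend removes a known fraction of the fast
fluctuation variance; measured variances are divided by the exact
white-noise attenuation factor of the detrend operator before the moment
formulas are applied (see :func:`fluctra.correlation.detrend_variance_factor`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .containers import ImageStack
from .correlation import detrend_stack, detrend_variance_factor
from .errors import (
    CalibrationWarning,
    EmptyResultError,
    EmptySelectionError,
    MultimodalHistogramWarning,
    NormalizationError,
)

__all__ = [
    "DetectorCalibration",
    "BrightnessMaps",
    "BrightnessHistogram",
    "NormalizedBrightness",
    "compute_nandb_maps",
    "calibrate_s_factor",
    "fit_b_histogram",
    "select_pixels_by_box",
    "normalize_brightness",
]


@dataclass(frozen=True)
class DetectorCalibration:
    """Analog-detector calibration: gain S, offset, readout variance.

    Instrument S factors for pseudo photon-counting PMTs typically sit in
    a narrow band (the dark-image method on the reference instrument gave
    6.8-7.3 day to day); S = 1, offset = 0, sigma0^2 = 0 describes an
    ideal photon-counting detector.
    """

    s_factor: float = 1.0
    offset: float = 0.0
    readout_variance: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.s_factor <= 0:
            raise ValueError("S factor must be positive")
        if self.readout_variance < 0:
            raise ValueError("readout variance must be >= 0")


@dataclass
class BrightnessMaps:
    """Per-pixel apparent brightness/number maps plus masks.

    ``b`` is on the photon-count scale (S divided out); masked pixels are
    NaN in ``b``/``n`` and excluded from all downstream statistics.
    """

    b: np.ndarray
    n: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    masks: dict = field(default_factory=dict)
    calibration: DetectorCalibration = DetectorCalibration()
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        """Boolean map of unmasked pixels."""
        ok = np.ones(self.b.shape, dtype=bool)
        for m in self.masks.values():
            ok &= ~m
        return ok

    @property
    def b_values(self) -> np.ndarray:
        """Unmasked B values, flattened."""
        return self.b[self.valid]

    @property
    def intensity_values(self) -> np.ndarray:
        return self.mean[self.valid]


@dataclass
class BrightnessHistogram:
    """B-value histogram with a mode-centred Gaussian fit."""

    bin_edges: np.ndarray
    counts: np.ndarray
    center: float
    width: float
    width_err: float = 0.0
    meta: dict = field(default_factory=dict)


@dataclass
class NormalizedBrightness:
    """Subunit count from brightness normalization."""

    value: float
    uncertainty: float
    b_complex: float
    b_reference: float


def compute_nandb_maps(
    stack: ImageStack,
    calibration: DetectorCalibration = DetectorCalibration(),
    detrend_window: Optional[int] = 10,
    saturation_level: Optional[float] = None,
) -> BrightnessMaps:
    """Per-pixel N&B maps with detector correction and detrending.

    Pixels with sigma^2 <= sigma0^2 or <I> <= offset carry no usable
    fluctuations and are masked ``fluctuation_free``; pixels that hit the
    saturation level (the dtype ceiling for integer stacks, or an explicit
    ``saturation_level``) in any frame are masked ``saturated``.
    """
    if stack.n_frames < 20:
        raise ValueError("need >= 20 frames")
    data = stack.data
    saturated = np.zeros(stack.frame_shape, dtype=bool)
    if saturation_level is not None:
        saturated = (data >= saturation_level).any(axis=0)
    elif np.issubdtype(data.dtype, np.integer):
        saturated = (data >= np.iinfo(data.dtype).max).any(axis=0)
    var_factor = 1.0
    work = stack
    if detrend_window is not None:
        work = detrend_stack(stack, detrend_window)
        var_factor = detrend_variance_factor(stack.n_frames, detrend_window)
    wdata = work.data.astype(float)
    mean = wdata.mean(axis=0)
    variance = wdata.var(axis=0, ddof=1) / var_factor
    off = calibration.offset
    sig0 = calibration.readout_variance
    num = variance - sig0
    den = mean - off
    flat = (num <= 0) | (den <= 0)
    masked = flat | saturated
    if np.all(masked):
        raise EmptyResultError("all pixels masked (no usable fluctuations)")
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(masked, 0.0, num / den / calibration.s_factor)
        n = np.where(masked, 0.0, den * den / num)
    return BrightnessMaps(
        b=b,
        n=n,
        mean=mean,
        variance=variance,
        masks={"fluctuation_free": flat, "saturated": saturated},
        calibration=calibration,
        meta={"detrend_window": detrend_window, "variance_factor": var_factor},
    )


def calibrate_s_factor(
    dark_stack: ImageStack,
    graded_stacks: Optional[Sequence[ImageStack]] = None,
    s_factor: Optional[float] = None,
) -> DetectorCalibration:
    """Detector calibration from a dark image stack.

    offset = grand mean of the dark stack; sigma0^2 = pooled per-pixel
    variance.  The gain S comes from the slope of per-pixel variance
    versus mean across graded-illumination stacks when provided (shot
    noise scales variance as S x signal), otherwise from ``s_factor``
    (default 1).  A drifting dark stack triggers a calibration warning.
    """
    dark = dark_stack.data.astype(float)
    offset = float(dark.mean())
    sigma0 = float(dark.var(axis=0, ddof=1).mean())
    frame_means = dark.mean(axis=(1, 2))
    t = np.arange(frame_means.size)
    slope = float(np.polyfit(t, frame_means, 1)[0])
    drift = abs(slope) * frame_means.size
    scale = max(abs(offset), np.sqrt(max(sigma0, 1e-30)))
    if drift > 0.1 * scale:
        warnings.warn(
            "dark stack mean drifts over the acquisition; calibration suspect",
            CalibrationWarning,
            stacklevel=2,
        )
    s = 1.0 if s_factor is None else float(s_factor)
    if graded_stacks:
        xs, ys = [], []
        for st in graded_stacks:
            d = st.data.astype(float)
            xs.append(d.mean(axis=0).ravel() - offset)
            ys.append(d.var(axis=0, ddof=1).ravel() - sigma0)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        good = x > 0
        if good.sum() < 10:
            raise ValueError("graded stacks carry no signal above the dark offset")
        # regression through the origin: var - sigma0^2 = S (mean - offset)
        s = float(np.sum(x[good] * y[good]) / np.sum(x[good] ** 2))
    return DetectorCalibration(
        s_factor=s, offset=offset, readout_variance=sigma0, source="dark_image"
    )


def _gaussian(x, amp, center, sigma):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fit_b_histogram(
    maps: BrightnessMaps,
    bin_width: float = 0.01,
    min_pixels: int = 1000,
) -> BrightnessHistogram:
    """Histogram of unmasked B values with a mode-centred Gaussian fit.

    The Gaussian centre is fixed at the histogram maximum (the population
    mode) and only amplitude and width are fitted, over a window of +/- 2
    FWHM around the mode; this tracks the majority population even when a
    minority of brighter pixels skews the tail.  Because bin-level shot
    noise makes the raw argmax wander across a flat peak, the maximum is
    located by a Gaussian peak fit constrained to within half a FWHM of
    the smoothed argmax.  A secondary mode above half the primary raises
    :class:`MultimodalHistogramWarning`.
    """
    values = maps.b_values
    values = values[np.isfinite(values)]
    if values.size < min_pixels:
        raise ValueError(f"need >= {min_pixels} unmasked pixels, got {values.size}")
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < bin_width:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # light smoothing so the mode is not set by single-bin shot noise
    k = np.ones(5) / 5.0
    smooth = np.convolve(counts, k, mode="same")
    imode = int(np.argmax(smooth))
    mode = float(centers[imode])
    peaks, _ = find_peaks(
        smooth,
        height=0.5 * smooth[imode],
        distance=5,
        prominence=0.2 * smooth[imode],
    )
    if [p for p in peaks if abs(p - imode) > 10]:
        warnings.warn(
            "brightness histogram has a secondary mode above half the primary",
            MultimodalHistogramWarning,
            stacklevel=2,
        )
    # initial width from half-maximum crossings around the mode
    half = smooth[imode] / 2.0
    right = imode
    while right < smooth.size - 1 and smooth[right] > half:
        right += 1
    left = imode
    while left > 0 and smooth[left] > half:
        left -= 1
    fwhm = max((right - left) * bin_width, bin_width)
    sigma0 = fwhm / 2.3548
    # refine the location of the maximum: bounded Gaussian peak fit around
    # the argmax (the argmax alone is bin-noise-limited on a flat peak)
    refine = np.abs(centers - mode) <= fwhm
    if refine.sum() >= 5 and np.count_nonzero(counts[refine]) >= 5:
        try:
            popt, _ = curve_fit(
                _gaussian,
                centers[refine],
                counts[refine],
                p0=[float(smooth[imode]), mode, sigma0],
                bounds=(
                    [0.0, mode - 0.5 * fwhm, bin_width / 10.0],
                    [np.inf, mode + 0.5 * fwhm, np.inf],
                ),
                maxfev=10000,
            )
            mode = float(popt[1])
        except RuntimeError:
            pass
    win = np.abs(centers - mode) <= 2.0 * fwhm
    if win.sum() < 5:
        win = np.abs(centers - mode) <= 5.0 * bin_width
    width_err = 0.0
    if win.sum() >= 3 and np.count_nonzero(counts[win]) >= 3:
        try:
            popt, pcov = curve_fit(
                lambda x, amp, sig: _gaussian(x, amp, mode, sig),
                centers[win],
                counts[win],
                p0=[float(smooth[imode]), sigma0],
                maxfev=10000,
            )
            sigma = abs(float(popt[1]))
            width_err = float(np.sqrt(np.diag(pcov))[1])
        except RuntimeError:
            sigma = sigma0
    else:
        # degenerate (delta-like) histogram: width limited by binning
        sigma = sigma0
    return BrightnessHistogram(
        bin_edges=edges,
        counts=counts,
        center=mode,
        width=sigma,
        width_err=width_err,
        meta={"bin_width": bin_width, "n_pixels": int(values.size)},
    )


def select_pixels_by_box(
    maps: BrightnessMaps,
    b_range: tuple[float, float],
    intensity_range: tuple[float, float],
) -> tuple[np.ndarray, dict]:
    """Mask of unmasked pixels inside a B x intensity rectangle.

    Returns the boolean mask and a summary with the mean B of the selected
    pixels and the fraction of unmasked pixels captured.
    """
    blo, bhi = b_range
    ilo, ihi = intensity_range
    if bhi < blo or ihi < ilo:
        raise ValueError("ranges must be (low, high)")
    valid = maps.valid
    sel = (
        valid
        & (maps.b >= blo)
        & (maps.b <= bhi)
        & (maps.mean >= ilo)
        & (maps.mean <= ihi)
    )
    n_sel = int(sel.sum())
    if n_sel == 0:
        raise EmptySelectionError("selection box captured no pixels")
    summary = {
        "mean_b": float(np.nanmean(maps.b[sel])),
        "fraction": n_sel / int(valid.sum()),
        "n_pixels": n_sel,
    }
    return sel, summary


def normalize_brightness(
    b_complex: float,
    b_reference: float,
    width_complex: float = 0.0,
    width_reference: float = 0.0,
) -> NormalizedBrightness:
    """Subunit count eps_norm = (B_complex - 1) / (B_reference - 1).

    Both inputs are photon-count-scale apparent brightnesses (monomer
    reference B_reference > 1).  Uncertainty is first-order propagation of
    the two Gaussian widths.
    """
    if b_reference <= 1.0:
        raise NormalizationError(
            "reference brightness must exceed 1 (no molecular fluctuation signal)"
        )
    denom = b_reference - 1.0
    value = (b_complex - 1.0) / denom
    var = (width_complex / denom) ** 2 + (
        (b_complex - 1.0) * width_reference / denom**2
    ) ** 2
    return NormalizedBrightness(
        value=float(value),
        uncertainty=float(np.sqrt(var)),
        b_complex=float(b_complex),
        b_reference=float(b_reference),
    )
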