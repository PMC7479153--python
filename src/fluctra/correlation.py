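"""Temporal and spatial autocorrelation estimators, plus detrending.

Conventions
-----------
Both estimators use the normalized fluctuation autocorrelation

    G = <dI(a) dI(b)> / <I>^2,   dI = I - <I>,

computed after subtracting the detector offset (passed explicitly).  The
temporal estimator offers a brute-force ``direct`` scheme (the oracle) and
the ``multi_tau`` octave-doubling scheme with pairwise block averaging; the
two are identical arithmetic on the linear lags of the first octave.  The
spatial estimator is the per-frame circular (FFT) 2D autocorrelation of the
mean-subtracted ROI, averaged over frames, so G(-xi, -psi) == G(xi, psi)
exactly by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import ImageStack, IntensityTrace
from .errors import DegenerateInputError

__all__ = [
    "TemporalACF",
    "SpatialACF",
    "temporal_acf",
    "spatial_acf",
    "detrend_stack",
    "detrend_variance_factor",
]


@dataclass
class TemporalACF:
    """Lag grid (seconds), G values and optional per-lag standard errors."""

    lags: np.ndarray
    g: np.ndarray
    se: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("G values must be finite")

    @property
    def dwell(self) -> Optional[float]:
        return self.meta.get("dwell")


@dataclass
class SpatialACF:
    """Centred 2D correlation grid over pixel shifts (psi rows, xi columns)."""

    g: np.ndarray
    xi: np.ndarray
    psi: np.ndarray
    se: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def value_at(self, xi: int, psi: int) -> float:
        iy = int(np.where(self.psi == psi)[0][0])
        ix = int(np.where(self.xi == xi)[0][0])
        return float(self.g[iy, ix])


def _acf_raw(x: np.ndarray, lags: np.ndarray, mean: float) -> np.ndarray:
    """<I_t I_{t+k}>_t / mean^2 - 1 for integer sample lags."""
    out = np.empty(lags.size)
    for i, k in enumerate(lags):
        k = int(k)
        out[i] = np.mean(x[: x.size - k] * x[k:]) / mean**2 - 1.0
    return out


def _direct(x: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    lags = np.arange(1, max_lag + 1)
    return lags.astype(float), _acf_raw(x, lags, float(np.mean(x)))


def _multi_tau(x: np.ndarray, m: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Octave-doubling correlator.

    Level 0 evaluates lags 1 .. 2m-1 on the raw series; each following
    level halves the series by pairwise averaging and evaluates lags
    m .. 2m-1 in the decimated sampling, i.e. log-spaced physical lags.
    """
    lags_all: list[np.ndarray] = []
    g_all: list[np.ndarray] = []
    y = x.astype(float)
    scale = 1
    level = 0
    while True:
        mean = float(np.mean(y))
        if level == 0:
            lags = np.arange(1, 2 * m)
        else:
            lags = np.arange(m, 2 * m)
        lags = lags[lags < y.size // 2]
        if lags.size == 0:
            break
        lags_all.append(lags * scale)
        g_all.append(_acf_raw(y, lags, mean))
        if y.size < 4 * m:
            break
        n_even = y.size - (y.size % 2)
        y = 0.5 * (y[0:n_even:2] + y[1:n_even:2])
        scale *= 2
        level += 1
    return (
        np.concatenate(lags_all).astype(float),
        np.concatenate(g_all),
    )


def temporal_acf(
    trace: IntensityTrace,
    scheme: str = "multi_tau",
    max_lag: Optional[int] = None,
    m: int = 16,
    n_segments: int = 1,
    offset: float = 0.0,
) -> TemporalACF:
    """Temporal autocorrelation of an intensity trace.

    Parameters
    ----------
    scheme
        ``"multi_tau"`` (log-spaced, fast) or ``"direct"`` (brute force,
        linear lags up to ``max_lag`` samples).
    n_segments
        When > 1, the trace is split into equal segments, the ACF is
        computed per segment and averaged, and per-lag standard errors of
        the mean are attached (used as fit weights downstream).
    offset
        Detector offset subtracted before normalization.
    """
    x = trace.values - offset
    if x.size < 2**10:
        raise ValueError("trace too short (< 1024 samples)")
    if np.std(x) == 0:
        raise DegenerateInputError("constant trace: correlation undefined")
    if scheme not in ("multi_tau", "direct"):
        raise ValueError(f"unknown scheme {scheme!r}")

    def one(seg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if scheme == "direct":
            ml = max_lag if max_lag is not None else min(seg.size // 4, 4096)
            return _direct(seg, ml)
        return _multi_tau(seg, m=m)

    if n_segments <= 1:
        lags, g = one(x)
        se = None
    else:
        seg_len = x.size // n_segments
        gs = []
        lags = None
        for i in range(n_segments):
            li, gi = one(x[i * seg_len : (i + 1) * seg_len])
            lags = li
            gs.append(gi)
        gmat = np.vstack(gs)
        g = gmat.mean(axis=0)
        se = gmat.std(axis=0, ddof=1) / np.sqrt(n_segments)
    return TemporalACF(
        lags * trace.dwell_time,
        g,
        se=se,
        meta={"dwell": trace.dwell_time, "scheme": scheme, "n_segments": n_segments},
    )


def spatial_acf(
    stack: ImageStack,
    roi: Optional[tuple[int, int, int, int]] = None,
    offset: float = 0.0,
) -> SpatialACF:
    """Frame-averaged 2D spatial autocorrelation of a stack (or ROI).

    Each frame is offset-corrected and mean-subtracted, circularly
    autocorrelated via FFT, normalized by the squared frame mean and the
    pixel count, then averaged over frames.  Per-shift standard errors over
    frames are attached.  ``roi`` is (x, y, width, height) in pixels.
    """
    data = stack.data
    if roi is not None:
        x0, y0, w, h = roi
        stack = stack.crop(x0, y0, w, h)
        data = stack.data
    if data.shape[0] < 20:
        raise ValueError("need >= 20 frames for a spatial ACF")
    data = data.astype(float) - offset
    h, w = data.shape[1], data.shape[2]
    mu = data.mean(axis=(1, 2))
    if np.any(mu == 0) or float(np.var(data)) == 0:
        raise DegenerateInputError("ROI has zero mean or zero variance")
    delta = data - mu[:, None, None]
    ft = np.fft.rfft2(delta, axes=(1, 2))
    corr = np.fft.irfft2(ft * np.conj(ft), s=(h, w), axes=(1, 2))
    g_frames = corr / (h * w) / mu[:, None, None] ** 2
    g_frames = np.fft.fftshift(g_frames, axes=(1, 2))
    g = g_frames.mean(axis=0)
    se = g_frames.std(axis=0, ddof=1) / np.sqrt(data.shape[0])
    xi = np.arange(w) - w // 2
    psi = np.arange(h) - h // 2
    return SpatialACF(
        g, xi, psi, se=se, meta={"n_frames": data.shape[0], "roi": roi}
    )


def _moving_average_frames(data: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along the frame axis with shrinking edges."""
    n = data.shape[0]
    lo_half = (window - 1) // 2
    hi_half = window // 2
    c = np.concatenate(
        [np.zeros((1,) + data.shape[1:]), np.cumsum(data, axis=0)], axis=0
    )
    t = np.arange(n)
    lo = np.maximum(0, t - lo_half)
    hi = np.minimum(n, t + hi_half + 1)
    sums = c[hi] - c[lo]
    counts = (hi - lo).astype(float)
    return sums / counts.reshape((-1,) + (1,) * (data.ndim - 1))


def detrend_stack(stack: ImageStack, window_frames: int = 10) -> ImageStack:
    """Per-pixel moving-average detrend, preserving the grand mean.

    Subtracts the centred moving average over ``window_frames`` frames and
    adds back the pixel's grand mean, removing slow drifts (bleaching, cell
    movement) while keeping physical intensity levels.  Edge frames use a
    symmetric shrinking window; output has the same frame count.
    """
    n = stack.n_frames
    if not 2 <= window_frames < n:
        raise ValueError("window must satisfy 2 <= window < n_frames")
    data = stack.data.astype(float)
    ma = _moving_average_frames(data, window_frames)
    # adding back the time-mean of the moving average (== the grand mean for
    # stationary data) keeps the per-pixel mean exactly unchanged
    out = data - ma + ma.mean(axis=0, keepdims=True)
    meta = dict(stack.meta)
    meta["detrend_window"] = window_frames
    return ImageStack(out, scan=stack.scan, meta=meta)


def detrend_variance_factor(n_frames: int, window: int) -> float:
    """Expected white-noise variance ratio after :func:`detrend_stack`.

    The detrend is a linear operator A on the frame axis; for i.i.d. input
    of variance sigma^2 the expected per-pixel sample variance of A x is
    c * sigma^2 with c = trace(M^T M) / (n - 1), M the mean-centred A.
    Moment analysis divides measured variances by this factor (for
    window = w and long stacks, c ~ 1 - 1/w).
    """
    n, w = int(n_frames), int(window)
    mov = _moving_average_frames(np.eye(n), w)
    a = np.eye(n) - mov + mov.mean(axis=0, keepdims=True)
    m = a - a.mean(axis=0, keepdims=True)
    return float(np.trace(m.T @ m) / (n - 1))
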