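"""Compiled inner loop for the streaming raster-scan renderer.

Per scan line, particles too far from the line to contribute take a single
Brownian jump over the line time; particles near the line are propagated
on a fine substep grid (substep displacement <= omega_r/3) across the
substeps their pixel window actually samples, with single Gaussian jumps
bridging the unsampled head and tail of the line.  This is an exact
decomposition of Brownian motion (independent Gaussian increments), not an
approximation, up to the negligible probability that a "far" particle
reaches the detection volume mid-jump — the near cutoffs include a 3-sigma
motion margin.

Normal variates come from an inline xorshift64* + Box-Muller generator
(the per-call overhead of the library generator dominates the render
otherwise); Poisson pixel counts use numba's seeded global generator.
Both are seeded from the caller, so output is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INV_2_53 = 1.0 / 9007199254740993.0
_TWO_PI = 6.283185307179586


@njit(inline="always", cache=True)
def _u01(state):
    """Uniform in (0, 1] from xorshift64*."""
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    y = x * np.uint64(2685821657736338717)
    return ((y >> np.uint64(11)) + np.uint64(1)) * _INV_2_53


@njit(inline="always", cache=True)
def _normal(state, spare):
    """Standard normal via Box-Muller with spare caching.

    ``spare`` is a 2-slot float64 scratch: [cached value, have-flag].
    """
    if spare[1] > 0.5:
        spare[1] = 0.0
        return spare[0]
    u1 = _u01(state)
    u2 = _u01(state)
    r = np.sqrt(-2.0 * np.log(u1))
    a = _TWO_PI * u2
    spare[0] = r * np.sin(a)
    spare[1] = 1.0
    return r * np.cos(a)


@njit(inline="always", cache=True)
def _wrap1(v, length):
    return v - length * np.floor(v / length + 0.5)


@njit(cache=True)
def raster_kernel(
    seed,
    pos,  # (n, 3) positions, modified in place
    sig_line,  # (n,) Brownian sigma over one line time
    sig_sub,  # (n,) Brownian sigma over one substep
    sig_gap,  # (n,) Brownian sigma over the inter-frame gap (0 if none)
    has_gap,
    brightness,  # (n,) counts/dwell at beam centre
    ycut,  # (n,) near-line cutoff in y
    zcut_near,  # (n,) near-line cutoff in z
    xcut,  # (n,) contribution cutoff in x incl. motion margin
    lx,
    ly,
    lz,
    periodic_x,
    xs,  # (cols,) pixel centre x
    ys,  # (rows,) line centre y
    sub_of_px,  # (cols,) substep index sampling each pixel
    n_sub,
    pixel_size,
    r2cut,
    zcut_c,
    inv_wr2,
    inv_wz2,
    env,  # (frames*rows,) bleaching envelope per line
    out,  # (frames, rows, cols) Poisson counts, written
):
    np.random.seed(seed)
    state = np.empty(1, np.uint64)
    state[0] = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(
        1442695040888963407
    )
    for _ in range(8):
        _u01(state)
    spare = np.zeros(2)
    n_frames, rows, cols = out.shape
    n = pos.shape[0]
    xk = np.empty(n_sub)
    yk = np.empty(n_sub)
    zk = np.empty(n_sub)
    lam = np.empty(cols)
    half_x = 0.5 * lx
    half_y = 0.5 * ly
    half_z = 0.5 * lz
    for f in range(n_frames):
        for r in range(rows):
            yr = ys[r]
            for j in range(cols):
                lam[j] = 0.0
            for i in range(n):
                dy0 = pos[i, 1] - yr
                dy0 -= ly * np.round(dy0 / ly)
                near = abs(dy0) <= ycut[i] and abs(pos[i, 2]) <= zcut_near[i]
                j0 = 0
                j1 = -1
                full_range = False
                if near:
                    xc = pos[i, 0]
                    j0 = int(np.floor((xc - xcut[i]) / pixel_size + cols * 0.5))
                    j1 = int(np.ceil((xc + xcut[i]) / pixel_size + cols * 0.5))
                    if j1 - j0 + 1 >= cols:
                        j0 = 0
                        j1 = cols - 1
                        full_range = True
                    elif periodic_x:
                        if j0 < 0 or j1 >= cols:
                            full_range = True
                    else:
                        if j0 < 0:
                            j0 = 0
                        if j1 > cols - 1:
                            j1 = cols - 1
                        if j0 > j1:
                            near = False  # window off-frame: nothing to sample
                if not near:
                    pos[i, 0] = _wrap1(
                        pos[i, 0] + _normal(state, spare) * sig_line[i], lx
                    )
                    pos[i, 1] = _wrap1(
                        pos[i, 1] + _normal(state, spare) * sig_line[i], ly
                    )
                    pos[i, 2] = _wrap1(
                        pos[i, 2] + _normal(state, spare) * sig_line[i], lz
                    )
                    continue
                if full_range:
                    k_lo = 0
                    k_hi = n_sub - 1
                else:
                    k_lo = sub_of_px[j0]
                    k_hi = sub_of_px[j1]
                x = pos[i, 0]
                y = pos[i, 1]
                z = pos[i, 2]
                s = sig_sub[i]
                # bridge from line start to the first sampled substep
                if k_lo > 0:
                    sj = s * np.sqrt(k_lo)
                    x = _wrap1(x + _normal(state, spare) * sj, lx)
                    y = _wrap1(y + _normal(state, spare) * sj, ly)
                    z = _wrap1(z + _normal(state, spare) * sj, lz)
                for k in range(k_lo, k_hi + 1):
                    x += _normal(state, spare) * s
                    y += _normal(state, spare) * s
                    z += _normal(state, spare) * s
                    if x < -half_x:
                        x += lx
                    elif x >= half_x:
                        x -= lx
                    if y < -half_y:
                        y += ly
                    elif y >= half_y:
                        y -= ly
                    if z < -half_z:
                        z += lz
                    elif z >= half_z:
                        z -= lz
                    xk[k] = x
                    yk[k] = y
                    zk[k] = z
                for jraw in range(j0, j1 + 1):
                    if periodic_x:
                        jm = jraw % cols
                    else:
                        jm = jraw
                    k = sub_of_px[jm]
                    dx = xk[k] - xs[jm]
                    if periodic_x:
                        dx -= lx * np.round(dx / lx)
                    dyy = yk[k] - yr
                    dyy -= ly * np.round(dyy / ly)
                    r2 = dx * dx + dyy * dyy
                    zz = zk[k]
                    if r2 < r2cut and abs(zz) < zcut_c:
                        lam[jm] += brightness[i] * np.exp(
                            -2.0 * r2 * inv_wr2 - 2.0 * zz * zz * inv_wz2
                        )
                # bridge from the last sampled substep to the line end
                tail = n_sub - 1 - k_hi
                if tail > 0:
                    sj = s * np.sqrt(tail)
                    x = _wrap1(x + _normal(state, spare) * sj, lx)
                    y = _wrap1(y + _normal(state, spare) * sj, ly)
                    z = _wrap1(z + _normal(state, spare) * sj, lz)
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
            e = env[f * rows + r]
            for j in range(cols):
                out[f, r, j] = np.random.poisson(lam[j] * e)
        if has_gap:
            for i in range(n):
                pos[i, 0] = _wrap1(pos[i, 0] + _normal(state, spare) * sig_gap[i], lx)
                pos[i, 1] = _wrap1(pos[i, 1] + _normal(state, spare) * sig_gap[i], ly)
                pos[i, 2] = _wrap1(pos[i, 2] + _normal(state, spare) * sig_gap[i], lz)
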