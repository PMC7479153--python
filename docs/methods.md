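# Methods

This note records the models implemented in `fluctra`, the assumptions
behind them, the numerical choices made where the underlying publications
of these techniques leave the design open, and what the synthetic-data
generator does and does not emulate.

## Observation model

All three analyses share one forward model. The confocal detection
profile is a 3D Gaussian,

    f(x, y, z) = exp(−2(x² + y²)/ω_r² − 2z²/ω_z²),

parameterized by the radial waist ω_r (µm), the structural factor
S = ω_r/ω_z (default 0.2, i.e. a 5:1 elongated volume) and the one-photon
geometric factor γ = ∫f²/∫f = 2^(−3/2) = 0.3536. A particle carrying q
fluorescent subunits, each with center brightness ε₁ (expected photon
counts per dwell when the particle sits at the beam center), contributes
q·ε₁·f(r) to the expected count rate; the recorded count per dwell is
Poisson. For uniformly distributed particles of concentration C this
model gives exactly

    ⟨I⟩ = C·q ε₁·V_3DG,      Var(I) = ⟨I⟩ + C·(q ε₁)²·γ·V_3DG,
    G(0) = γ/(C·V_3DG),      B − 1 = γ·q ε₁,

with V_3DG = ω_r² ω_z (π/2)^(3/2). Three consequences worth keeping in
mind:

* the "true molecular brightness" ε of moment analysis relates to the
  center brightness by ε = γ·q ε₁ — apparent brightness averages over the
  Gaussian volume;
* the concentration relation C = 1/(G(0)·N_A·V_eff) with
  V_eff = 2^(3/2)·V_3DG is exact under this model (γ·2^(3/2) = 1). The
  package implements it literally; the alternative convention
  C = N/(N_A V_eff) with N = γ/G(0), which differs by the factor γ, is
  available via `concentration_from_g0(..., include_gamma=True)`;
* N&B's apparent number N = γ/G(0) = C·V_3DG converts to the occupancy of
  the effective volume through n = N(ε+1)/ε.

## Synthetic-data generator

Particles follow free Brownian motion (Gaussian steps of variance 2DΔt
per axis) in a periodic box, with constant particle number. Species are
defined by (D, ε₁, q, number density); per-species particle counts are
the rounded expectation density × box volume, so sub-volume occupancy is
binomial ≈ Poisson. Detector models: ideal photon counting, or analog
"pseudo photon counting" with I = S·counts + offset + N(0, σ₀²) —
Gaussian readout noise and a constant offset, matching the terms the
moment formulas correct for. Optional bleaching applies a slow
multiplicative envelope (exponential or linear) to the emission rate.

**Box sizing.** The axial box dimension must exceed 10·ω_z; laterally the
floor is 12·ω_r (plus the scan footprint for imaging) — the detection
profile extends only ~3 waists radially. One subtlety matters for
single-point FCS: the ACF tail is carried by long-wavelength
concentration modes, which a periodic box quantizes at 2π/L, so a
lateral box at the 12·ω_r floor measurably suppresses G(τ) beyond a few
diffusion times (ratio to the infinite-medium model ≈0.96 at 4 τ_D,
≈0.90 at 9 τ_D) and biases fitted D upward by >10% for fast dyes whose
fitted lag range spans many τ_D. The default FCS box is therefore
24·ω_r laterally, which pushes the suppression below the statistical
noise of a 2×10⁶-dwell trace. Raster stacks span the 12.8 µm scan
footprint and fit spatial shifts ≤0.8 µm, far from the box scale, so the
floor is adequate there. Tests of means, variances and amplitudes (not
tail shapes) use the compact box.

**Problem sizes.** Default single-point FCS simulations use a mean
occupancy of 0.25 particles in V_3DG (≈2.7 nM) — the high-contrast,
low-concentration regime in which amplitude and decay are cleanest — and
2×10⁶ dwells of 10 µs. Imaging simulations use the standard protocol
(12.5 µs dwell, 256×256 pixels of 0.05 µm, 100 frames, line time =
1.1×dwell×columns, no inter-frame dead time) at 5–10 nM, i.e. thousands
to tens of thousands of particles; these sizes keep a full stack render
around a minute on one CPU while leaving every estimator deeply inside
its asymptotic regime.

**Renderers.** Small problems can materialize trajectories
(`simulate_paths`) and render from them; paper-scale problems use fused
streaming generators. The FCS generator advances positions chunk-wise at
one step per dwell (positions are piecewise-constant within a dwell,
adequate because the step is ≪ ω_r for every D used). The raster
generator exploits the independence of Brownian increments: per scan
line, particles outside a contribution cutoff (3 waists + 3σ of
line-time motion) take a single Gaussian jump over the line time, while
near particles are propagated on a substep grid fine enough that one
substep moves them ≤ ω_r/3, and only across the substeps their pixel
window actually samples, with bridging jumps for the rest of the line.
This is an exact decomposition, not a coarse-graining; the only
approximation is ignoring contributions from particles that would have
to cross a 3σ margin mid-line, a sub-10⁻³ intensity effect. The inner
loop is compiled (numba) and uses an inline xorshift64*/Box–Muller
normal generator; all streams are seeded from the single run seed, so
every trace and stack is bit-reproducible.

**What the generator does not emulate:** triplet/blinking photophysics,
anomalous or confined diffusion, membrane-bound 2D diffusion, detector
afterpulsing or dead time, nucleotide-dependent assembly kinetics, and
cellular heterogeneity (organelles, bright immobile puncta) except
through the optional bleaching envelope. Passing recovery tests on this
generator therefore validates the estimators under their own model
assumptions — it does not certify robustness to, e.g., photophysics or
anomalous transport in real cells.

## Correlators

Both correlators estimate G = ⟨δI δI⟩/⟨I⟩² after subtracting the detector
offset (the moment formulas treat the offset explicitly, so the
correlators must too).

* **Temporal**: a brute-force direct estimator (the test oracle) and a
  multi-tau scheme (m = 16 lags per octave, pairwise block averaging).
  The two are the same arithmetic on the first octave's linear lags.
  Per-lag standard errors come from splitting the trace into 8 segments
  and averaging segment ACFs; they weight the fits. Constant traces are
  rejected as degenerate.
* **Spatial**: per-frame circular FFT autocorrelation of the
  mean-subtracted ROI, normalized by the squared frame mean and averaged
  over frames, so G(−ξ,−ψ) = G(ξ,ψ) holds exactly and frame order is
  irrelevant. Per-shift standard errors over frames weight the RICS fit.
  The finite-ROI mean subtraction imprints a small negative baseline
  (the SACF sums to zero); the RICS fit absorbs it with a floated
  additive constant.
* **Detrending**: per pixel, a centered moving average over w frames
  (default 10, configurable 2…n−1; edges use a symmetric shrinking
  window) is subtracted and the time-mean of that average — the grand
  mean, for stationary data — is added back, so per-pixel means are
  exactly preserved and slow drifts (bleaching, cell movement) are
  removed while physical intensity levels survive for the moment
  formulas.

Detrending necessarily removes a known fraction (≈1/w) of the *fast*
fluctuation variance as well. Moment analysis therefore divides measured
per-pixel variances by the exact white-noise attenuation factor of the
detrend operator, computed from its matrix representation
(`detrend_variance_factor`; trace(MᵀM)/(n−1) of the mean-centered
operator — ~0.90 for w = 10, n = 100, edges included). Without this
correction B − 1 is biased low by ~1/w, which the brightness ratio ε_norm
amplifies several-fold. The correction is exact when frames are
uncorrelated at the pixel level (frame intervals ≫ the diffusion time
through a pixel, true for every condition simulated here).

## FCS fitting

Weighted least squares (lmfit/Levenberg–Marquardt) of the one- or
two-component 3D-Gaussian diffusion model. Choices:

* The structural factor is frozen at the calibrated PSF value during
  sample fits and floated only during PSF calibration, avoiding the
  well-known τ_D–S degeneracy.
* The first fitted lag is 2 dwells (suppresses residual shot-noise and
  detector artifacts at lag 1); initial guesses are G0 from the first
  lags and τ_D from the half-amplitude lag.
* Two-component fits share a single total amplitude with fractional
  amplitudes (f, 1−f); the fast component's τ_D can be frozen at
  ω_r²/(4·D_dye) to absorb trace free dye, and results are reported
  major-component-first. Nearly equal diffusion times trigger an
  ill-conditioning warning; non-convergence sets a flag rather than
  raising.
* PSF calibration inverts τ_D = ω_r²/4D for a reference dye of known D
  and rejects radial waists outside 0.1–0.5 µm (high-NA instruments
  calibrate near 0.21–0.28 µm).

Physical constants: k_B = 1.380649×10⁻²³ J/K, N_A = 6.02214076×10²³;
internal units are µm, s, µm²/s, nM throughout, converted only at I/O
boundaries.

## RICS fitting

The model is the diffusion factor times the scanning-offset Gaussian
(see README); the time lag uses |τ_p ξ + τ_l ψ| so the time-symmetric
estimator is matched for negative shifts. The fit region defaults to
|ξ| ≤ 16, |ψ| ≤ 8 pixels — beyond a few waists the correlation is noise —
and excludes (0,0), whose shot-noise spike the diffusion model does not
describe. D is fitted in log₁₀ space (bounds 10⁻³–10⁴ µm²/s) after a
coarse grid scan for a robust start; N and the small baseline are free.
A concentration follows from N via C = N/(N_A·V_3DG).

The localized-ROI pipeline (crop → detrend → spatial ACF → fit) mirrors
live-cell practice of analyzing a 64×64-pixel (3.2×3.2 µm) region at the
cell periphery, away from bright immobile puncta; a variance-based guard
warns when the ROI contains bright pixels with suppressed temporal
fluctuations or saturated codes. ROI placement itself stays manual —
"periphery" is a biological judgement the artifact does not automate.

## N&B analysis

Per-pixel means and variances of the detrended stack (variance corrected
as above) enter the moment formulas. Pixels with σ² ≤ σ₀² or ⟨I⟩ ≤ offset
carry no molecular fluctuation information and are masked
(fluctuation-free, B = N = 0); pixels hitting the dtype ceiling (or an
explicit saturation level) are masked saturated; an all-masked frame is
an error. Detector calibration via the dark-image route: offset = grand
mean and σ₀² = pooled per-pixel variance of a dark stack (a drifting dark
stack warns); the gain S comes from the variance-vs-mean slope across
graded-illumination stacks when available — both paths are provided since
the exact historical recipe is not fixed — otherwise from configuration.
Analyses operate on the photon-count scale (B divided by S), where the
monomer lands at B = 1 + ε; this is the scale on which published B values
around 1.1–1.7 live, since with S ≈ 7 the raw analog B would be ≈ S(ε+1).

The B histogram (bin width 0.01) is fitted by a Gaussian *centered at the
distribution maximum*: the maximum is located by argmax of a lightly
smoothed histogram refined by a bounded Gaussian peak fit (pure argmax is
bin-noise-limited on a flat peak and wanders by several bin widths), the
center is then fixed and only amplitude and width are fitted over ±2 FWHM.
Mode-centering tracks the majority population when a bright minority
skews the tail, which is the reason this procedure is used on cellular
data. A secondary mode above half the primary warns of multimodality.

Subunit counts come from ε_norm = (B_complex − 1)/(B_reference − 1) with
first-order error propagation from the two Gaussian widths; a reference
B ≤ 1 is undefined (no molecular fluctuations to normalize by) and
raises.

One estimator property worth knowing: with 100 frames the per-pixel
variance estimate is χ²-distributed and its *mode* sits a few percent
below the true variance, so modal B values land slightly below 1 + ε
(≈1.12 instead of 1.16 for the monomer, ≈1.55 instead of 1.64 for the
tetramer at 100 frames). The shift affects numerator and denominator of
ε_norm in the same direction and mostly — not entirely — cancels in the
ratio: matched monomer/tetramer stacks return ε_norm ≈ 4.5, reproducibly
across seeds, against a generative value of 4. This ≈ +12% offset is a
property of the mode-centered procedure at 100 frames per pixel, not of
the simulation; it shrinks as 1/n_frames (the oligomer-linearity test
uses 400-frame stacks, where the ratio sits within a few percent of q).

## Known limitations

* Estimator variances quoted by the fits are asymptotic
  (covariance-matrix) errors; for strongly correlated ACF noise they can
  be optimistic. The acceptance checks therefore use parameter recovery
  across seeds, not the quoted errors.
* Two-component FCS fits near fraction 0 or 1, and D below ~1 µm²/s with
  20-second traces, are at the edge of identifiability; the slow-regime
  recovery tolerance reflects that.
* The RICS fit assumes a spatially homogeneous ROI; the immobile-feature
  guard flags, but does not remove, violations.
* No cross-correlation (two-color) variants, no photon-counting
  histogram, no anomalous-diffusion exponents — out of scope.
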