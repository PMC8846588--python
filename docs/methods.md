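# Methods

This note documents the models, conventions and free parameters behind each
pipeline stage, the physics the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Attenuation model and EAL convention

Excitation light is modeled as attenuating exponentially with depth,
`I(z) = I(0) exp(−z/EAL)`, with a piecewise-constant EAL across contiguous
tissue layers (cuticle, shallow brain, deep brain). An n-photon contrast
(fluorescence of order n, or THG with n = 3) generated at the focus then
scales as `S ∝ P(z)ⁿ exp(−n·A(z))`, where P(z) is the surface power from
the acquisition schedule and `A(z) = ∫₀ᶻ dz′/EAL(z′)` the accumulated
attenuation exponent.

The estimator mirrors this model: per-frame signal = mean of the brightest
0.25 % of pixels (k = round-half-away-from-zero of fraction·N, floored at
1; ties at the k-th value are equal by definition and cannot affect the
mean); normalization S/Pⁿ; ordinary unweighted least squares of
ln(S/Pⁿ) on depth within a closed window `[z_lo, z_hi]`;
**EAL = −n/slope**. The factor n is a convention choice — the regression
could equally be run on ln((S/Pⁿ)^(1/n)) with slope −1/EAL — but the
adopted form makes 2P and 3P EALs directly comparable and is applied
uniformly. Natural logarithms throughout. Depths are measured from the
first acquired plane (cuticle surface); a configurable `depth_offset_um`
supports a brain-surface origin. Points with nonpositive normalized signal
are excluded from the log fit (and counted), never clamped; fewer than 3
usable points is a fit error, and a nonnegative slope yields an explicit
"undefined EAL" flag rather than a negative length.

A caveat the tests respect: the top-pixel statistic is an extreme-value
estimator whose positive bias grows as photon counts fall (roughly
+3√μ on a mean-μ Poisson peak). Recovery tolerances are therefore stated
for the regime where the per-plane peak expectation stays ≳10³ photons;
below that the fitted EAL drifts high.

### Photon / pulse-energy calibration

`photons_per_pulse` converts the top-pixel signal to photons via a
calibration factor c (photons per intensity unit) and divides by pulses
per pixel (= dwell × repetition rate). The pulse energy needed for a
target rate (default 0.1 photon/pulse) uses the n-photon scaling
S ∝ Eⁿ/τⁿ⁻¹: `E_req = E_meas (target/measured)^(1/n)`, reported after
normalization to a 60 fs reference width as `E_req (τ₀/τ)^((n−1)/n)`.

## Resolution fits

Lateral profiles: `a·exp(−(x−µ)²/2σ²) + b`, FWHM = 2√(2 ln 2)·σ.
Axial profiles: `a·[1 + ((z−µ)/γ)²]^(−k) + b`,
FWHM = 2γ√(2^(1/k) − 1).

The axial power k is mapped to the excitation order (2P → 2, 3P → 3),
which is what n-photon PSF theory gives for the axial intensity response;
k is nevertheless an explicit argument so the opposite pairing is equally
runnable. The baseline is a free parameter initialized at the profile
minimum; amplitude/center/width are initialized from profile moments
(γ via the FWHM relation). Fits use Levenberg–Marquardt
(`scipy.optimize.curve_fit`, xtol 1e−10); a profile whose maximum sits at
an endpoint is rejected before fitting. Profile extraction samples the
image bilinearly along the segment and averages over `width_px`
perpendicular unit-pixel offsets.

## Temporal demultiplexing

The 3P laser pulses every 2.5 µs (400 kHz); the 2P beam passes only while
an EOM gate is high for 1 µs centered between consecutive pulses. Sample
assignment: within `[pulse, pulse + response_window]` → 3P; gate high and
at least `guard` (default 250 ns) clear of every pulse window → 2P;
otherwise discarded. The response window defaults to 3 detector time
constants when a bandwidth is recorded (the detector is modeled as a
single-pole low-pass, e.g. the 1.9 MHz anti-aliasing filter → τ ≈ 84 ns),
else to one sample period (rectangular response). Assignment partitions
the samples, so without the low-pass the two images plus discarded energy
conserve the stream total exactly; with the filter a small fraction of
burst energy leaks past the window, which is what the guard suppresses.
Samples bin into pixels row-major, unidirectional scan. A half-sample
tolerance in the pulse lookup keeps a sample that coincides with a pulse
time (to float rounding) inside that pulse's window.

Crosstalk is measured by nonnegative least-squares unmixing of each
recovered image against the two generating scenes normalized to unit total
intensity; the leak fraction is the share of recovered linear signal
attributable to the other channel's scene. Collinear scenes are rejected
as unidentifiable.

## ΔF/F₀ pipeline conventions

* Frame averaging: non-overlapping k-blocks, trailing partial block
  dropped, effective rate = rate/k (17/4 → 4.25 Hz, 6.5/5 → 1.3 Hz).
* Median filter: disc structuring element of the given radius (square
  optional), reflect borders.
* Pre-stimulus baseline: mean of the k = 10 frames immediately before the
  onset sample.
* Rolling baseline: **centered** 4 s window (the causal variant was the
  other defensible reading; centered is the default and the window is
  configurable), computed with stimulus-masked samples removed from every
  window's average and truncated at the edges; windows containing only
  stimulus samples inherit the nearest valid baseline by linear
  interpolation over sample index.
* Smoothing: trailing 8-frame moving mean with edge truncation (sample i
  averages the available most recent ≤8 samples).
* Peak ΔF/F₀: maximum within 20 frames after stimulus **onset** (not
  offset); the anchor is an argument.
* Resampling: cubic spline onto a uniform 5 Hz grid spanning the original
  times.
* Registration: integer-pixel translation maximizing FFT
  cross-correlation, applied with zero fill — adequate because measured
  motion (~1.3 µm) is far below neuron size (~5 µm); subpixel or
  non-rigid registration is out of scope.
* Landmark motion: intensity-weighted centroid inside a window recentered
  on the previous position each frame (window-minimum subtracted for
  robustness); displacement = centroid step × pixel size; the intensity
  trace is (I − Ī)/Ī with Ī the trace mean. A centroid within one pixel
  of the window border raises a tracking error carrying the frame index.

## Treadmill kinematics

Axis convention follows the FicTrac lab-frame layout (delta-rotation
vector in columns 6–8 of the standard `.dat` file): pitch drives forward
translation, yaw drives turning; the column map and axis meaning are
configurable because log layouts vary between versions. Speeds are
reported as magnitudes (signed variants available):
Sf = |Δpitch|·R/Δt, Sr = |Δyaw|/Δt. Downsampling averages samples in
`[t, t + 200 ms)` windows; empty windows are flagged missing and filled
by linear interpolation (nearest value at the ends). The fictive path
dead-reckons: heading accumulates yaw deltas, each step advances
pitch·R along the current heading (roll ignored by default). Pre/post
summaries compare means over `[onset − 5 s, onset)` and
`[stim_end, stim_end + 5 s)` — the post window is anchored at stimulus
end because the behavioral response outlasts the stimulus; the anchor is
configurable. The paired t-test (two-tailed, n − 1 df) flags
zero-variance differences as degenerate instead of dividing by zero.

## Synthetic generators: what they emulate and what they do not

All generators draw from a single `numpy.random.default_rng(seed)`;
identical seed and configuration are bit-reproducible.

* **Depth stacks** (`make_phantom_stack`): geometric primitives (slabs,
  spheres, tubes standing in for mushroom-body lobes, ring neurons,
  trachea) rasterized on the voxel grid, blurred with a Gaussian lateral /
  Lorentzian^k axial PSF (reflect padding), scaled by
  `photon_budget·(P(z)/P(0))ⁿ·exp(−n·A(z))`, then Poisson-sampled.
  Shot noise only — PMT photon counting dominates; a read-noise hook is
  the natural extension. No scattering Monte-Carlo, no wave optics, no
  depth-dependent aberrations: passing recovery tests shows the estimators
  invert the stated model, not that real tissue obeys it.
* **Calcium movies** (`make_calcium_movie`): per-ROI trace
  `baseline·(1 + drift·t)·(1 + amplitude·h(t))` with h a
  **unit-peak** double-exponential kernel (rise 0.18 s, decay 1.2 s —
  plausible slow-indicator values, free parameters, asserted nowhere as
  measured constants). Unit-peak normalization makes `amplitude` the true
  peak ΔF/F₀. Gaussian noise as a fraction of baseline. No bleaching,
  no neuropil contamination, no spatial motion.
* **PMT streams** (`make_pmt_stream`): bursts at pulse times with the 3P
  scene's pixel amplitude, continuous gated 2P contribution, optional
  single-pole low-pass; noiseless by default so demux properties are
  exact.
* **Behavior logs** (`make_behavior_log`): per-frame rotation magnitudes
  with mean set by the target speeds (Sf·Δt/R, Sr·Δt), fractional Gaussian
  jitter, random yaw sign, a gain window after odor offset. Defaults
  (8 Hz, 5 mm ball radius, 3 s odor) follow the treadmill acquisition
  conditions.
* **Jitter movies** (`make_jitter_movie`): a Gaussian spot random-walks
  with per-frame step magnitudes from a Rayleigh (or fixed) model and
  uniform direction, reflected at a margin inside the field; ground truth
  records the *realized* (post-reflection) displacements, so tracker
  checks are exact and the analytic Rayleigh mean σ√(π/2) applies up to
  the (rare, field-size-controlled) reflections.
* **Transmission samples** (`make_transmission_samples`): located
  (P_T, P_T0) pairs scattered around a known fractional field.

## Problem sizes and tolerances

Test and acceptance runs use deliberately small geometries — 32×32 depth
planes, 8×8 demux scenes at 10 MHz sampling, 32×32 calcium movies,
384×384 jitter fields — chosen so noiseless recoveries are exact to
regression tolerance and stochastic recoveries sit well inside their
stated bounds (EAL 0.5 % noiseless / 5 % with shot noise at ≥10³ peak
photons; FWHM 1 %; ΔF/F₀ amplitude 10 % noiseless / 20 % at 5 % noise;
landmark motion 10 %). Fit convergence uses `curve_fit` defaults with
xtol 1e−10 and moment-based initialization; degenerate inputs (empty
frames, flat profiles, zero-variance differences, collinear scenes) are
rejected or flagged explicitly rather than silently coerced.

## Known limitations

Registration is integer-pixel and translation-only; demultiplexing
assumes unidirectional row-major scanning and a trusted gate waveform
(pulse times are reconstructible from gate edges if absent, not
implemented as a fallback inference); the rolling-baseline gap fill and
the pre/post window anchor are conventions, configurable but defaulted;
the synthetic tissue model is exponential-attenuation-plus-Poisson and
deliberately contains none of the structured background (out-of-focus
excitation near the surface, THG at interfaces) that sets the practical
depth limit in real preparations.
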