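# throughcuticle

Quantitative analysis pipeline for multiphoton (2P/3P) imaging of the
*Drosophila* brain through the intact head cuticle.

Through-cuticle imaging avoids the head surgery that limits how long fly
neural activity can be recorded, but it raises a set of quantitative
questions that this package answers as tested, reproducible code: how much
excitation light the cuticle transmits, how fast the signal attenuates with
imaging depth, what spatial resolution survives the cuticle, how a single
detector stream carrying interleaved 2P and 3P excitation is split back into
two channels, how odor-evoked calcium transients are extracted from GCaMP
movies, how stable the preparation is (landmark motion), and how
spherical-treadmill logs convert into walking kinematics. It is written for
microscopists and fly-neuroscience labs who want these analyses scriptable
rather than buried in one-off notebook code, and every stage comes with a
synthetic-data generator with known ground truth so the whole pipeline is
testable without microscope data.

## The quantities it computes

**Transmission.** Ballistic and total transmission fractions
`T = P_T / P_T0` (sample over resin-only reference), per-wavelength
mean ± SEM, and spatially gridded transmission maps.

**Effective attenuation length (EAL).** The per-frame signal S is the mean
of the brightest 0.25 % of pixels; normalizing by surface power as S/Pⁿ
(n = 2 for 2P, 3 for 3P/THG) removes the power schedule. With excitation
attenuating as exp(−z/EAL), ln(S/Pⁿ) is linear in depth with slope −n/EAL,
so an ordinary least-squares fit over a depth window gives

    EAL = −n / slope ,

piecewise over depth windows when the tissue is layered. A photon/pulse
calibration converts the same top-pixel signal into photons per pulse and
the pulse energy required for a target rate (0.1 photon/pulse), normalized
to a 60 fs reference pulse width via S ∝ Eⁿ/τⁿ⁻¹.

**Resolution.** Line profiles through small structures are fitted with a
Gaussian laterally (FWHM = 2√(2 ln 2) σ ≈ 2.3548 σ) and with a Lorentzian
raised to the excitation order k axially
(FWHM = 2γ√(2^(1/k) − 1)).

**Temporal demultiplexing.** With a 400 kHz 3P laser (pulses 2.5 µs apart)
and the 80 MHz 2P beam gated on for 1 µs between pulses, PMT samples are
assigned to the 3P channel inside a short response window after each pulse,
to the 2P channel while the gate is high and clear of any pulse window by a
guard time, and binned into pixels by the scan clock. Crosstalk is
quantified by least-squares unmixing against the true scenes.

**ΔF/F₀ traces.** Frame averaging (e.g. 17 Hz / 4 → 4.25 Hz), disc median
filtering (radius 10 px), ROI means, baseline F₀ from either the 10 frames
before stimulus onset or a 4 s rolling average excluding stimulus samples,
(F − F₀)/F₀, trailing 8-frame smoothing, peak ΔF/F₀ within 20 post-onset
frames, and 5 Hz cubic-spline resampling. Integer-pixel translation
registration and centroid landmark tracking quantify motion.

**Treadmill kinematics.** Ball delta rotations → forward speed
Sf = |Δpitch|·R/Δt (mm/s) and rotational speed Sr = |Δyaw|/Δt (rad/s),
8 → 5 Hz downsampling by 200 ms window means with linear gap
interpolation, dead-reckoned 2D fictive paths, 5 s pre/post-stimulus
summaries, and a paired t utility.

## Worked example

Recover a two-layer attenuation profile from a synthetic noiseless 3P depth
stack whose generating EALs are 59.4 µm (shallow) and 91.7 µm (deep), with
the surface power ramped from 2 to 15 mW over depth:

```python
import numpy as np
from throughcuticle.core import (AcquisitionParams, AttenuationProfile,
                                 PowerSchedule, PSFModel, ScenePhantom, Slab)
from throughcuticle import synthetic, attenuation

phantom  = ScenePhantom((37, 32, 32), 0.5, 5.0, [Slab(0.0, 180.0)])
atten    = AttenuationProfile([(0, 100, 59.4), (100, 200, 91.7)], 3)
psf      = PSFModel(0.5, 0.4, 3)
schedule = PowerSchedule(np.array([0.0, 180.0]), np.array([2.0, 15.0]))
params   = AcquisitionParams(1320.0, 3, 400e3)

stack, truth = synthetic.make_phantom_stack(
    phantom, params, atten, psf, schedule, 1e4, seed=0, shot_noise=False)
profile = attenuation.profile_from_stack(stack, schedule, 3)
for f in attenuation.piecewise_eal(profile, [(5, 95), (105, 180)], 3):
    print(f"window {f.window_um}: EAL = {f.eal_um:.1f} um, "
          f"slope = {f.slope_per_um:.5f} /um, R^2 = {f.r_squared:.6f}, n = {f.n_points}")
```

prints

```
window (5.0, 95.0): EAL = 59.4 um, slope = -0.05051 /um, R^2 = 1.000000, n = 19
window (105.0, 180.0): EAL = 91.7 um, slope = -0.03272 /um, R^2 = 1.000000, n = 16
```

The slope is −n/EAL (−3/59.4 = −0.0505 /µm), and the fit recovers both
generating EALs exactly because the profile is noiseless and the power
normalization cancels the schedule.

Every stage is also a CLI subcommand
(`throughcuticle simulate|transmission|eal|resolution|demux|dff|motion|behavior`)
taking `--config config.yaml --seed N --out DIR`; the CLI and the library
produce identical result records for identical configurations.

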