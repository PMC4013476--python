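# freeloc

Ideal-observer analysis of visual detection, free-localization, and
detect-and-localize tasks in power-law Gaussian noise.

## The problem

In visual psychophysics and medical-image perception, *observer efficiency*
measures how much of the information in a noisy stimulus a (human or model)
observer actually uses, by comparison with the *ideal observer* (IO) — the
Bayes-optimal decision rule for the exact statistical model of the stimuli.
This package implements the complete methodology for three tasks on the same
stimulus family:

* **fixed-location detection** — yes/no presence of a Gaussian "bump" target
  at a cued location;
* **free localization** — the target is always present somewhere in a
  search region and the response is a location, scored correct within a
  5-pixel acceptance radius;
* **detect-and-localize (D&L)** — free localization with 50% target-present
  trials and an explicit "absent" response governed by a criterion.

Stimuli are 256×256 images: a mean level of 100 gray levels (gl), stationary
Gaussian noise with a power-law power spectrum `S_β(f) = C_β/f^β`
(β ∈ {0, 1, 2, 3}; DC set to the first-harmonic value; `C_β` fixed so the
background RMS contrast is 20%), plus a Gaussian target with σ = 3 px and
peak amplitude `contrast × 100` gl.

## The model

With image `g` (mean subtracted) and noise covariance `Σ_β`, the detection
IO is the prewhitened matched filter `w = Σ_β⁻¹ s` compared with a criterion
`t_crit`.  The localization IO forms the posterior over target locations
`p(l|g) ∝ exp(s_lᵀ Σ_β⁻¹ g)`, integrates it over the radius-5 acceptance
disk around each candidate location, and reports the maximizing pixel; the
D&L observer additionally answers "absent" when the maximum disk score is
below a criterion.  Efficiency is the squared contrast ratio
`η = (C_IO / C_Obs)²` at matched performance, with the IO threshold read
from Monte-Carlo PC-vs-contrast look-up tables (localization) or from
matching hit/false-alarm rates (detection), or a 2-D rate match (D&L).
Classification images estimate an observer's decision weights from the
whitened trial noise fields — for localization via the response-aligned
average over false-localization trials.

Human trial data for these tasks are not public, so the package ships
synthetic model-human observers whose efficiency is known in closed form
(e.g. an equivalent-input-noise observer with `η = 1/(1+γ²)` for every
task), making the whole pipeline testable end to end.

## Worked example

```python
import freeloc as fl

# Monte-Carlo look-up table for the beta=1 free-localization ideal observer
lut = fl.simulate_lut("localization", beta=1.0, n_per_point=2000,
                      step=0.01, seed=1, shape=256)
print(round(lut.invert(0.80), 3))           # -> 0.381

# a model-human with 2x equivalent input noise (true efficiency 0.5)
noise = fl.NoiseSpec(beta=1.0, shape=64)
obs = fl.EquivalentInputNoiseObserver(spectrum=fl.build_spectrum(noise),
                                      target=fl.TargetSpec(3.0), gamma=1.0)
lut64 = fl.simulate_lut("localization", 1.0, n_per_point=1500, step=0.02,
                        seed=11, shape=64)
c_obs = lut64.invert(0.8) * 2**0.5
trials = fl.run_experiment("localization", obs, noise, 3.0, [c_obs],
                           1500, seed=21, store_noise=False)
print(fl.EfficiencyModel(trials.frame, lut=lut64).fit().summary())
```

```
Efficiency (localization, beta=1)
------------------------------------
observer threshold contrast C_obs: 0.3917
IO-equivalent contrast C_io:       0.2818
efficiency eta = (C_io/C_obs)^2:   0.5176  (51.8%)
sessions: 30   se(eta) = 0.0182
```

The IO needs contrast ≈ 0.4 (0.381 for this seed) to localize the σ = 3 px
target at 80% correct in β = 1 noise; the degraded observer needs √2 more contrast for the same
performance, and the pipeline recovers its true efficiency of 0.5 within
Monte-Carlo error.  `summary()` output above is verbatim from this code.

A thin CLI wraps the same pipeline
(`freeloc lut|make-stimuli|simulate-observer|efficiency|classify|report`).

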