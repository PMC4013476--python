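"""Synthetic (model-human) observers with known ground-truth suboptimality.

Human trial data for these tasks are not public, so efficiency estimation
and classification-image recovery are exercised against simulated observers
whose efficiency is known in closed form:

* :class:`LinearObserver` — a linear-template decision maker with additive
  internal noise on the decision statistic (or response map), trial-to-trial
  criterion jitter, and integer motor jitter on localization responses.  Its
  template may be the ideal prewhitened filter or a deliberately distorted
  one (low-frequency-suppressed, peak-shifted, or a fixed-beta template used
  across conditions).  For fixed-location detection its efficiency is exactly
  ``eta* = (w's)^2 / (s'Sigma^-1 s * w'Sigma w * (1 + s_int^2 + s_jit^2))``.

* :class:`EquivalentInputNoiseObserver` — adds an independent noise field
  with the stimulus spectrum scaled by ``gamma`` and then applies the exact
  ideal-observer pipeline at the effective contrast.  The degraded trial is
  statistically identical to an original trial at contrast
  ``c / sqrt(1 + gamma^2)``, so efficiency is exactly ``1 / (1 + gamma^2)``
  for every task — the closed-form oracle for localization and D&L.

Internal-noise and jitter scales are expressed relative to the standard
deviation of the template's noise-driven response, so ``internal_noise_sd=1``
doubles the decision variance regardless of condition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import observer as obs
from .records import TRIAL_COLUMNS, TrialSet
from .stimulus import (
    NoiseSpec,
    SpectrumGrid,
    StimulusImage,
    TargetSpec,
    build_spectrum,
    make_trial,
    sample_noise,
    search_bounds,
    search_mask,
    target_origin_profile,
)

__all__ = [
    "LinearObserver",
    "EquivalentInputNoiseObserver",
    "io_template",
    "mismatched_template",
    "analytic_linear_efficiency",
    "respond_detection",
    "respond_localization",
    "respond_dandl",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def io_template(noise: NoiseSpec, target: TargetSpec,
                spectrum: Optional[SpectrumGrid] = None) -> obs.Template:
    """The ideal prewhitened matched filter for a condition."""
    if spectrum is None:
        spectrum = build_spectrum(noise)
    return obs.build_template(target, spectrum)


def mismatched_template(noise: NoiseSpec, target: TargetSpec,
                        kind: str = "low-suppressed",
                        strength: float = 1.0,
                        fixed_beta: float = 2.0) -> obs.Template:
    """Deliberately suboptimal linear templates.

    ``low-suppressed``
        IO frequency weights multiplied by the high-pass ``f^2/(f^2+f0^2)``
        with ``f0 = strength * 0.03`` cyc/pixel (suppresses low frequencies,
        as human classification images show for white noise).
    ``peak-shifted``
        IO weights evaluated with the Gaussian's scale inflated by
        ``1 + strength/2`` (shifts the bandpass peak to lower frequency).
    ``fixed-beta``
        The IO template for ``fixed_beta`` used regardless of the actual
        background (a non-adapting observer).
    """
    spectrum = build_spectrum(noise)
    n = noise.shape
    if kind == "fixed-beta":
        sp_fix = build_spectrum(dataclasses.replace(noise, beta=fixed_beta))
        t_fix = obs.build_template(target, sp_fix)
        return obs.Template(
            spatial_weights=t_fix.spatial_weights,
            freq_weights=t_fix.freq_weights,
            target_profile=t_fix.target_profile,
            spectrum=spectrum,  # decisions are still scored in the true noise
            beta=noise.beta,
        )
    base = obs.build_template(target, spectrum)
    from .stimulus import radial_frequency_grid
    f = radial_frequency_grid(n)
    if kind == "low-suppressed":
        f0 = 0.03 * strength
        gain = f**2 / (f**2 + f0**2)
    elif kind == "peak-shifted":
        wide = TargetSpec(sigma_pixels=target.sigma_pixels * (1 + strength / 2),
                          contrast=target.contrast)
        return obs.Template(
            spatial_weights=obs.build_template(wide, spectrum).spatial_weights,
            freq_weights=obs.build_template(wide, spectrum).freq_weights,
            target_profile=base.target_profile,
            spectrum=spectrum,
            beta=noise.beta,
        )
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    freq = base.freq_weights * gain
    return obs.Template(
        spatial_weights=np.fft.ifft2(freq).real,
        freq_weights=freq,
        target_profile=base.target_profile,
        spectrum=spectrum,
        beta=noise.beta,
    )


# ---------------------------------------------------------------------------
# Observer models
# ---------------------------------------------------------------------------

@dataclass
class LinearObserver:
    """Linear-template observer with internal noise and response jitter.

    ``internal_noise_sd`` and ``criterion_jitter_sd`` are in units of the
    template response's noise-driven standard deviation; ``criterion`` is in
    absolute decision-statistic units; ``motor_jitter_sd`` is in pixels.
    """

    template: obs.Template
    internal_noise_sd: float = 0.0
    criterion: float = 0.0
    criterion_jitter_sd: float = 0.0
    motor_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("internal_noise_sd", "criterion_jitter_sd",
                     "motor_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.all(np.isfinite(self.template.spatial_weights)):
            raise ValueError("template weights must be finite")

    @property
    def response_sd(self) -> float:
        """Std. dev. of the noise-driven template response ``sqrt(w'Sigma w)``."""
        n = self.template.shape
        w_f = self.template.freq_weights
        s = self.template.spectrum.values
        return float(np.sqrt(np.sum(np.abs(w_f) ** 2 * s).real / n**2))

    def to_json(self) -> dict:
        return {
            "beta": self.template.beta,
            "internal_noise_sd": self.internal_noise_sd,
            "criterion": self.criterion,
            "criterion_jitter_sd": self.criterion_jitter_sd,
            "motor_jitter_sd": self.motor_jitter_sd,
        }


def analytic_linear_efficiency(model: LinearObserver) -> float:
    """Closed-form fixed-location detection efficiency of a linear observer.

    ``eta* = (w's)^2 / (s'Sigma^-1 s * w'Sigma w * (1 + s_int^2 + s_jit^2))``
    evaluated by direct frequency-domain sums; equals 1 for the ideal
    template with no internal noise.
    """
    t = model.template
    n = t.shape
    s_f = np.fft.fft2(t.target_profile)
    w_f = t.freq_weights
    sv = t.spectrum.values
    ws = float(np.sum(np.conj(w_f) * s_f).real / n**2)
    wSw = float(np.sum(np.abs(w_f) ** 2 * sv).real / n**2)
    sS_inv_s = float(np.sum(np.abs(s_f) ** 2 / sv).real / n**2)
    infl = 1.0 + model.internal_noise_sd**2 + model.criterion_jitter_sd**2
    return ws**2 / (sS_inv_s * wSw * infl)


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _record(stim: StimulusImage, *, detected, response, correct, statistic,
            session=0, trial_id=0) -> dict:
    loc = stim.truth_location
    return {
        "trial_id": trial_id,
        "task": stim.task,
        "beta": stim.beta,
        "contrast": stim.contrast,
        "present": stim.truth_present,
        "loc_x": loc[1] if loc is not None else np.nan,
        "loc_y": loc[0] if loc is not None else np.nan,
        "response_x": response[1] if response is not None else np.nan,
        "response_y": response[0] if response is not None else np.nan,
        "detected": detected,
        "correct": correct,
        "statistic": statistic,
        "session": session,
        "seed": stim.seed,
        "processed": stim.processed,
    }


def respond_detection(stim: StimulusImage, model: LinearObserver, seed,
                      **rec) -> dict:
    """Yes/no response: template statistic plus internal noise against a
    jittered criterion."""
    rng = _as_rng(seed)
    n = stim.shape
    w = np.roll(model.template.spatial_weights, (n // 2, n // 2), axis=(0, 1))
    stat = float(np.sum(w * (stim.pixels - stim.mean_level)))
    sd = model.response_sd
    stat += model.internal_noise_sd * sd * rng.standard_normal()
    crit = model.criterion + model.criterion_jitter_sd * sd * rng.standard_normal()
    detected = stat > crit
    correct = detected == stim.truth_present
    return _record(stim, detected=detected, response=None, correct=correct,
                   statistic=stat, **rec)


def _response_map(stim: StimulusImage, model: LinearObserver,
                  rng: np.random.Generator) -> np.ndarray:
    m = np.fft.ifft2(np.fft.fft2(stim.pixels - stim.mean_level)
                     * np.conj(model.template.freq_weights)).real
    if model.internal_noise_sd > 0:
        m = m + model.internal_noise_sd * model.response_sd \
            * rng.standard_normal(m.shape)
    return m


def _jittered(loc: Tuple[int, int], sd: float, rng, shape: int) -> Tuple[int, int]:
    if sd <= 0:
        return loc
    lo, hi = search_bounds(shape)
    r = int(np.clip(loc[0] + round(rng.normal(0, sd)), lo, hi - 1))
    c = int(np.clip(loc[1] + round(rng.normal(0, sd)), lo, hi - 1))
    return (r, c)


def respond_localization(stim: StimulusImage, model: LinearObserver, seed,
                         radius_px: int = obs.DEFAULT_RADIUS, **rec) -> dict:
    """Pick the maximum of the (noisy) template response map over the search
    region, then add integer motor jitter clipped to the region.

    Unlike the ideal observer, no acceptance-disk integration of a posterior
    is performed — a principled suboptimality of the model-human.
    """
    rng = _as_rng(seed)
    m = _response_map(stim, model, rng)
    loc = obs._masked_argmax(m, search_mask(stim.shape))
    stat = float(m[loc])
    loc = _jittered(loc, model.motor_jitter_sd, rng, stim.shape)
    correct = obs.is_correct_location(loc, stim.truth_location, radius_px)
    return _record(stim, detected=True, response=loc, correct=correct,
                   statistic=stat, **rec)


def respond_dandl(stim: StimulusImage, model: LinearObserver, seed,
                  radius_px: int = obs.DEFAULT_RADIUS, **rec) -> dict:
    """As localization, but respond "absent" when the map maximum falls
    below the (jittered) criterion."""
    rng = _as_rng(seed)
    m = _response_map(stim, model, rng)
    loc = obs._masked_argmax(m, search_mask(stim.shape))
    stat = float(m[loc])
    sd = model.response_sd
    crit = model.criterion + model.criterion_jitter_sd * sd * rng.standard_normal()
    if stat > crit:
        loc = _jittered(loc, model.motor_jitter_sd, rng, stim.shape)
        correct = stim.truth_present and obs.is_correct_location(
            loc, stim.truth_location, radius_px)
        return _record(stim, detected=True, response=loc, correct=correct,
                       statistic=stat, **rec)
    return _record(stim, detected=False, response=None,
                   correct=not stim.truth_present, statistic=stat, **rec)


@dataclass
class EquivalentInputNoiseObserver:
    """Ideal observer degraded by equivalent input noise.

    Adds an independent noise field with the stimulus spectrum scaled by
    ``gamma`` and runs the exact IO decision rule at the effective contrast
    ``c / sqrt(1 + gamma^2)``; efficiency is ``1/(1+gamma^2)`` for every
    task by construction.
    """

    spectrum: SpectrumGrid
    target: TargetSpec
    gamma: float = 1.0
    radius_px: int = obs.DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        self._template = obs.build_template(self.target, self.spectrum)

    @property
    def efficiency(self) -> float:
        return 1.0 / (1.0 + self.gamma**2)

    def _degrade(self, stim: StimulusImage, rng) -> StimulusImage:
        scale = np.sqrt(1.0 + self.gamma**2)
        extra = self.gamma * sample_noise(self.spectrum, rng)
        pixels = stim.mean_level + (stim.pixels - stim.mean_level + extra) / scale
        return dataclasses.replace(stim, pixels=pixels,
                                   contrast=stim.contrast / scale)

    def respond_localization(self, stim: StimulusImage, seed, **rec) -> dict:
        rng = _as_rng(seed)
        deg = self._degrade(stim, rng)
        score = obs.localization_score(deg, self._template, self.radius_px)
        dec = obs.localize(score)
        correct = obs.is_correct_location(dec.location, stim.truth_location,
                                          self.radius_px)
        out = _record(stim, detected=True, response=dec.location,
                      correct=correct, statistic=dec.statistic, **rec)
        return out

    def respond_detection(self, stim: StimulusImage, seed,
                          t_crit: float = 0.0, **rec) -> dict:
        rng = _as_rng(seed)
        deg = self._degrade(stim, rng)
        dec = obs.detect(deg, self._template, t_crit)
        return _record(stim, detected=dec.detected, response=None,
                       correct=dec.detected == stim.truth_present,
                       statistic=dec.statistic, **rec)

    def respond_dandl(self, stim: StimulusImage, seed, threshold: float,
                      **rec) -> dict:
        rng = _as_rng(seed)
        deg = self._degrade(stim, rng)
        score = obs.localization_score(deg, self._template, self.radius_px)
        dec = obs.detect_and_localize(score, threshold)
        if dec.detected:
            correct = stim.truth_present and obs.is_correct_location(
                dec.location, stim.truth_location, self.radius_px)
        else:
            correct = not stim.truth_present
        return _record(stim, detected=dec.detected, response=dec.location,
                       correct=correct, statistic=dec.statistic, **rec)


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

def run_experiment(task: str,
                   model: Union[LinearObserver, EquivalentInputNoiseObserver],
                   noise: NoiseSpec, sigma_pixels: float,
                   contrasts: Sequence[float], n_per_level: int,
                   seed: int = 0, block_size: int = 50,
                   radius_px: int = obs.DEFAULT_RADIUS,
                   dl_threshold: float = 0.0,
                   store_noise: bool = True) -> TrialSet:
    """Run a full design (levels x trials) and return the trial table.

    Sessions are consecutive blocks of ``block_size`` trials within a
    contrast level, mirroring runs-of-50 psychophysics sessions.  The whole
    table is reproducible from ``seed``.
    """
    spectrum = build_spectrum(noise)
    ss = np.random.SeedSequence(seed)
    rows = []
    fields = [] if store_noise else None
    trial_id = 0
    for li, contrast in enumerate(contrasts):
        target = TargetSpec(sigma_pixels=sigma_pixels, contrast=float(contrast))
        child = np.random.default_rng(ss.spawn(1)[0])
        for i in range(n_per_level):
            stim_seed = int(child.integers(0, 2**31 - 1))
            stim = make_trial(task, noise, target, stim_seed, spectrum=spectrum)
            session = li * 1000 + i // block_size
            rec_kw = {"session": session, "trial_id": trial_id}
            if isinstance(model, EquivalentInputNoiseObserver):
                if task == "detection":
                    row = model.respond_detection(stim, child, **rec_kw)
                elif task == "localization":
                    row = model.respond_localization(stim, child, **rec_kw)
                else:
                    row = model.respond_dandl(stim, child,
                                              threshold=dl_threshold, **rec_kw)
            else:
                if task == "detection":
                    row = respond_detection(stim, model, child, **rec_kw)
                elif task == "localization":
                    row = respond_localization(stim, model, child,
                                               radius_px=radius_px, **rec_kw)
                else:
                    row = respond_dandl(stim, model, child,
                                        radius_px=radius_px, **rec_kw)
            rows.append(row)
            if fields is not None:
                fields.append(stim.noise.astype(np.float32))
            trial_id += 1
    frame = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    noise_stack = np.stack(fields) if fields else None
    return TrialSet(frame=frame, noise=noise_stack, spectrum=spectrum,
                    meta={"task": task, "seed": seed, "radius_px": radius_px,
                          "sigma_pixels": sigma_pixels})
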