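"""Batched Monte-Carlo engines for ideal-observer performance estimation.

The per-image decision path in :mod:`freeloc.observer` is exact but too slow
for look-up tables built from thousands of trials per contrast.  The engine
here exploits two structural facts:

* the template correlation of a trial separates into a noise part
  ``r_n = corr(template, noise)`` and a deterministic signal part
  ``amp * rho`` (``rho`` = template/target cross-correlation) shifted to the
  target location — so one set of noise correlations can be reused across
  every contrast (common random numbers);
* the posterior is zero outside the search region, so the acceptance-disk
  convolution can be evaluated on the search-region block alone with
  zero padding (identical to the circular convolution because the border
  exceeds the disk radius).

Scores are accumulated in float32; the disk convolution uses
``scipy.signal.fftconvolve``.  Agreement with the exact per-image path is
covered by tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal

from .observer import DEFAULT_RADIUS, build_template, disk_kernel
from .stimulus import (
    NoiseSpec,
    SpectrumGrid,
    TargetSpec,
    build_spectrum,
    search_bounds,
    target_origin_profile,
)

__all__ = ["LocalizationEngine", "DetectionEngine", "make_engine"]


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class _LocTrials:
    """Common-random-number trial bank for localization / D&L."""

    r_noise: np.ndarray      # (n, M, M) float32, noise correlation in search region
    rho: np.ndarray          # (n, M, M) float32, signal correlation for each location
    truth: np.ndarray        # (n, 2) search-region coordinates of the target
    present: np.ndarray      # (n,) bool (all True for pure localization)


class LocalizationEngine:
    """Simulates the free-localization / detect-and-localize ideal observer.

    One engine instance is bound to a noise condition and target; trial banks
    generated from a seed can be scored at any contrast, which implements the
    common-random-number reuse used for the contrast look-up tables.
    """

    def __init__(self, noise: NoiseSpec, target: TargetSpec,
                 radius_px: int = DEFAULT_RADIUS,
                 target_profile: Optional[np.ndarray] = None,
                 spectrum: Optional[SpectrumGrid] = None):
        self.noise_spec = noise
        self.target_spec = target
        self.radius_px = radius_px
        n = noise.shape
        self.shape = n
        self.spectrum = spectrum if spectrum is not None else build_spectrum(noise)
        s0 = target_profile if target_profile is not None \
            else target_origin_profile(target, n)
        self.template = build_template(s0, self.spectrum)
        s_f = np.fft.fft2(s0)
        sv = self.spectrum.values
        # corr(template, noise) in one pass: noise~ = W*sqrt(S), so
        # r~ = noise~ * conj(s~)/S = W * conj(s~)/sqrt(S)
        self._noise_to_corr = (np.conj(s_f) / np.sqrt(sv))[:, : n // 2 + 1]
        # signal correlation rho(l - l0) = corr(template, target at l0)
        self.rho = np.fft.ifft2(np.abs(s_f) ** 2 / sv).real
        self.lo, self.hi = search_bounds(n)
        self._kernel = disk_kernel(radius_px)[None, :, :]

    # -- trial banks ---------------------------------------------------

    def sample_trials(self, n_trials: int, seed, present_prob: float = 1.0,
                      batch: int = 128) -> _LocTrials:
        """Draw noise correlations and target geometry for ``n_trials`` trials."""
        n = self.shape
        lo, hi = self.lo, self.hi
        m = hi - lo
        rng = np.random.default_rng(_seedseq(seed))
        r_noise = np.empty((n_trials, m, m), dtype=np.float32)
        rho_sh = np.empty((n_trials, m, m), dtype=np.float32)
        truth = np.empty((n_trials, 2), dtype=np.int64)
        present = (np.ones(n_trials, dtype=bool) if present_prob >= 1.0
                   else rng.random(n_trials) < present_prob)
        for start in range(0, n_trials, batch):
            stop = min(start + batch, n_trials)
            b = stop - start
            white = rng.standard_normal((b, n, n))
            rn = np.fft.irfft2(np.fft.rfft2(white) * self._noise_to_corr,
                               s=(n, n))
            r_noise[start:stop] = rn[:, lo:hi, lo:hi]
            locs = rng.integers(lo, hi, size=(b, 2))
            truth[start:stop] = locs - lo
            for i in range(b):
                rho_sh[start + i] = np.roll(
                    self.rho, (locs[i, 0], locs[i, 1]), axis=(0, 1)
                )[lo:hi, lo:hi]
        return _LocTrials(r_noise=r_noise, rho=rho_sh, truth=truth,
                          present=present)

    # -- scoring -------------------------------------------------------

    def score_trials(self, trials: _LocTrials, contrast: float,
                     chunk: int = 256
                     ) -> Tuple[np.ndarray, np.ndarray]:
        """Max disk score and location-correctness flag for every trial.

        Returns ``(max_score, loc_correct)``; ``loc_correct`` marks trials
        whose argmax lies within the acceptance radius of the (drawn) target
        location.  On absent trials the signal term is simply not added.
        """
        amp = np.float32(contrast * self.noise_spec.mean_level)
        n_tr = trials.r_noise.shape[0]
        m = trials.r_noise.shape[1]
        max_score = np.empty(n_tr, dtype=np.float64)
        correct = np.empty(n_tr, dtype=bool)
        r2 = self.radius_px**2
        for start in range(0, n_tr, chunk):
            stop = min(start + chunk, n_tr)
            # exponent = amp * corr, corr = r_noise + present * amp * rho
            z = trials.r_noise[start:stop].astype(np.float64, copy=True)
            pres = trials.present[start:stop]
            if amp != 0:
                z[pres] += amp * trials.rho[start:stop][pres]
            z *= amp
            z -= z.max(axis=(1, 2), keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=(1, 2), keepdims=True)
            disk = signal.fftconvolve(p, self._kernel, mode="same", axes=(1, 2))
            flat = disk.reshape(disk.shape[0], -1)
            idx = np.argmax(flat, axis=1)
            max_score[start:stop] = np.clip(flat[np.arange(len(idx)), idx], 0.0, 1.0)
            rr, cc = idx // m, idx % m
            tr = trials.truth[start:stop]
            correct[start:stop] = ((rr - tr[:, 0]) ** 2
                                   + (cc - tr[:, 1]) ** 2) <= r2
        return max_score, correct

    def pc_localization(self, trials: _LocTrials, contrast: float) -> float:
        """Proportion of trials localized within the acceptance radius."""
        _, correct = self.score_trials(trials, contrast)
        return float(np.mean(correct))

    def dandl_rates(self, trials: _LocTrials, contrast: float,
                    threshold: float) -> Tuple[float, float, float]:
        """(correct-D&L rate on present trials, FP rate on absent trials, PC).

        A present trial is correct when the maximum disk score exceeds the
        criterion *and* the reported location is within the acceptance
        radius; an absent trial is correct when the observer stays below the
        criterion.
        """
        score, loc_ok = self.score_trials(trials, contrast)
        pres = trials.present
        said_present = score > threshold
        if pres.any():
            correct_dl = float(np.mean(said_present[pres] & loc_ok[pres]))
        else:
            correct_dl = float("nan")
        fp = float(np.mean(said_present[~pres])) if (~pres).any() else float("nan")
        n_corr = (said_present[pres] & loc_ok[pres]).sum() + (~said_present[~pres]).sum()
        return correct_dl, fp, float(n_corr / len(pres))


class DetectionEngine:
    """Simulates the fixed-location yes/no ideal observer.

    The decision statistic of a trial decomposes as
    ``t = t_noise + present * amp * v`` with ``v = s' Sigma^-1 s``, so one
    bank of noise statistics serves every contrast and criterion.
    """

    def __init__(self, noise: NoiseSpec, target: TargetSpec,
                 target_profile: Optional[np.ndarray] = None,
                 spectrum: Optional[SpectrumGrid] = None):
        self.noise_spec = noise
        self.target_spec = target
        n = noise.shape
        self.shape = n
        self.spectrum = spectrum if spectrum is not None else build_spectrum(noise)
        s0 = target_profile if target_profile is not None \
            else target_origin_profile(target, n)
        self.template = build_template(s0, self.spectrum)
        s_f = np.fft.fft2(s0)
        sv = self.spectrum.values
        self.energy = float(np.sum(np.abs(s_f) ** 2 / sv).real / n**2)
        # t_noise = w' n with n~ = W sqrt(S): t~ = W conj(s~)/sqrt(S) at lag 0
        self._noise_to_stat = (np.conj(s_f) / np.sqrt(sv))[:, : n // 2 + 1]

    def sample_statistics(self, n_trials: int, seed, batch: int = 256) -> np.ndarray:
        """Noise-only decision statistics ``w' n`` for ``n_trials`` fields."""
        n = self.shape
        rng = np.random.default_rng(_seedseq(seed))
        out = np.empty(n_trials)
        for start in range(0, n_trials, batch):
            stop = min(start + batch, n_trials)
            white = rng.standard_normal((stop - start, n, n))
            corr = np.fft.irfft2(np.fft.rfft2(white) * self._noise_to_stat,
                                 s=(n, n))
            out[start:stop] = corr[:, 0, 0]
        return out

    def pc_detection(self, t_noise: np.ndarray, contrast: float,
                     t_crit: Optional[float] = None) -> float:
        """PC over an equal present/absent split at criterion ``t_crit``
        (midpoint/unbiased criterion when omitted)."""
        amp = contrast * self.noise_spec.mean_level
        shift = amp * self.energy
        if t_crit is None:
            t_crit = shift / 2.0
        half = len(t_noise) // 2
        hits = t_noise[:half] + shift > t_crit
        rejections = t_noise[half:] <= t_crit
        return float((hits.sum() + rejections.sum()) / (half + len(t_noise) - half))

    def rates(self, t_noise: np.ndarray, contrast: float,
              t_crit: float) -> Tuple[float, float]:
        """(hit rate, false-alarm rate) over an equal present/absent split."""
        amp = contrast * self.noise_spec.mean_level
        half = len(t_noise) // 2
        hit = float(np.mean(t_noise[:half] + amp * self.energy > t_crit))
        fa = float(np.mean(t_noise[half:] > t_crit))
        return hit, fa


def make_engine(task: str, noise: NoiseSpec, target: TargetSpec,
                radius_px: int = DEFAULT_RADIUS, **kw):
    if task == "detection":
        return DetectionEngine(noise, target, **kw)
    if task in ("localization", "dandl"):
        return LocalizationEngine(noise, target, radius_px=radius_px, **kw)
    raise ValueError(f"unknown task {task!r}")
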