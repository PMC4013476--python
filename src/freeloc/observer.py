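"""Ideal-observer decision functions for detection, free localization, and
detect-and-localize in stationary Gaussian noise.

The optimal detector is the prewhitened matched filter ``w = Sigma^-1 s``;
with the spectrum convention of :mod:`freeloc.stimulus` the covariance acts
as multiplication by ``S(f)`` in the DFT domain, so the template's frequency
weights are ``FT(target) / S`` and all inner products reduce to frequency
sums with a ``1/N^2`` Parseval factor.

The free-localization observer forms the posterior over target locations
(uniform prior), integrates it over the acceptance disk around each
candidate location, and reports the location with the largest disk score.
The detect-and-localize observer additionally compares the maximum disk
score to a criterion.  A brute-force oracle computes the same posterior by
explicit shifted-template inner products for small images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import ndimage

from .stimulus import (
    SpectrumGrid,
    StimulusImage,
    TargetSpec,
    search_bounds,
    search_mask,
    target_origin_profile,
)

__all__ = [
    "Template",
    "ScoreMap",
    "IODecision",
    "build_template",
    "detect",
    "analytic_dprime",
    "disk_offsets",
    "disk_kernel",
    "localization_score",
    "localize",
    "detect_and_localize",
    "is_correct_location",
    "brute_force_localize",
]

DEFAULT_RADIUS = 5


@dataclass(frozen=True)
class Template:
    """Prewhitened matched filter for one noise condition.

    ``freq_weights = FT(target)/S`` on the full DFT grid (real for the
    symmetric targets used here); ``spatial_weights`` is its inverse
    transform with the weight for the target-at-origin placement at pixel
    (0, 0).  A global scale is irrelevant to every decision.
    """

    spatial_weights: np.ndarray
    freq_weights: np.ndarray
    target_profile: np.ndarray  # origin-centered, unit peak (or filtered)
    spectrum: SpectrumGrid
    beta: float

    @property
    def shape(self) -> int:
        return self.spatial_weights.shape[0]

    @property
    def whitened_energy(self) -> float:
        """``s' Sigma^-1 s`` for the unit-amplitude profile."""
        n = self.shape
        s_f = np.fft.fft2(self.target_profile)
        return float(np.sum(np.abs(s_f) ** 2 / self.spectrum.values).real / n**2)


@dataclass
class ScoreMap:
    """Acceptance-disk-integrated posterior over target locations.

    ``posterior`` sums to one over the search region and is zero outside it;
    ``disk_score[l]`` is the posterior mass within ``radius_px`` of ``l``.
    """

    posterior: np.ndarray
    disk_score: np.ndarray
    search_mask: np.ndarray
    radius_px: int = DEFAULT_RADIUS


@dataclass(frozen=True)
class IODecision:
    task: str
    detected: Optional[bool]
    location: Optional[Tuple[int, int]]
    statistic: float
    criterion_used: Optional[float] = None


def _target_profile(target: Union[TargetSpec, np.ndarray], shape: int) -> np.ndarray:
    if isinstance(target, np.ndarray):
        if target.shape != (shape, shape):
            raise ValueError("target profile shape does not match spectrum")
        return target
    return target_origin_profile(target, shape)


def build_template(target: Union[TargetSpec, np.ndarray],
                   spectrum: SpectrumGrid) -> Template:
    """Ideal-observer template: Fourier transform of the target divided by
    the noise power spectrum (DC handled by the spectrum's DC rule).

    ``target`` may be a :class:`TargetSpec` or an explicit origin-centered
    profile array (e.g. the filtered target of processed stimuli).
    """
    n = spectrum.shape
    if np.any(spectrum.values <= 0):
        raise ValueError("spectrum must be strictly positive")
    s0 = _target_profile(target, n)
    freq = np.fft.fft2(s0) / spectrum.values
    spatial = np.fft.ifft2(freq)
    if np.max(np.abs(spatial.imag)) > 1e-9 * max(np.max(np.abs(spatial.real)), 1e-300):
        raise ValueError("template is not real; asymmetric target profile?")
    return Template(
        spatial_weights=spatial.real,
        freq_weights=freq,
        target_profile=s0,
        spectrum=spectrum,
        beta=spectrum.beta,
    )


def detect(stim: StimulusImage, tmpl: Template, t_crit: float) -> IODecision:
    """Fixed-location yes/no detection: compare ``w'(g - mean)`` to ``t_crit``.

    Exact equality with the criterion resolves to "not detected".
    """
    if stim.pixels.shape != tmpl.spatial_weights.shape:
        raise ValueError("stimulus and template shapes differ")
    # Target cued at the image center: align the origin-referenced template.
    n = tmpl.shape
    w = np.roll(tmpl.spatial_weights, (n // 2, n // 2), axis=(0, 1))
    stat = float(np.sum(w * (stim.pixels - stim.mean_level)))
    return IODecision(
        task="detection",
        detected=bool(stat > t_crit),
        location=None,
        statistic=stat,
        criterion_used=t_crit,
    )


def analytic_dprime(target: Union[TargetSpec, np.ndarray],
                    spectrum: SpectrumGrid,
                    mean_level: float = 100.0) -> float:
    """Detectability per unit contrast: ``mean_level * sqrt(s' Sigma^-1 s)``.

    ``d' = contrast * analytic_dprime(...)`` for the fixed-location task;
    evaluated as the frequency-domain sum ``(1/N^2) sum |s~|^2 / S``.
    """
    n = spectrum.shape
    s0 = _target_profile(target, n)
    s_f = np.fft.fft2(s0)
    v = float(np.sum(np.abs(s_f) ** 2 / spectrum.values).real / n**2)
    return mean_level * np.sqrt(v)


def disk_offsets(radius: int) -> np.ndarray:
    """Integer lattice offsets with Euclidean norm <= radius (81 for radius 5)."""
    d = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(d, d, indexing="ij")
    keep = dx**2 + dy**2 <= radius**2
    return np.stack([dx[keep], dy[keep]], axis=1)


def disk_kernel(radius: int) -> np.ndarray:
    d = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(d, d, indexing="ij")
    return (dx**2 + dy**2 <= radius**2).astype(float)


def localization_score(stim: StimulusImage, tmpl: Template,
                       radius_px: int = DEFAULT_RADIUS) -> ScoreMap:
    """Posterior over locations and its acceptance-disk integral.

    Steps (all convolutions circular): (1) correlate the prewhitened template
    with the mean-subtracted image and scale by the target amplitude; (2)
    exponentiate — after subtracting the in-region maximum, which leaves the
    normalized posterior unchanged but cannot overflow; (3) zero outside the
    search region; (4) normalize to unit sum; (5) convolve with the radius-5
    disk.
    """
    n = stim.shape
    if tmpl.shape != n:
        raise ValueError("stimulus and template shapes differ")
    x = stim.pixels - stim.mean_level
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite stimulus")
    amp = stim.contrast * stim.mean_level
    corr = np.fft.ifft2(np.fft.fft2(x) * np.conj(tmpl.freq_weights)).real
    z = amp * corr

    mask = search_mask(n)
    z_in = np.where(mask, z, -np.inf)
    post = np.exp(z_in - z_in.max())
    post /= post.sum()
    disk = ndimage.convolve(post, disk_kernel(radius_px), mode="wrap")
    return ScoreMap(posterior=post, disk_score=disk, search_mask=mask,
                    radius_px=radius_px)


def _masked_argmax(values: np.ndarray, mask: np.ndarray) -> Tuple[int, int]:
    flat = np.where(mask, values, -np.inf).ravel()
    idx = int(np.argmax(flat))  # first occurrence = row-major tie break
    n = values.shape[1]
    return idx // n, idx % n


def localize(score: ScoreMap) -> IODecision:
    """Choose the location with the largest disk score (row-major tie break)."""
    loc = _masked_argmax(score.disk_score, score.search_mask)
    return IODecision(
        task="localization",
        detected=None,
        location=loc,
        statistic=float(score.disk_score[loc]),
    )


def detect_and_localize(score: ScoreMap, threshold: float) -> IODecision:
    """Report the best location if its disk score exceeds the criterion,
    otherwise respond target-absent."""
    loc = _masked_argmax(score.disk_score, score.search_mask)
    stat = float(score.disk_score[loc])
    detected = stat > threshold
    return IODecision(
        task="dandl",
        detected=detected,
        location=loc if detected else None,
        statistic=stat,
        criterion_used=threshold,
    )


def is_correct_location(response: Optional[Tuple[int, int]],
                        truth: Optional[Tuple[int, int]],
                        radius_px: int = DEFAULT_RADIUS) -> bool:
    """Acceptance-region scoring: correct iff within ``radius_px`` of truth."""
    if response is None or truth is None:
        return False
    dr = response[0] - truth[0]
    dc = response[1] - truth[1]
    return dr * dr + dc * dc <= radius_px * radius_px


def brute_force_localize(stim: StimulusImage,
                         target: Union[TargetSpec, np.ndarray],
                         spectrum: SpectrumGrid,
                         radius_px: int = DEFAULT_RADIUS) -> Tuple[int, int]:
    """Oracle localization by explicit per-location evaluation (small images).

    Computes ``s_l' Sigma^-1 g`` for every candidate location by shifting the
    target profile pixel-by-pixel against the whitened image, normalizes the
    posterior over the search region, sums it over the acceptance disk by
    direct summation, and returns the argmax under the same row-major tie
    rule as :func:`localize`.  Cost is O(shape^4); refused above 64 pixels.
    """
    n = stim.shape
    if n > 64:
        raise ValueError("brute-force oracle is limited to shapes <= 64")
    s0 = _target_profile(target, n)
    amp = stim.contrast * stim.mean_level
    q = np.fft.ifft2(np.fft.fft2(stim.pixels - stim.mean_level)
                     / spectrum.values).real
    lo, hi = search_bounds(n)
    z = np.full((n, n), -np.inf)
    for r in range(lo, hi):
        for c in range(lo, hi):
            z[r, c] = amp * float(np.sum(np.roll(s0, (r, c), axis=(0, 1)) * q))
    post = np.exp(z - z[lo:hi, lo:hi].max())
    post[~search_mask(n)] = 0.0
    post /= post.sum()
    offs = disk_offsets(radius_px)
    disk = np.zeros((n, n))
    for r in range(lo, hi):
        for c in range(lo, hi):
            disk[r, c] = post[(r + offs[:, 0]) % n, (c + offs[:, 1]) % n].sum()
    return _masked_argmax(disk, search_mask(n))
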