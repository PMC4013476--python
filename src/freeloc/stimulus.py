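"""Stimulus synthesis: power-law Gaussian noise textures and Gaussian bump targets.

Noise backgrounds are stationary Gaussian fields with a radially symmetric
power-law power spectrum ``S_beta(f) = C_beta / f**beta`` on the 2-D DFT grid
(frequencies in cycles/pixel).  The singular DC value is replaced by the value
at the first harmonic ``f = 1/shape``, and the normalization ``C_beta`` is set
so that the implied pixel variance equals ``(rms_contrast * mean_level)**2``
(400 gl^2 for the default 20% RMS contrast on a mean level of 100 gray levels).

DFT scaling convention used throughout the package: a field sampled as
``irfft2(rfft2(white) * sqrt(S))`` (unit-variance white input) has pixel
variance equal to the plain mean of ``S`` over the DFT grid, so
``SpectrumGrid.values.mean()`` *is* the pixel variance.  The covariance
operator acts as multiplication by ``S(f)`` under the numpy ``fft2/ifft2``
pair, which is the convention the ideal-observer module relies on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

__all__ = [
    "TASKS",
    "NoiseSpec",
    "TargetSpec",
    "SpectrumGrid",
    "StimulusImage",
    "radial_frequency_grid",
    "build_spectrum",
    "sample_noise",
    "gaussian_target",
    "target_origin_profile",
    "search_bounds",
    "search_mask",
    "make_trial",
    "pink_amplitude_filter",
    "process_white_to_pink",
    "filtered_target_profile",
    "processed_spectrum",
]

TASKS = ("detection", "localization", "dandl")


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one power-law noise background condition.

    beta
        Power-law exponent of the noise power spectrum (0 = white noise,
        2 resembles natural-scene statistics).
    rms_contrast
        Background RMS contrast relative to the mean level (0.20 default).
    mean_level
        Mean background intensity in gray levels (100 gl default).
    shape
        Image side length in pixels (must be even, >= 8).
    """

    beta: float = 2.0
    rms_contrast: float = 0.20
    mean_level: float = 100.0
    shape: int = 256

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0 < self.rms_contrast < 1:
            raise ValueError("rms_contrast must lie in (0, 1)")
        if self.mean_level <= 0:
            raise ValueError("mean_level must be positive")
        if self.shape < 8 or self.shape % 2:
            raise ValueError("shape must be an even integer >= 8")

    @property
    def pixel_variance(self) -> float:
        """Implied noise pixel variance in gl^2 (400 for the defaults)."""
        return (self.rms_contrast * self.mean_level) ** 2


@dataclass(frozen=True)
class TargetSpec:
    """Gaussian bump target: ``exp(-r^2 / (2 sigma^2))`` with unit peak.

    Contrast is defined as the peak target amplitude divided by the mean
    background level, so the embedded target is
    ``contrast * mean_level * profile``.
    """

    sigma_pixels: float = 3.0
    contrast: float = 0.0
    profile_kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma_pixels <= 0:
            raise ValueError("sigma_pixels must be positive")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        if self.profile_kind not in ("gaussian", "filtered"):
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")

    @property
    def fwhm_pixels(self) -> float:
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigma_pixels


@dataclass(frozen=True)
class SpectrumGrid:
    """Discrete noise power spectrum on the full 2-D DFT grid.

    ``values.mean()`` equals the pixel variance (see module docstring);
    the DC entry holds the first-harmonic value (``dc_rule``).
    """

    values: np.ndarray
    beta: float
    normalization: float  # C_beta in gl^2 * pixel^2 (power at f = 1 cyc/pix)
    dc_rule: str = "first-harmonic"

    @property
    def shape(self) -> int:
        return self.values.shape[0]

    @property
    def pixel_variance(self) -> float:
        return float(self.values.mean())

    def rfft_values(self) -> np.ndarray:
        """The spectrum restricted to the ``rfft2`` half-plane grid."""
        n = self.shape
        return self.values[:, : n // 2 + 1]


@dataclass
class StimulusImage:
    """One trial's stimulus: pixels plus ground truth and condition tags.

    ``noise`` holds the zero-mean noise field alone (no target, no mean),
    which classification-image estimation needs.  ``truth_location`` is
    0-based ``(row, col)`` with origin at the top-left pixel.
    """

    pixels: np.ndarray
    noise: np.ndarray
    mean_level: float
    truth_present: bool
    truth_location: Optional[Tuple[int, int]]
    task: str
    beta: float
    contrast: float
    seed: int
    processed: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("stimulus pixels must be finite")
        if not self.truth_present and self.truth_location is not None:
            raise ValueError("absent trials cannot carry a target location")

    @property
    def shape(self) -> int:
        return self.pixels.shape[0]

    @property
    def condition(self) -> Tuple[str, float, float]:
        return (self.task, self.beta, self.contrast)


def radial_frequency_grid(shape: int) -> np.ndarray:
    """Radial DFT frequency magnitude ``sqrt(fx^2 + fy^2)`` in cycles/pixel."""
    f = np.fft.fftfreq(shape)
    return np.hypot(f[:, None], f[None, :])


def build_spectrum(spec: NoiseSpec) -> SpectrumGrid:
    """Power-law spectrum ``C_beta / f**beta`` with the DC/first-harmonic rule.

    ``C_beta`` is chosen so the implied pixel variance equals
    ``spec.pixel_variance`` exactly (mean of the grid == variance).
    """
    n = spec.shape
    f = radial_frequency_grid(n)
    with np.errstate(divide="ignore"):
        raw = np.where(f > 0, f, 1.0) ** (-spec.beta)
    raw[0, 0] = float(n) ** spec.beta  # DC <- value at f = 1/shape
    c = spec.pixel_variance / raw.mean()
    return SpectrumGrid(values=c * raw, beta=spec.beta, normalization=c)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_noise(spectrum: SpectrumGrid, seed) -> np.ndarray:
    """One zero-mean stationary Gaussian field with power spectrum ``spectrum``.

    White Gaussian noise is filtered in the frequency domain by ``sqrt(S)``
    (the square-root filter); the result is real by Hermitian symmetry and
    reproducible for a fixed seed or Generator.
    """
    rng = _as_rng(seed)
    n = spectrum.shape
    white = rng.standard_normal((n, n))
    amp = np.sqrt(spectrum.rfft_values())
    return np.fft.irfft2(np.fft.rfft2(white) * amp, s=(n, n))


def gaussian_target(spec: TargetSpec, shape: int) -> np.ndarray:
    """Unit-peak Gaussian profile centered at pixel ``(shape//2, shape//2)``.

    Distances wrap circularly, consistent with the circular-shift embedding
    used when placing the target at arbitrary locations.
    """
    d = np.arange(shape) - shape // 2
    r2 = d[:, None] ** 2 + d[None, :] ** 2
    return np.exp(-r2 / (2.0 * spec.sigma_pixels**2))


def target_origin_profile(spec: TargetSpec, shape: int) -> np.ndarray:
    """The target profile with its peak at pixel (0, 0) (DFT origin)."""
    return np.fft.ifftshift(gaussian_target(spec, shape))


def search_bounds(shape: int) -> Tuple[int, int]:
    """Half-open row/col bounds of the central search region (half side)."""
    if shape < 4:
        raise ValueError("image too small to hold a search region")
    return shape // 4, 3 * shape // 4


def search_mask(shape: int) -> np.ndarray:
    lo, hi = search_bounds(shape)
    m = np.zeros((shape, shape), dtype=bool)
    m[lo:hi, lo:hi] = True
    return m


def make_trial(task: str, noise: NoiseSpec, target: TargetSpec, seed,
               spectrum: Optional[SpectrumGrid] = None) -> StimulusImage:
    """Compose one trial stimulus for a task.

    detection
        Target present with probability 0.5 at the image center (cued).
    localization
        Target always present, uniform over the central search region
        (one quarter of the image area).
    dandl
        Present with probability 0.5; location uniform over the search
        region when present.

    ``pixels = mean_level + noise + contrast * mean_level * shifted_profile``.
    The random draws (presence, location, noise) do not depend on contrast,
    so trials with the same seed and different contrasts share their noise
    and geometry exactly.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    n = noise.shape
    lo, hi = search_bounds(n)
    if spectrum is None:
        spectrum = build_spectrum(noise)
    rng = _as_rng(seed)

    present = True if task == "localization" else bool(rng.random() < 0.5)
    if task == "detection":
        loc = (n // 2, n // 2)
    else:
        loc = (int(rng.integers(lo, hi)), int(rng.integers(lo, hi)))
    field = sample_noise(spectrum, rng)

    pixels = noise.mean_level + field
    if present and target.contrast > 0:
        amp = target.contrast * noise.mean_level
        profile = np.roll(target_origin_profile(target, n), loc, axis=(0, 1))
        pixels = pixels + amp * profile
    return StimulusImage(
        pixels=pixels,
        noise=field,
        mean_level=noise.mean_level,
        truth_present=present,
        truth_location=loc if present else None,
        task=task,
        beta=noise.beta,
        contrast=target.contrast,
        seed=int(seed) if np.isscalar(seed) and not isinstance(seed, np.random.Generator) else -1,
    )


def pink_amplitude_filter(shape: int) -> np.ndarray:
    """Amplitude filter proportional to 1/f (DC set by the first-harmonic rule),
    normalized so that ``mean(filter**2) == 1``.

    Applied to a white (beta=0) background this yields a beta=2 power-law
    spectrum while leaving the background pixel variance — hence the 20% RMS
    contrast — unchanged in expectation.  The normalization is deterministic
    (a property of the filter, not of any particular noise sample).
    """
    f = radial_frequency_grid(shape)
    with np.errstate(divide="ignore"):
        raw = np.where(f > 0, 1.0 / np.where(f > 0, f, 1.0), float(shape))
    return raw / np.sqrt(np.mean(raw**2))


def process_white_to_pink(stim: StimulusImage) -> StimulusImage:
    """Filter a white-noise (beta=0) stimulus to a beta=2 power-law background.

    The mean level is removed, the DFT is multiplied by the normalized 1/f
    amplitude filter, and the mean restored.  Ground-truth metadata is
    preserved; the embedded target becomes the filtered profile (heavier
    tails than the original Gaussian).  Refuses non-white or already
    processed inputs.
    """
    if stim.beta != 0:
        raise ValueError("processing is defined for beta=0 stimuli only")
    if stim.processed:
        raise ValueError("stimulus is already processed")
    n = stim.shape
    amp = pink_amplitude_filter(n)[:, : n // 2 + 1]

    def _filt(x: np.ndarray) -> np.ndarray:
        return np.fft.irfft2(np.fft.rfft2(x) * amp, s=(n, n))

    out = dataclasses.replace(
        stim,
        pixels=stim.mean_level + _filt(stim.pixels - stim.mean_level),
        noise=_filt(stim.noise),
        processed=True,
    )
    return out


def filtered_target_profile(target: TargetSpec, shape: int) -> np.ndarray:
    """Origin-centered target profile after the white->pink processing filter."""
    n = shape
    amp = pink_amplitude_filter(n)[:, : n // 2 + 1]
    s0 = target_origin_profile(target, n)
    return np.fft.irfft2(np.fft.rfft2(s0) * amp, s=(n, n))


def processed_spectrum(spec: NoiseSpec) -> SpectrumGrid:
    """Noise spectrum of processed (white->pink) backgrounds.

    Identical to ``build_spectrum`` with beta=2 at the same contrast: the
    normalized 1/f amplitude filter maps the flat spectrum onto exactly the
    beta=2 grid used for natively generated pink noise.
    """
    if spec.beta != 0:
        raise ValueError("processed_spectrum applies to the beta=0 condition")
    return build_spectrum(dataclasses.replace(spec, beta=2.0))
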