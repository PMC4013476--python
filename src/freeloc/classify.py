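"""Classification images: estimated decision weights from trial records.

For detection, the classification image is the signed combination of the
class-mean whitened noise fields over the four outcome classes
(``FP - TN + TP - FN``).  For free localization the response-aligned
variant is used: on every incorrectly localized trial the whitened noise
field is circularly shifted so the response pixel lands at the image
center, and those fields are averaged.  Whitening multiplies the noise DFT
by ``1/S_beta`` (the inverse covariance under the generation model), so
for a linear-template observer the expected classification image is
proportional to the template.

Frequency-domain summaries follow the display conventions: a radial
Butterworth spatial window before the Fourier transform, radial averaging
in annuli one DFT step wide, and peak-normalized profiles in cycles/degree.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .records import TrialSet
from .stimulus import SpectrumGrid, TargetSpec, radial_frequency_grid
from .workbench import PIXEL_ANGLE_DEG

__all__ = [
    "ClassificationImage",
    "RadialProfile",
    "whiten_noise",
    "detection_ci",
    "localization_ci",
    "butterworth_smooth",
    "radial_profile",
    "io_frequency_weights",
    "analytic_io_peak",
    "ClassificationImageModel",
]


@dataclass
class ClassificationImage:
    """Estimated decision weights in the space domain (whitened-noise units)."""

    weights: np.ndarray
    task: str
    beta: float
    n_trials_used: int
    pixel_angle_deg: float = PIXEL_ANGLE_DEG
    crop_deg: float = 2.1

    @property
    def shape(self) -> int:
        return self.weights.shape[0]

    def cropped(self) -> np.ndarray:
        """Central crop of ``crop_deg`` degrees per side (display convention)."""
        half = int(round(self.crop_deg / self.pixel_angle_deg)) // 2
        c = self.shape // 2
        return self.weights[c - half:c + half, c - half:c + half]


@dataclass
class RadialProfile:
    """Radially averaged frequency weights, peak-normalized."""

    freq_cyc_deg: np.ndarray
    weights: np.ndarray
    weights_imag: Optional[np.ndarray] = None  # diagnostic

    def __post_init__(self) -> None:
        self.freq_cyc_deg = np.asarray(self.freq_cyc_deg, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.freq_cyc_deg) <= 0):
            raise ValueError("frequency bins must be increasing")

    @property
    def peak_frequency(self) -> float:
        return float(self.freq_cyc_deg[int(np.argmax(self.weights))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center_cyc_per_deg": self.freq_cyc_deg,
                             "weight": self.weights})


def whiten_noise(noise_field: np.ndarray, spectrum: SpectrumGrid) -> np.ndarray:
    """``q = Sigma^-1 n``: divide the noise DFT by the power spectrum.

    Accepts a single field or a stack ``(n, N, N)``; output is real.
    """
    sv = spectrum.values
    if np.any(sv <= 0):
        raise ValueError("spectrum must be strictly positive")
    x = np.asarray(noise_field, dtype=float)
    if x.shape[-2:] != sv.shape:
        raise ValueError("noise field and spectrum shapes differ")
    return np.fft.ifft2(np.fft.fft2(x, axes=(-2, -1)) / sv, axes=(-2, -1)).real


def _whitened_stack(trials: TrialSet) -> np.ndarray:
    if trials.noise is None:
        raise ValueError("trial set carries no noise fields")
    if trials.spectrum is None:
        raise ValueError("trial set carries no spectrum (whitening must use "
                         "the generating spectrum)")
    return whiten_noise(trials.noise, trials.spectrum)


def detection_ci(trials: TrialSet,
                 pixel_angle_deg: float = PIXEL_ANGLE_DEG) -> ClassificationImage:
    """Detection classification image: ``qbar_FP - qbar_TN + qbar_TP - qbar_FN``
    (unweighted sum of the four outcome-class means)."""
    q = _whitened_stack(trials)
    f = trials.frame
    pres = f["present"].astype(bool).to_numpy()
    det = f["detected"].astype(bool).to_numpy()
    classes = {
        "TP": pres & det, "FN": pres & ~det,
        "FP": ~pres & det, "TN": ~pres & ~det,
    }
    counts = {k: int(v.sum()) for k, v in classes.items()}
    if min(counts.values()) == 0:
        raise ValueError(f"empty outcome class(es); counts: {counts}")
    w = (q[classes["FP"]].mean(axis=0) - q[classes["TN"]].mean(axis=0)
         + q[classes["TP"]].mean(axis=0) - q[classes["FN"]].mean(axis=0))
    return ClassificationImage(weights=w, task="detection",
                               beta=float(f["beta"].iloc[0]),
                               n_trials_used=int(len(f)),
                               pixel_angle_deg=pixel_angle_deg)


def localization_ci(trials: TrialSet,
                    pixel_angle_deg: float = PIXEL_ANGLE_DEG
                    ) -> ClassificationImage:
    """Response-aligned localization classification image.

    For every false-localization trial (a location response outside the
    acceptance region) the whitened noise field is circularly shifted so
    that the response pixel moves to the image center, and the shifted
    fields are averaged.
    """
    q = _whitened_stack(trials)
    f = trials.frame
    has_resp = f["response_x"].notna().to_numpy()
    wrong = ~f["correct"].astype(bool).to_numpy() & has_resp
    idx = np.flatnonzero(wrong)
    if idx.size == 0:
        raise ValueError("no incorrectly localized trials with a response")
    n = q.shape[-1]
    c = n // 2
    acc = np.zeros((n, n))
    rows = f["response_y"].to_numpy()
    cols = f["response_x"].to_numpy()
    for i in idx:
        acc += np.roll(q[i], (c - int(rows[i]), c - int(cols[i])), axis=(0, 1))
    return ClassificationImage(weights=acc / idx.size, task="localization",
                               beta=float(f["beta"].iloc[0]),
                               n_trials_used=int(idx.size),
                               pixel_angle_deg=pixel_angle_deg)


def butterworth_smooth(ci: ClassificationImage, order: int = 4,
                       cutoff_cyc_per_deg: float = 5.6) -> ClassificationImage:
    """Low-pass the classification image with a radial Butterworth gain
    ``1/sqrt(1 + (f/f_c)^(2*order))`` (display smoothing; 5.6 cyc/deg is
    0.29 cyc/pixel under the default geometry)."""
    n = ci.shape
    f = radial_frequency_grid(n) / ci.pixel_angle_deg  # cyc/deg
    gain = 1.0 / np.sqrt(1.0 + (f / cutoff_cyc_per_deg) ** (2 * order))
    sm = np.fft.ifft2(np.fft.fft2(ci.weights) * gain).real
    return dataclasses.replace(ci, weights=sm)


def _radial_bins(shape: int, pixel_angle_deg: float
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Annular bin index per DFT frequency and the bin centers in cyc/deg.

    Annuli are one DFT step (1/shape cyc/pixel) wide; a bin's center is the
    mean radial frequency of its member grid points.
    """
    f = radial_frequency_grid(shape)
    k = np.rint(f * shape).astype(int)
    n_bins = k.max() + 1
    sums = np.bincount(k.ravel(), weights=f.ravel(), minlength=n_bins)
    counts = np.bincount(k.ravel(), minlength=n_bins)
    centers = sums / counts / pixel_angle_deg
    return k, centers


def radial_profile(ci: ClassificationImage, window_cutoff_deg: float = 1.05,
                   window_order: int = 4,
                   max_freq_cyc_deg: Optional[float] = None) -> RadialProfile:
    """Radially averaged frequency weights of a centered classification image.

    A radial spatial Butterworth window (cutoff ``window_cutoff_deg``) is
    applied around the image center before the Fourier transform; the real
    part is averaged in annuli one DFT step wide and the profile is
    normalized so the peak weight is 1.  The imaginary part is carried as a
    diagnostic.
    """
    if not np.any(ci.weights):
        raise ValueError("all-zero classification image")
    n = ci.shape
    d = np.arange(n) - n // 2
    r = np.hypot(d[:, None], d[None, :])
    r_c = window_cutoff_deg / ci.pixel_angle_deg
    window = 1.0 / np.sqrt(1.0 + (r / r_c) ** (2 * window_order))
    spec = np.fft.fft2(np.fft.ifftshift(ci.weights * window))
    k, centers = _radial_bins(n, ci.pixel_angle_deg)
    n_bins = len(centers)
    re = np.bincount(k.ravel(), weights=spec.real.ravel(), minlength=n_bins) \
        / np.bincount(k.ravel(), minlength=n_bins)
    im = np.bincount(k.ravel(), weights=spec.imag.ravel(), minlength=n_bins) \
        / np.bincount(k.ravel(), minlength=n_bins)
    if max_freq_cyc_deg is None:
        keep = centers <= centers[min(n // 2, n_bins - 1)]  # up to Nyquist
    else:
        keep = centers <= max_freq_cyc_deg
    re, im, centers = re[keep], im[keep], centers[keep]
    peak = np.abs(re).max()
    return RadialProfile(freq_cyc_deg=centers, weights=re / peak,
                         weights_imag=im / peak)


def io_frequency_weights(beta: float, sigma_pixels: float = 3.0,
                         shape: int = 256,
                         pixel_angle_deg: float = PIXEL_ANGLE_DEG
                         ) -> RadialProfile:
    """Analytic ideal-observer frequency weights, radially binned.

    The IO filter is the target spectrum over the noise spectrum, giving
    radial weights proportional to ``f^beta * exp(-2 pi^2 sigma^2 f^2)``;
    they are evaluated on the DFT grid, averaged in the same annuli as
    :func:`radial_profile`, and peak-normalized.  The continuous-formula
    peak sits at ``sqrt(beta) / (2 pi sigma)``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    f = radial_frequency_grid(shape)  # cyc/pixel
    w = np.where(f > 0, f, 0.0) ** beta * np.exp(
        -2.0 * np.pi**2 * sigma_pixels**2 * f**2)
    if beta == 0:
        w[0, 0] = 1.0
    k, centers = _radial_bins(shape, pixel_angle_deg)
    n_bins = len(centers)
    prof = np.bincount(k.ravel(), weights=w.ravel(), minlength=n_bins) \
        / np.bincount(k.ravel(), minlength=n_bins)
    keep = np.arange(n_bins) <= shape // 2
    prof, centers = prof[keep], centers[keep]
    return RadialProfile(freq_cyc_deg=centers, weights=prof / prof.max())


def analytic_io_peak(beta: float, sigma_pixels: float = 3.0,
                     pixel_angle_deg: float = PIXEL_ANGLE_DEG) -> float:
    """Continuous-formula peak frequency ``sqrt(beta)/(2 pi sigma)`` in cyc/deg."""
    sigma_deg = sigma_pixels * pixel_angle_deg
    return float(np.sqrt(beta) / (2.0 * np.pi * sigma_deg))


class ClassificationImageModel:
    """Model/Results wrapper around the classification-image estimators.

    ``kind`` defaults to the trial table's task: the four-class estimator
    for detection, the response-aligned false-localization estimator for
    localization and detect-and-localize records.
    """

    def __init__(self, trials: TrialSet, kind: Optional[str] = None,
                 pixel_angle_deg: float = PIXEL_ANGLE_DEG):
        self.trials = trials
        self.kind = kind or trials.frame["task"].iloc[0]
        self.pixel_angle_deg = pixel_angle_deg

    def fit(self) -> "ClassificationImageResults":
        if self.kind == "detection":
            ci = detection_ci(self.trials, self.pixel_angle_deg)
        else:
            ci = localization_ci(self.trials, self.pixel_angle_deg)
        return ClassificationImageResults(ci=ci)


@dataclass
class ClassificationImageResults:
    ci: ClassificationImage

    def smoothed(self, order: int = 4,
                 cutoff_cyc_per_deg: float = 5.6) -> ClassificationImage:
        return butterworth_smooth(self.ci, order, cutoff_cyc_per_deg)

    def radial_profile(self, **kw) -> RadialProfile:
        return radial_profile(self.ci, **kw)

    def summary(self) -> str:
        prof = self.radial_profile()
        return "\n".join([
            f"Classification image ({self.ci.task}, beta={self.ci.beta:g})",
            "-" * 40,
            f"trials used:     {self.ci.n_trials_used}",
            f"image shape:     {self.ci.shape} x {self.ci.shape}",
            f"peak frequency:  {prof.peak_frequency:.2f} cyc/deg",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.ci.cropped(), cmap="gray")
        ax.set_title(f"CI {self.ci.task} beta={self.ci.beta:g}")
        ax.set_xticks([])
        ax.set_yticks([])
        return ax
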