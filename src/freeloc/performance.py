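"""Performance analysis: contrast look-up tables, psychometric fits,
criterion matching, efficiency, and localization-deviation statistics.

Efficiency follows the squared-contrast-ratio definition
``eta = (C_IO / C_Obs)**2`` at matched performance: the ideal observer's
threshold contrast comes either from inverting a Monte-Carlo PC-vs-contrast
look-up table (localization) or from matching hit/false-alarm rates through
the closed-form Gaussian decision model (fixed-location detection), or from
a two-dimensional rate match (detect-and-localize).  Standard errors are
computed session-by-session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.isotonic import IsotonicRegression

from .observer import DEFAULT_RADIUS, disk_offsets
from .simulate import DetectionEngine, LocalizationEngine
from .stimulus import NoiseSpec, SpectrumGrid, TargetSpec

__all__ = [
    "LUT",
    "simulate_lut",
    "invert_lut",
    "PsychometricModel",
    "PsychometricResults",
    "fit_psychometric",
    "EfficiencyEstimate",
    "EfficiencyModel",
    "efficiency_localization",
    "match_detection_criterion",
    "match_dl_criterion",
    "localization_deviation",
    "DeviationSummary",
    "session_se",
    "binomial_se",
]

MAX_LUT_CONTRAST = 2.0


# ---------------------------------------------------------------------------
# Look-up tables
# ---------------------------------------------------------------------------

@dataclass
class LUT:
    """Monte-Carlo ideal-observer proportion correct vs. target contrast."""

    task: str
    beta: float
    contrast_grid: np.ndarray
    pc: np.ndarray
    n_per_point: int
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.contrast_grid = np.asarray(self.contrast_grid, dtype=float)
        self.pc = np.asarray(self.pc, dtype=float)
        if np.any(np.diff(self.contrast_grid) <= 0):
            raise ValueError("contrast grid must be strictly increasing")
        if np.any((self.pc < 0) | (self.pc > 1)):
            raise ValueError("pc values must lie in [0, 1]")

    def invert(self, pc_target: float = 0.80) -> float:
        return invert_lut(self, pc_target)

    def to_json(self, path=None) -> Optional[str]:
        obj = {
            "task": self.task,
            "beta": self.beta,
            "contrast_grid": self.contrast_grid.tolist(),
            "pc": self.pc.tolist(),
            "n_per_point": self.n_per_point,
            "seed": self.seed,
            "meta": self.meta,
        }
        text = json.dumps(obj, indent=1)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source: Union[str, dict]) -> "LUT":
        if isinstance(source, dict):
            obj = source
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            task=obj["task"], beta=obj["beta"],
            contrast_grid=np.asarray(obj["contrast_grid"]),
            pc=np.asarray(obj["pc"]),
            n_per_point=obj["n_per_point"], seed=obj["seed"],
            meta=obj.get("meta", {}),
        )


def simulate_lut(task: str, beta: float, *, n_per_point: int = 2000,
                 step: float = 0.01, stop_pc: float = 0.94, seed: int = 0,
                 shape: int = 256, sigma_pixels: float = 3.0,
                 radius_px: int = DEFAULT_RADIUS, mean_level: float = 100.0,
                 rms_contrast: float = 0.20,
                 engine: Optional[Union[DetectionEngine, LocalizationEngine]] = None,
                 dl_threshold: Optional[float] = None,
                 max_contrast: float = MAX_LUT_CONTRAST) -> LUT:
    """Build a PC-vs-contrast look-up table by Monte-Carlo simulation.

    The grid runs from contrast 0 in increments of ``step`` until PC exceeds
    ``stop_pc``; each point uses ``n_per_point`` simulated trials.  One bank
    of noise samples is reused across contrasts (common random numbers), so
    neighbouring points are positively correlated but each remains an
    unbiased ``n_per_point``-trial estimate.  Detect-and-localize tables
    require an explicit score criterion ``dl_threshold``.
    """
    noise = NoiseSpec(beta=beta, rms_contrast=rms_contrast,
                      mean_level=mean_level, shape=shape)
    target = TargetSpec(sigma_pixels=sigma_pixels)
    if engine is None:
        if task == "detection":
            engine = DetectionEngine(noise, target)
        else:
            engine = LocalizationEngine(noise, target, radius_px=radius_px)

    if task == "detection":
        t_noise = engine.sample_statistics(n_per_point, seed)
        def pc_at(c: float) -> float:
            return engine.pc_detection(t_noise, c)
    elif task == "localization":
        trials = engine.sample_trials(n_per_point, seed, present_prob=1.0)
        def pc_at(c: float) -> float:
            return engine.pc_localization(trials, c)
    elif task == "dandl":
        if dl_threshold is None:
            raise ValueError("dandl LUTs need an explicit dl_threshold "
                             "(the D&L criterion is a free parameter)")
        trials = engine.sample_trials(n_per_point, seed, present_prob=0.5)
        def pc_at(c: float) -> float:
            return engine.dandl_rates(trials, c, dl_threshold)[2]
    else:
        raise ValueError(f"unknown task {task!r}")

    grid, pcs = [], []
    c = 0.0
    while True:
        pc = pc_at(c)
        grid.append(c)
        pcs.append(pc)
        if pc > stop_pc:
            break
        c = round(c + step, 10)
        if c > max_contrast:
            raise RuntimeError(
                f"PC did not exceed {stop_pc} below contrast {max_contrast}")
    return LUT(task=task, beta=beta, contrast_grid=np.array(grid),
               pc=np.array(pcs), n_per_point=n_per_point, seed=int(seed),
               meta={"shape": shape, "sigma_pixels": sigma_pixels,
                     "radius_px": radius_px, "step": step,
                     "stop_pc": stop_pc, "mean_level": mean_level,
                     "rms_contrast": rms_contrast,
                     "dl_threshold": dl_threshold})


def invert_lut(lut: LUT, pc_target: float = 0.80) -> float:
    """Threshold contrast at ``pc_target`` by isotonic regularization of the
    Monte-Carlo PC curve followed by linear interpolation."""
    iso = IsotonicRegression(increasing=True)
    pc_iso = iso.fit_transform(lut.contrast_grid, lut.pc)
    if pc_target <= pc_iso[0] or pc_target > pc_iso[-1]:
        raise ValueError(
            f"pc_target={pc_target} outside the attained range "
            f"[{pc_iso[0]:.3f}, {pc_iso[-1]:.3f}]")
    i = int(np.searchsorted(pc_iso, pc_target, side="left"))
    c0, c1 = lut.contrast_grid[i - 1], lut.contrast_grid[i]
    p0, p1 = pc_iso[i - 1], pc_iso[i]
    return float(c0 + (c1 - c0) * (pc_target - p0) / (p1 - p0))


def binomial_se(pc: float, n: int) -> float:
    """Standard error of a proportion estimated from n Bernoulli trials."""
    return float(np.sqrt(pc * (1.0 - pc) / n))


# ---------------------------------------------------------------------------
# Psychometric functions
# ---------------------------------------------------------------------------

class PsychometricModel:
    """Cumulative-Gaussian psychometric function fitted to binomial counts.

    The performance model is ``p(c) = floor + (1 - floor) * Phi((c - mu) /
    sigma)`` with chance level ``floor`` (0.5 for yes/no detection,
    approximately the disk/search area ratio for free localization).  The
    fit is maximum-likelihood under independent binomial counts.
    """

    def __init__(self, levels: Sequence[float], n_correct: Sequence[int],
                 n_trials: Sequence[int], floor: float = 0.5):
        self.levels = np.asarray(levels, dtype=float)
        self.n_correct = np.asarray(n_correct, dtype=float)
        self.n_trials = np.asarray(n_trials, dtype=float)
        self.floor = float(floor)
        if len(self.levels) < 3:
            raise ValueError("need at least 3 contrast levels")
        if not (len(self.levels) == len(self.n_correct) == len(self.n_trials)):
            raise ValueError("levels, n_correct, n_trials must align")
        if np.any(self.n_correct > self.n_trials) or np.any(self.n_correct < 0):
            raise ValueError("invalid counts")
        if not 0 <= floor < 1:
            raise ValueError("floor must lie in [0, 1)")
        phat = self.n_correct / self.n_trials
        pooled_se = np.sqrt(max(floor * (1 - floor), 0.25 / self.n_trials.max())
                            / self.n_trials.sum())
        if phat.max() <= self.floor + max(0.02, 3 * pooled_se):
            raise ValueError(
                "degenerate data: performance never rises above chance; "
                "collect data at higher contrasts")
        if phat.min() >= 0.99:
            raise ValueError(
                "degenerate data: performance saturated at every level; "
                "collect data at lower contrasts")

    def _nll(self, params: np.ndarray) -> float:
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        p = self.floor + (1 - self.floor) * stats.norm.cdf(
            (self.levels - mu) / sigma)
        p = np.clip(p, 1e-10, 1 - 1e-10)
        return -float(np.sum(self.n_correct * np.log(p)
                             + (self.n_trials - self.n_correct) * np.log1p(-p)))

    def fit(self) -> "PsychometricResults":
        phat = self.n_correct / self.n_trials
        mid = self.floor + 0.5 * (1 - self.floor)
        mu0 = float(np.interp(mid, np.maximum.accumulate(phat), self.levels))
        sigma0 = max((self.levels.max() - self.levels.min()) / 4, 1e-3)
        x0 = np.array([mu0, np.log(sigma0)])
        res = optimize.minimize(self._nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 2000})
        mu, sigma = res.x[0], float(np.exp(res.x[1]))
        # observed-information standard errors on (mu, sigma)
        bse = self._bse(mu, sigma)
        return PsychometricResults(model=self, mu=float(mu), sigma=sigma,
                                   loglik=-float(res.fun), bse=bse,
                                   converged=bool(res.success))

    def _bse(self, mu: float, sigma: float) -> Tuple[float, float]:
        def nll_ms(p):
            return self._nll(np.array([p[0], np.log(max(p[1], 1e-12))]))
        h = np.array([max(1e-4, 1e-4 * abs(mu)), 1e-4 * sigma])
        x = np.array([mu, sigma])
        hess = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                hess[i, j] = (nll_ms(x + ei + ej) - nll_ms(x + ei - ej)
                              - nll_ms(x - ei + ej) + nll_ms(x - ei - ej)) \
                    / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(hess)
            d = np.diag(cov)
            if np.all(d > 0):
                return float(np.sqrt(d[0])), float(np.sqrt(d[1]))
        except np.linalg.LinAlgError:
            pass
        return float("nan"), float("nan")


@dataclass
class PsychometricResults:
    """MLE fit of the cumulative-Gaussian psychometric function."""

    model: PsychometricModel
    mu: float
    sigma: float
    loglik: float
    bse: Tuple[float, float]
    converged: bool

    def predict(self, contrast) -> np.ndarray:
        c = np.asarray(contrast, dtype=float)
        f = self.model.floor
        return f + (1 - f) * stats.norm.cdf((c - self.mu) / self.sigma)

    def threshold_at(self, pc: float = 0.80) -> float:
        f = self.model.floor
        if not f < pc < 1:
            raise ValueError(f"pc={pc} not attainable above floor {f}")
        return float(self.mu + self.sigma * stats.norm.ppf((pc - f) / (1 - f)))

    def summary(self) -> str:
        lines = [
            "Cumulative-Gaussian psychometric fit",
            "------------------------------------",
            f"levels:        {len(self.model.levels)}"
            f"  (n = {int(self.model.n_trials.sum())} trials)",
            f"floor (chance): {self.model.floor:.4f}",
            f"mu:            {self.mu:.4f}  (se {self.bse[0]:.4f})",
            f"sigma:         {self.sigma:.4f}  (se {self.bse[1]:.4f})",
            f"log-likelihood: {self.loglik:.2f}",
            f"80% threshold:  {self.threshold_at(0.80):.4f}",
        ]
        return "\n".join(lines)


def fit_psychometric(levels, n_correct, n_trials,
                     floor: float = 0.5) -> PsychometricResults:
    """Convenience wrapper: ``PsychometricModel(...).fit()``."""
    return PsychometricModel(levels, n_correct, n_trials, floor=floor).fit()


# ---------------------------------------------------------------------------
# Criterion matching
# ---------------------------------------------------------------------------

def match_detection_criterion(hit_rate: float, fa_rate: float,
                              target: TargetSpec, spectrum: SpectrumGrid,
                              mean_level: float = 100.0
                              ) -> Tuple[float, float]:
    """Contrast and criterion at which the detection IO reproduces observed
    hit and false-alarm rates.

    Solves the Gaussian equal-variance system: ``z(hit) - z(fa) = c * d'_1``
    with ``d'_1`` the detectability per unit contrast, and places ``t_crit``
    so the false-alarm rate matches.  Returns ``(c_io, t_crit)`` with
    ``t_crit`` in decision-statistic units.
    """
    if not (0 < fa_rate < 1 and 0 < hit_rate < 1):
        raise ValueError("rates must lie strictly inside (0, 1)")
    if hit_rate <= fa_rate:
        raise ValueError("hit rate must exceed the false-alarm rate")
    from .observer import analytic_dprime
    dprime_per_c = analytic_dprime(target, spectrum, mean_level=mean_level)
    dprime = stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate)
    c_io = dprime / dprime_per_c
    sd_stat = dprime_per_c / mean_level  # sqrt(s' Sigma^-1 s)
    t_crit = float(sd_stat * stats.norm.ppf(1.0 - fa_rate))
    return float(c_io), t_crit


def match_dl_criterion(correct_dl_rate: float, fp_rate: float,
                       engine: LocalizationEngine, *, n_sim: int = 2000,
                       seed: int = 0, c_bracket: Tuple[float, float] = (1e-3, 1.5),
                       xtol: float = 1e-4) -> Tuple[float, float]:
    """Contrast and score criterion at which the D&L ideal observer
    reproduces an observed (correct-D&L rate, false-positive rate) pair.

    For a candidate contrast the criterion is pinned to the empirical
    ``1 - fp_rate`` quantile of the absent-trial maximum disk scores, then
    the contrast is root-found so the present-trial correct-D&L rate
    matches.  Common random numbers (one trial bank across the whole search)
    keep both maps smooth in contrast.
    """
    if not (0 < correct_dl_rate < 1 and 0 < fp_rate < 1):
        raise ValueError("rates must lie strictly inside (0, 1)")
    ss = np.random.SeedSequence(seed).spawn(2)
    pres = engine.sample_trials(n_sim, ss[0], present_prob=1.0)
    absent = engine.sample_trials(n_sim, ss[1], present_prob=0.0)

    def rates_at(c: float) -> Tuple[float, float]:
        score_a, _ = engine.score_trials(absent, c)
        thr = float(np.quantile(score_a, 1.0 - fp_rate))
        score_p, loc_ok = engine.score_trials(pres, c)
        return float(np.mean((score_p > thr) & loc_ok)), thr

    def gap(c: float) -> float:
        return rates_at(c)[0] - correct_dl_rate

    lo, hi = c_bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo > 0 or g_hi < 0:
        raise ValueError(
            f"rate pair unattainable on contrast bracket {c_bracket}: "
            f"correct-D&L spans [{g_lo + correct_dl_rate:.3f}, "
            f"{g_hi + correct_dl_rate:.3f}] at fp={fp_rate:.3f}")
    c_io = float(optimize.brentq(gap, lo, hi, xtol=xtol))
    _, thr = rates_at(c_io)
    return c_io, float(thr)


# ---------------------------------------------------------------------------
# Efficiency
# ---------------------------------------------------------------------------

@dataclass
class EfficiencyEstimate:
    """Observer efficiency ``eta = (c_io / c_obs)**2`` for one condition."""

    eta: float
    c_obs: float
    c_io: float
    task: str
    beta: float
    per_session: np.ndarray = field(default_factory=lambda: np.array([]))
    se: float = float("nan")

    def __post_init__(self) -> None:
        self.per_session = np.asarray(self.per_session, dtype=float)

    @property
    def eta_percent(self) -> float:
        return 100.0 * self.eta

    def summary(self) -> str:
        lines = [
            f"Efficiency ({self.task}, beta={self.beta:g})",
            "-" * 36,
            f"observer threshold contrast C_obs: {self.c_obs:.4f}",
            f"IO-equivalent contrast C_io:       {self.c_io:.4f}",
            f"efficiency eta = (C_io/C_obs)^2:   {self.eta:.4f}"
            f"  ({self.eta_percent:.1f}%)",
        ]
        if self.per_session.size:
            lines.append(f"sessions: {self.per_session.size}"
                         f"   se(eta) = {self.se:.4f}")
        return "\n".join(lines)


def efficiency_localization(c_obs: float, pc_obs: float, lut: LUT,
                            per_session: Optional[Sequence[Tuple[float, float]]] = None
                            ) -> EfficiencyEstimate:
    """Localization efficiency from an observed (contrast, PC) pair and an
    ideal-observer LUT.  ``per_session`` holds optional (c_obs, pc) pairs for
    session-wise standard errors."""
    c_io = invert_lut(lut, pc_obs)
    eta = (c_io / c_obs) ** 2
    sess = np.array([])
    se = float("nan")
    if per_session is not None:
        vals = []
        for c_s, pc_s in per_session:
            try:
                vals.append((invert_lut(lut, pc_s) / c_s) ** 2)
            except ValueError:
                vals.append(np.nan)
        sess = np.asarray(vals, dtype=float)
        good = sess[np.isfinite(sess)]
        if good.size >= 2:
            se = session_se(good)
    return EfficiencyEstimate(eta=float(eta), c_obs=float(c_obs),
                              c_io=float(c_io), task=lut.task, beta=lut.beta,
                              per_session=sess, se=se)


class EfficiencyModel:
    """Efficiency of an observer's trial records against the ideal observer.

    Built from a trial table (one condition: fixed task, beta, contrast)
    plus the matching ideal-observer machinery: a :class:`LUT` for
    localization, the target/spectrum pair for detection, or a
    :class:`LocalizationEngine` for detect-and-localize.  ``fit`` pools all
    trials for the point estimate and repeats the calculation per session
    for the standard error.
    """

    def __init__(self, frame: pd.DataFrame, *, task: Optional[str] = None,
                 lut: Optional[LUT] = None,
                 target: Optional[TargetSpec] = None,
                 spectrum: Optional[SpectrumGrid] = None,
                 engine: Optional[LocalizationEngine] = None,
                 n_match: int = 2000, seed: int = 0):
        if hasattr(frame, "frame"):  # accept a TrialSet
            frame = frame.frame
        self.frame = frame
        self.task = task or frame["task"].iloc[0]
        self.lut = lut
        self.target = target
        self.spectrum = spectrum
        self.engine = engine
        self.n_match = n_match
        self.seed = seed
        c = frame["contrast"].unique()
        if len(c) != 1:
            raise ValueError("efficiency needs records at a single contrast")
        self.c_obs = float(c[0])
        self.beta = float(frame["beta"].iloc[0])

    def _sessions(self):
        if "session" in self.frame and self.frame["session"].nunique() >= 2:
            return list(self.frame.groupby("session"))
        return []

    def fit(self) -> EfficiencyEstimate:
        if self.task == "detection":
            est = self._fit_detection()
        elif self.task == "localization":
            est = self._fit_localization()
        elif self.task == "dandl":
            est = self._fit_dandl()
        else:
            raise ValueError(f"unknown task {self.task!r}")
        return est

    def _fit_localization(self) -> EfficiencyEstimate:
        if self.lut is None:
            raise ValueError("localization efficiency needs an IO LUT")
        pooled_pc = float(self.frame["correct"].mean())
        per = [(self.c_obs, float(g["correct"].mean()))
               for _, g in self._sessions()]
        return efficiency_localization(self.c_obs, pooled_pc, self.lut,
                                       per_session=per or None)

    def _fit_detection(self) -> EfficiencyEstimate:
        if self.target is None or self.spectrum is None:
            raise ValueError("detection efficiency needs target and spectrum")
        mean_level = float(self.frame.get("mean_level", pd.Series([100.0])).iloc[0])

        def one(df) -> float:
            pres = df["present"].astype(bool)
            hit = float(df.loc[pres, "detected"].mean())
            fa = float(df.loc[~pres, "detected"].mean())
            # keep rates away from 0/1 for the probit transform
            n_p, n_a = pres.sum(), (~pres).sum()
            hit = min(max(hit, 0.5 / n_p), 1 - 0.5 / n_p)
            fa = min(max(fa, 0.5 / n_a), 1 - 0.5 / n_a)
            c_io, _ = match_detection_criterion(hit, fa, self.target,
                                                self.spectrum,
                                                mean_level=mean_level)
            return c_io

        c_io = one(self.frame)
        sess = np.array([(one(g) / self.c_obs) ** 2
                         for _, g in self._sessions()])
        se = session_se(sess) if sess.size >= 2 else float("nan")
        return EfficiencyEstimate(eta=float((c_io / self.c_obs) ** 2),
                                  c_obs=self.c_obs, c_io=float(c_io),
                                  task="detection", beta=self.beta,
                                  per_session=sess, se=se)

    def _fit_dandl(self) -> EfficiencyEstimate:
        if self.engine is None:
            raise ValueError("D&L efficiency needs a LocalizationEngine")

        def one(df, seed) -> float:
            pres = df["present"].astype(bool)
            cdl = float((df.loc[pres, "detected"] & df.loc[pres, "correct"]).mean())
            fp = float(df.loc[~pres, "detected"].mean())
            n_p, n_a = pres.sum(), (~pres).sum()
            cdl = min(max(cdl, 0.5 / n_p), 1 - 0.5 / n_p)
            fp = min(max(fp, 0.5 / n_a), 1 - 0.5 / n_a)
            c_io, _ = match_dl_criterion(cdl, fp, self.engine,
                                         n_sim=self.n_match, seed=seed)
            return c_io

        c_io = one(self.frame, self.seed)
        sess = np.array([(one(g, self.seed) / self.c_obs) ** 2
                         for _, g in self._sessions()])
        se = session_se(sess) if sess.size >= 2 else float("nan")
        return EfficiencyEstimate(eta=float((c_io / self.c_obs) ** 2),
                                  c_obs=self.c_obs, c_io=float(c_io),
                                  task="dandl", beta=self.beta,
                                  per_session=sess, se=se)


# ---------------------------------------------------------------------------
# Response deviation and session statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviationSummary:
    mean_px: float
    mean_deg: Optional[float]
    n_correct: int
    uniform_px: float
    uniform_deg: Optional[float]


def uniform_disk_deviation(radius_px: int = DEFAULT_RADIUS) -> float:
    """Mean distance from center for responses uniform over the discrete
    acceptance region (the integer lattice points within the radius)."""
    offs = disk_offsets(radius_px)
    return float(np.hypot(offs[:, 0], offs[:, 1]).mean())


def localization_deviation(records: pd.DataFrame,
                           radius_px: int = DEFAULT_RADIUS,
                           pixel_angle_deg: Optional[float] = None
                           ) -> DeviationSummary:
    """Mean distance of correct localization responses from the true target
    location, with the uniform-over-acceptance-region baseline."""
    if hasattr(records, "frame"):
        records = records.frame
    ok = records[records["correct"].astype(bool)
                 & records["response_x"].notna()
                 & records["loc_x"].notna()]
    if len(ok) == 0:
        raise ValueError("no correct localization trials in the records")
    d = np.hypot(ok["response_y"] - ok["loc_y"], ok["response_x"] - ok["loc_x"])
    mean_px = float(d.mean())
    uni = uniform_disk_deviation(radius_px)
    deg = (mean_px * pixel_angle_deg) if pixel_angle_deg else None
    uni_deg = (uni * pixel_angle_deg) if pixel_angle_deg else None
    return DeviationSummary(mean_px=mean_px, mean_deg=deg,
                            n_correct=int(len(ok)),
                            uniform_px=uni, uniform_deg=uni_deg)


def session_se(per_session_values: Sequence[float]) -> float:
    """Standard error across sessions: sd / sqrt(#sessions)."""
    v = np.asarray(per_session_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 sessions")
    return float(np.std(v, ddof=1) / np.sqrt(v.size))
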