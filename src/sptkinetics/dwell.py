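"""Residence-time analysis of slow-tracking data.

At long exposures (hundreds of ms) diffusing molecules blur out and only
chromatin-bound molecules appear as diffraction-limited spots.  The length
of each bound track measures the time before unbinding *or* photobleaching.
The analysis chain is: extract dwell times from trajectories, build the
survival curve S(t) = fraction of events lasting at least t, fit a
two-exponential decay (fast, non-specific binding plus slow, specific
binding), and subtract the apparent off-rate of a stably bound histone
control to remove the photobleaching contribution:

    S(t) ~ A exp(-k_fast t) + (1 - A) exp(-k_slow t)
    k_corrected = k_slow(sample) - k_slow(control)
    residence time = 1 / k_corrected,   apparent half-life = ln 2 / k_corrected
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import lmfit

from .trajectories import TrajectoryDataset

__all__ = [
    "DwellTimeSample",
    "SurvivalCurve",
    "BiexpFit",
    "ResidenceTimeResult",
    "EmptySampleError",
    "DegenerateCurveError",
    "extract_dwells",
    "survival",
    "fit_biexp",
    "correct_and_summarize",
    "read_dwell_sample",
    "write_dwell_sample",
]


class EmptySampleError(ValueError):
    """No qualifying bound trajectory / empty dwell sample."""


class DegenerateCurveError(ValueError):
    """Survival curve has too few distinct time points to fit."""


@dataclass(frozen=True)
class DwellTimeSample:
    """Observed bound-molecule dwell durations (seconds).

    ``censored[i]`` is True when event i was still bound when the movie
    ended, so its true duration is only known to be >= ``durations_s[i]``.
    """

    durations_s: np.ndarray
    censored: np.ndarray
    frame_interval_s: float
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.durations_s, dtype=float)
        c = np.asarray(self.censored, dtype=bool)
        object.__setattr__(self, "durations_s", d)
        object.__setattr__(self, "censored", c)
        if d.size == 0:
            raise EmptySampleError("dwell sample is empty")
        if d.shape != c.shape:
            raise ValueError("durations and censoring flags differ in length")
        if not (d > 0).all():
            raise ValueError("dwell durations must be positive")

    def __len__(self) -> int:
        return int(self.durations_s.size)


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survival S(t): fraction of events with duration >= t."""

    t_s: np.ndarray
    s: np.ndarray
    n_events: int
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "at_risk", np.asarray(self.at_risk, dtype=np.int64))
        if s[0] != 1.0:
            raise ValueError("S(0) must be 1")
        if (np.diff(s) > 1e-12).any():
            raise ValueError("survival must be nonincreasing")
        if (s < 0).any():
            raise ValueError("survival must be nonnegative")


@dataclass(frozen=True)
class BiexpFit:
    """Two-exponential survival fit; the slow component is read as specific
    binding, the fast one as non-specific binding."""

    amplitude_fast: float
    k_fast_per_s: float
    k_slow_per_s: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude_fast <= 1.0):
            raise ValueError("amplitude must lie in [0, 1]")
        if not (self.k_fast_per_s >= self.k_slow_per_s > 0):
            raise ValueError("rates must satisfy k_fast >= k_slow > 0")

    @property
    def effectively_monoexponential(self) -> bool:
        """True when the two components are indistinguishable (amplitude at
        a boundary or rates within 1%)."""
        return (self.amplitude_fast < 1e-3 or self.amplitude_fast > 1 - 1e-3
                or self.k_fast_per_s / self.k_slow_per_s < 1.01)

    def predict(self, t: np.ndarray) -> np.ndarray:
        a = self.amplitude_fast
        return a * np.exp(-self.k_fast_per_s * t) + (1 - a) * np.exp(-self.k_slow_per_s * t)


@dataclass(frozen=True)
class ResidenceTimeResult:
    """Photobleaching-corrected binding kinetics.

    When the control off-rate exceeds the sample's the measurement is
    bleach-limited and no residence time is emitted (``resolvable`` False).
    """

    k_apparent_per_s: float
    k_bleach_per_s: float
    k_corrected_per_s: float
    resolvable: bool
    residence_time_s: Optional[float]
    half_life_s: Optional[float]

    def to_dict(self) -> dict:
        d = {
            "k_apparent_per_s": self.k_apparent_per_s,
            "k_bleach_per_s": self.k_bleach_per_s,
            "k_corrected_per_s": self.k_corrected_per_s,
            "resolvable": self.resolvable,
            "residence_time_s": self.residence_time_s,
            "half_life_s": self.half_life_s,
        }
        if not self.resolvable:
            d["status"] = "bleach-limited, residence time unresolvable"
        return d


def extract_dwells(
    dataset: TrajectoryDataset,
    bound_criterion_um: float = 0.22,
    min_frames: int = 2,
    movie_frames: Optional[int] = None,
) -> DwellTimeSample:
    """Identify bound molecules and measure how long each stayed bound.

    A trajectory qualifies when every displacement between successive
    localizations is at most ``bound_criterion_um`` and it spans at least
    ``min_frames`` frames.  The dwell is (frame span) x frame interval; a
    track touching the final movie frame is right-censored.
    """
    dt = dataset.settings.frame_interval_s
    if dt < 0.1:
        raise ValueError(
            f"dwell extraction expects slow-tracking data (frame interval >= 0.1 s), "
            f"got {dt} s")
    if movie_frames is None:
        last_frame = max(int(t.frames[-1]) for t in dataset.trajectories)
    else:
        last_frame = movie_frames - 1
    durations, censored = [], []
    for traj in dataset.trajectories:
        if len(traj) < min_frames:
            continue
        xy = traj.xy
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        if (steps > bound_criterion_um).any():
            continue
        frames = traj.frames
        durations.append((frames[-1] - frames[0]) * dt)
        censored.append(frames[-1] >= last_frame)
    if not durations:
        raise EmptySampleError("no trajectory satisfies the bound criterion")
    return DwellTimeSample(np.array(durations), np.array(censored), dt,
                           dict(dataset.metadata))


def survival(sample: DwellTimeSample) -> SurvivalCurve:
    """Empirical survival curve on the observed duration grid.

    Censored events count as "still bound" up to their observed duration,
    which is exact for t up to the censoring horizon when all events start
    within the movie.
    """
    d = sample.durations_s
    n = d.size
    grid = np.unique(np.concatenate([[0.0], d]))
    at_risk = (d[None, :] >= grid[:, None] - 1e-12).sum(axis=1)
    return SurvivalCurve(grid, at_risk / n, n, at_risk)


def _biexp_residual(params: lmfit.Parameters, t: np.ndarray, s: np.ndarray,
                    w: np.ndarray) -> np.ndarray:
    a = params["amplitude_fast"].value
    ks = params["k_slow"].value
    kf = ks * params["rate_ratio"].value
    model = a * np.exp(-kf * t) + (1 - a) * np.exp(-ks * t)
    return (model - s) * w


def fit_biexp(
    curve: SurvivalCurve,
    n_starts: int = 8,
    starts_seed: int = 0,
    min_at_risk: int = 5,
    ml_refine: bool = True,
) -> BiexpFit:
    """Weighted least-squares fit of a two-exponential survival model.

    Residuals are weighted by sqrt(events at risk) so the noisy tail does
    not dominate, and points where fewer than ``min_at_risk`` events remain
    are dropped.  Because empirical at-risk counts fluctuate with the same
    noise as the curve itself (which biases the slow rate low), the fit is
    re-run once with weights taken from the fitted model's at-risk counts.
    Multi-start over log-spaced rate initialisations; the lowest-residual
    solution wins (deterministic given ``starts_seed``).  With ``ml_refine``
    the solution is polished by maximizing the interval-censored multinomial
    likelihood of the at-risk counts, which restores the efficiency the
    correlated survival residuals lose.
    """
    keep = curve.at_risk >= min_at_risk
    t, s = curve.t_s[keep], curve.s[keep]
    w = np.sqrt(curve.at_risk[keep])
    if np.unique(t).size < 6:
        raise DegenerateCurveError(
            f"need >= 6 distinct time points after truncation, have {np.unique(t).size}")
    # Events shorter than the first observable duration are missing, so the
    # empirical curve is conditioned on surviving until the first grid point
    # with S = 1.  Anchoring the model's S = 1 constraint there (rather than
    # at t = 0) keeps the two-exponential form exact and the rates unbiased.
    t0 = float(t[s >= 1.0 - 1e-12].max()) if (s >= 1.0 - 1e-12).any() else float(t[0])
    sel = t >= t0
    t, s, w = t[sel] - t0, s[sel], w[sel]

    t_span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    # a decay slower than ~half the record is indistinguishable from a
    # constant plateau, so the slow rate is bounded away from that regime
    k_lo, k_hi = 0.5 / t_span, 1e3 / t_span
    rng = np.random.default_rng(starts_seed)
    # log-spaced slow-rate starts spanning the observable window, jittered
    base = np.geomspace(0.1 / t_span, 30.0 / t_span, n_starts)
    starts = base * np.exp(rng.uniform(-0.2, 0.2, n_starts))

    def _multistart(weights: np.ndarray):
        best = None
        for ks0 in starts:
            params = lmfit.Parameters()
            params.add("amplitude_fast", value=0.5, min=0.0, max=1.0)
            params.add("k_slow", value=float(np.clip(ks0, k_lo, k_hi)),
                       min=k_lo, max=k_hi)
            params.add("rate_ratio", value=20.0, min=1.0, max=1e5)
            try:
                res = lmfit.minimize(_biexp_residual, params, args=(t, s, weights),
                                     method="least_squares")
            except Exception:
                continue
            rss = float(np.sum(res.residual**2))
            if best is None or rss < best[0]:
                best = (rss, res.params)
        if best is None:
            raise RuntimeError("bi-exponential fit failed to converge on all starts")
        return best

    rss, p = _multistart(w)
    # model-based reweighting pass (weights independent of the noise)
    a0, ks0 = p["amplitude_fast"].value, p["k_slow"].value
    model_s = (a0 * np.exp(-ks0 * p["rate_ratio"].value * t)
               + (1 - a0) * np.exp(-ks0 * t))
    w2 = np.sqrt(np.maximum(curve.n_events * model_s, float(min_at_risk)))
    rss, p = _multistart(w2)
    ks = float(p["k_slow"].value)
    kf = float(ks * p["rate_ratio"].value)
    a = float(p["amplitude_fast"].value)

    # nested-model guard: on effectively single-exponential data the second
    # component only chases noise (splitting the true rate in two), so the
    # mono-exponential fit is kept unless the biexponential at least halves
    # the weighted residual
    mono = _monoexp_fit(t, s, w2, k_lo, k_hi)
    collapsed = False
    if mono is not None and rss > 0.5 * mono[0]:
        rss, k_mono = mono
        ks = kf = k_mono
        a = 1.0
        collapsed = True
    # a component carrying < 5% amplitude is not a real second phase:
    # collapse to the dominant rate so the slow rate reported downstream is
    # the one carrying the mass
    elif 1.0 - a < 0.05:
        ks, a, collapsed = kf, 1.0, True
    elif a < 0.05:
        kf, a, collapsed = ks, 0.0, True
    if ml_refine:
        a, kf, ks = _ml_polish(curve, t0, a, kf, ks, mono_only=collapsed)
    return BiexpFit(amplitude_fast=a, k_fast_per_s=kf, k_slow_per_s=ks,
                    rss=rss, n_points=int(t.size))


def _ml_polish(curve: SurvivalCurve, t0: float, a: float, kf: float,
               ks: float, mono_only: bool) -> tuple[float, float, float]:
    """Refine the curve-fit solution by maximizing the interval-censored
    multinomial likelihood of the at-risk counts.

    The weighted least-squares fit ignores the correlation structure of the
    empirical survival curve; the multinomial likelihood restores full
    statistical efficiency.  Events still at risk at the last grid point
    are treated as right-censored there.
    """
    from scipy.optimize import minimize as _minimize

    sel = curve.t_s >= t0
    t = curve.t_s[sel] - t0
    at_risk = curve.at_risk[sel].astype(float)
    counts = at_risk[:-1] - at_risk[1:]
    n_tail = at_risk[-1]
    eps = 1e-300

    def survival_model(theta, tt):
        if mono_only:
            return np.exp(-math.exp(theta[0]) * tt)
        aa = 1.0 / (1.0 + math.exp(-theta[0]))
        return (aa * np.exp(-math.exp(theta[1]) * tt)
                + (1 - aa) * np.exp(-math.exp(theta[2]) * tt))

    def nll(theta):
        s_model = survival_model(theta, t)
        p = s_model[:-1] - s_model[1:]
        ll = float(np.sum(counts * np.log(np.maximum(p, eps))))
        ll += float(n_tail * math.log(max(s_model[-1], eps)))
        return -ll

    if mono_only:
        starts = [[math.log(max(ks, 1e-12))]]
    else:
        a_c = min(max(a, 1e-3), 1 - 1e-3)
        la = math.log(a_c / (1 - a_c))
        lkf, lks = math.log(max(kf, 1e-12)), math.log(max(ks, 1e-12))
        # perturbed restarts guard against ridge-shaped local optima
        starts = [[la, lkf, lks],
                  [la, lkf + 0.3, lks - 0.15],
                  [la, lkf - 0.3, lks + 0.15]]
    best = None
    for theta0 in starts:
        res = _minimize(nll, theta0, method="Nelder-Mead",
                        options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-10})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun > nll(np.asarray(starts[0])) + 1e-9:
        return a, kf, ks  # keep the curve-fit solution
    th = best.x
    if mono_only:
        k = float(math.exp(th[0]))
        return a, k, k
    aa = float(1.0 / (1.0 + math.exp(-th[0])))
    k1, k2 = float(math.exp(th[1])), float(math.exp(th[2]))
    if k1 < k2:
        k1, k2, aa = k2, k1, 1 - aa
    return aa, k1, k2


def _monoexp_fit(t: np.ndarray, s: np.ndarray, w: np.ndarray,
                 k_lo: float, k_hi: float):
    """Weighted single-exponential fit; returns (rss, k) or None."""
    k0 = -math.log(max(float(s[-1]), 1e-9)) / max(float(t[-1]), 1e-12)
    params = lmfit.Parameters()
    params.add("amplitude_fast", value=0.0, vary=False)
    params.add("k_slow", value=float(np.clip(k0, k_lo, k_hi)), min=k_lo, max=k_hi)
    params.add("rate_ratio", value=1.0, vary=False)
    try:
        res = lmfit.minimize(_biexp_residual, params, args=(t, s, w),
                             method="least_squares")
    except Exception:
        return None
    return float(np.sum(res.residual**2)), float(res.params["k_slow"].value)


def correct_and_summarize(fit: BiexpFit, control_fit: BiexpFit) -> ResidenceTimeResult:
    """Subtract the control's apparent off-rate (photobleaching) from the
    sample's slow off-rate and convert to residence time and half-life."""
    k_app = fit.k_slow_per_s
    k_bleach = control_fit.k_slow_per_s
    k_corr = k_app - k_bleach
    if k_corr <= 0:
        return ResidenceTimeResult(k_app, k_bleach, k_corr, False, None, None)
    return ResidenceTimeResult(
        k_apparent_per_s=k_app,
        k_bleach_per_s=k_bleach,
        k_corrected_per_s=k_corr,
        resolvable=True,
        residence_time_s=1.0 / k_corr,
        half_life_s=math.log(2) / k_corr,
    )


def write_dwell_sample(sample: DwellTimeSample, path: Union[str, Path]) -> None:
    pd.DataFrame({
        "duration_s": sample.durations_s,
        "censored": sample.censored.astype(int),
    }).to_csv(Path(path), index=False)


def read_dwell_sample(path: Union[str, Path], frame_interval_s: float,
                      metadata: Optional[Mapping[str, object]] = None) -> DwellTimeSample:
    df = pd.read_csv(Path(path))
    return DwellTimeSample(df["duration_s"].to_numpy(float),
                           df["censored"].to_numpy(bool),
                           frame_interval_s, dict(metadata or {}))
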