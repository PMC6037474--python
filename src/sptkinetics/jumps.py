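"""Jump-length distributions and multi-state Brownian mixture fitting.

Fast-tracking spaSPT yields, for each time lag n·Δτ (n = 1..jumps
considered), the distribution of planar displacements r.  For a single
Brownian state with diffusion coefficient D observed with static
localization error σ the jump-length CDF is

    P(r <= R) = 1 - exp(-R² / (4 (D Δt + σ²))),

and the data are modelled as a 2- or 3-state mixture of such kernels.
Because diffusing molecules wander axially out of the detection slab while
bound ones do not, the mixture weight of state k at lag n·Δτ is its
equilibrium fraction F_k multiplied by a defocalization survival Z_k
(see :mod:`sptkinetics.defocalization`) and renormalized:

    w_k(nΔτ) = F_k Z_k(nΔτ) / Σ_j F_j Z_j(nΔτ).

Fitting minimizes stacked residuals between empirical and model CDFs
across all lags simultaneously (CDF fitting, not histogram fitting), with
multi-start box-constrained least squares.  The bound state's D is fitted
within a small window (default [0, 0.08] µm²/s) rather than pinned to 0,
since chromatin-bound molecules retain residual motion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .defocalization import z_correction, z_correction_profile
from .trajectories import TrajectoryDataset

__all__ = [
    "JumpLengthDistribution",
    "KineticModelSpec",
    "KineticFit",
    "ModelComparison",
    "EmptyDistributionError",
    "collect_jumps",
    "merge_distributions",
    "jump_cdf_model",
    "fit_kinetic_model",
    "compare_models",
    "summarize_bound_fraction",
]

logger = logging.getLogger(__name__)


class EmptyDistributionError(ValueError):
    """Dataset yields no displacements at lag 1."""


@dataclass(frozen=True)
class JumpLengthDistribution:
    """Pooled displacements per frame-lag multiple.

    ``jumps[n]`` holds the sorted displacements (µm) between detections
    separated by exactly n frames, n = 1..jumps_considered.
    """

    frame_interval_s: float
    jumps: Mapping[int, np.ndarray]

    def __post_init__(self) -> None:
        sorted_jumps = {}
        for n, r in self.jumps.items():
            arr = np.sort(np.asarray(r, dtype=float))
            if (arr < 0).any():
                raise ValueError("displacements must be nonnegative")
            sorted_jumps[int(n)] = arr
        object.__setattr__(self, "jumps", sorted_jumps)

    @property
    def lags(self) -> list[int]:
        return sorted(self.jumps)

    def counts(self) -> dict[int, int]:
        return {n: int(r.size) for n, r in self.jumps.items()}

    def empirical_cdf(self, lag: int, radius_grid: np.ndarray) -> np.ndarray:
        """Empirical CDF of lag-``lag`` displacements on ``radius_grid``;
        nondecreasing from 0 to 1."""
        r = self.jumps[lag]
        if r.size == 0:
            raise EmptyDistributionError(f"no displacements at lag {lag}")
        return np.searchsorted(r, radius_grid, side="right") / r.size


def collect_jumps(
    dataset: TrajectoryDataset,
    jumps_considered: Optional[int] = None,
) -> JumpLengthDistribution:
    """Pool displacements between detections exactly n frames apart.

    A displacement spanning a one-frame blink gap is n = 2 frames apart and
    therefore contributes to lag 2, never to lag 1.
    """
    n_max = jumps_considered or dataset.settings.jumps_considered
    pooled: dict[int, list[np.ndarray]] = {n: [] for n in range(1, n_max + 1)}
    for traj in dataset.trajectories:
        if len(traj) < 2:
            continue  # singleton tracks contribute no displacements
        frames = traj.frames
        xy = traj.xy
        for n in range(1, n_max + 1):
            pos = np.searchsorted(frames, frames + n)
            valid = pos < frames.size
            valid[valid] &= frames[pos[valid]] == frames[np.flatnonzero(valid)] + n
            i = np.flatnonzero(valid)
            if i.size:
                pooled[n].append(np.linalg.norm(xy[pos[i]] - xy[i], axis=1))
    jumps = {n: (np.concatenate(v) if v else np.empty(0)) for n, v in pooled.items()}
    if jumps[1].size == 0 and all(r.size == 0 for r in jumps.values()):
        raise EmptyDistributionError("dataset contains no multi-point trajectory")
    return JumpLengthDistribution(dataset.settings.frame_interval_s, jumps)


def merge_distributions(dists: Sequence[JumpLengthDistribution]) -> JumpLengthDistribution:
    """Pool per-cell distributions (e.g. to fit several cells jointly)."""
    if not dists:
        raise EmptyDistributionError("nothing to merge")
    dt = dists[0].frame_interval_s
    if any(abs(d.frame_interval_s - dt) > 1e-12 for d in dists):
        raise ValueError("cannot merge distributions with different frame intervals")
    lags = sorted({n for d in dists for n in d.lags})
    jumps = {n: np.concatenate([d.jumps[n] for d in dists if n in d.jumps])
             for n in lags}
    return JumpLengthDistribution(dt, jumps)


_DEFAULT_BOUNDS = {
    2: ((0.0, 0.08), (0.15, 25.0)),
    3: ((0.0, 0.08), (0.08, 2.5), (2.5, 25.0)),
}


@dataclass(frozen=True)
class KineticModelSpec:
    """Configuration of the mixture fit.

    ``d_bounds_um2s`` must be ordered (nondecreasing lower and upper
    edges) so the slowest state is identifiably "bound".  ``dz_um`` is the
    detection-slab thickness; None switches the defocalization correction
    off (Z_k = 1).
    """

    n_states: int = 3
    d_bounds_um2s: Optional[tuple[tuple[float, float], ...]] = None
    localization_error_um: float = 0.045
    dz_um: Optional[float] = 0.7
    gaps_allowed: int = 1
    radius_max_um: float = 3.0
    n_radius: int = 200
    n_starts: int = 10
    starts_seed: int = 0
    min_jumps_per_lag: int = 50

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        bounds = self.d_bounds_um2s or _DEFAULT_BOUNDS[self.n_states]
        bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
        if len(bounds) != self.n_states:
            raise ValueError("need one (lo, hi) diffusivity bound per state")
        for (lo, hi) in bounds:
            if not (0 <= lo < hi):
                raise ValueError(f"invalid diffusivity bound ({lo}, {hi})")
        los = [b[0] for b in bounds]
        his = [b[1] for b in bounds]
        if los != sorted(los) or his != sorted(his):
            raise ValueError("diffusivity bounds must be ordered slow to fast")
        object.__setattr__(self, "d_bounds_um2s", bounds)
        if self.localization_error_um < 0:
            raise ValueError("localization_error_um must be >= 0")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    @property
    def radius_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.radius_max_um, self.n_radius)


@dataclass(frozen=True)
class KineticFit:
    """Fitted state fractions and diffusion coefficients.

    States are ordered slow to fast, so ``fractions[0]`` is the bound
    fraction.
    """

    fractions: tuple[float, ...]
    diffusion_um2s: tuple[float, ...]
    localization_error_um: float
    rss: float
    n_jumps: Mapping[int, int]
    bic: float
    n_states: int
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions)
        if (f < -1e-9).any() or abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must be nonnegative and sum to 1")
        d = np.asarray(self.diffusion_um2s)
        if (np.diff(d) < 0).any():
            raise ValueError("states must be ordered by increasing D")

    @property
    def bound_fraction(self) -> float:
        return float(self.fractions[0])


@dataclass(frozen=True)
class ModelComparison:
    """2- vs 3-state comparison by information criterion (lower wins).

    The criterion is the Bayesian information criterion computed from the
    Rayleigh-mixture log-likelihood of the pooled displacement samples at
    the CDF-fitted parameters: BIC = -2 logL + n_par ln(n_jumps).  BIC is
    model-selection consistent, so the generating model is preferred with
    probability -> 1 as the number of displacements grows."""

    fit2: KineticFit
    fit3: KineticFit
    delta_bic: float   # bic3 - bic2
    preferred: int     # 2 or 3

    def __post_init__(self) -> None:
        better = self.fit3 if self.fit3.bic < self.fit2.bic else self.fit2
        if self.preferred != better.n_states:
            raise ValueError("preferred model must have the lower criterion")


def _state_variances(diffusions: np.ndarray, sigma: float, lag_s: float) -> np.ndarray:
    """Per-state s² = D·Δt + σ² (quarter of the mean squared jump)."""
    return np.maximum(diffusions * lag_s + sigma * sigma, 1e-12)


def _lag_weights(fractions: np.ndarray, z_profiles: np.ndarray, lag_index: int) -> np.ndarray:
    w = fractions * z_profiles[:, lag_index - 1]
    total = w.sum()
    if total <= 0:
        return fractions
    return w / total


def jump_cdf_model(
    fractions: Sequence[float],
    diffusions: Sequence[float],
    sigma_um: float,
    lag_s: float,
    radius_grid_um: np.ndarray,
    dz_um: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
    gaps_allowed: int = 0,
) -> np.ndarray:
    """Model CDF of the jump-length mixture at one time lag.

    With ``dz_um`` set, state weights are defocalization-adjusted:
    w_k = F_k Z_k / Σ F_j Z_j, where Z_k is the detection survival of
    state k over the lag (checked at ``frame_interval_s`` cadence with
    ``gaps_allowed`` tolerated misses; default: one check at the lag).
    """
    f = np.asarray(fractions, dtype=float)
    d = np.asarray(diffusions, dtype=float)
    if (d < 0).any() or sigma_um < 0:
        raise ValueError("diffusivities and localization error must be >= 0")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    if lag_s <= 0:
        raise ValueError("lag must be positive")
    r = np.asarray(radius_grid_um, dtype=float)
    if dz_um is not None:
        z = np.array([z_correction(dk, lag_s, dz_um,
                                   frame_interval_s=frame_interval_s,
                                   gaps_allowed=gaps_allowed) for dk in d])
        w = f * z
        w = w / w.sum()
    else:
        w = f
    s2 = _state_variances(d, sigma_um, lag_s)
    cdf = np.zeros_like(r)
    for k in range(d.size):
        cdf += w[k] * (1.0 - np.exp(-r * r / (4.0 * s2[k])))
    return cdf


def _model_residuals(
    fractions: np.ndarray,
    diffusions: np.ndarray,
    spec: KineticModelSpec,
    dt: float,
    lags: list[int],
    targets: np.ndarray,
) -> np.ndarray:
    grid = spec.radius_grid
    if spec.dz_um is not None:
        zp = np.stack([
            z_correction_profile(dk, dt, spec.dz_um, max(lags),
                                 gaps_allowed=spec.gaps_allowed)
            for dk in diffusions])
    else:
        zp = np.ones((diffusions.size, max(lags)))
    out = np.empty((len(lags), grid.size))
    for i, n in enumerate(lags):
        w = _lag_weights(fractions, zp, n)
        s2 = _state_variances(diffusions, spec.localization_error_um, n * dt)
        cdf = np.zeros_like(grid)
        for k in range(diffusions.size):
            cdf += w[k] * (1.0 - np.exp(-grid * grid / (4.0 * s2[k])))
        out[i] = cdf
    return (out - targets).ravel()


def _unpack(theta: np.ndarray, n_states: int) -> tuple[np.ndarray, np.ndarray]:
    if n_states == 2:
        f = np.array([theta[0], 1.0 - theta[0]])
        d = theta[1:]
    else:
        fb, ffrac = theta[0], theta[1]
        f = np.array([fb, (1.0 - fb) * (1.0 - ffrac), (1.0 - fb) * ffrac])
        d = theta[2:]
    return f, np.asarray(d)


def _sample_loglik(
    fractions: np.ndarray,
    diffusions: np.ndarray,
    spec: KineticModelSpec,
    dist: JumpLengthDistribution,
    lags: list[int],
) -> tuple[float, int]:
    """Log-likelihood of the pooled displacements under the fitted mixture
    (2-D displacement magnitudes: per-state Rayleigh kernels)."""
    dt = dist.frame_interval_s
    if spec.dz_um is not None:
        zp = np.stack([
            z_correction_profile(dk, dt, spec.dz_um, max(lags),
                                 gaps_allowed=spec.gaps_allowed)
            for dk in diffusions])
    else:
        zp = np.ones((diffusions.size, max(lags)))
    ll = 0.0
    n_total = 0
    for n in lags:
        r = dist.jumps[n]
        w = _lag_weights(fractions, zp, n)
        s2 = _state_variances(diffusions, spec.localization_error_um, n * dt)
        pdf = np.zeros_like(r)
        for k in range(diffusions.size):
            pdf += w[k] * (r / (2.0 * s2[k])) * np.exp(-r * r / (4.0 * s2[k]))
        ll += float(np.log(np.maximum(pdf, 1e-300)).sum())
        n_total += r.size
    return ll, n_total


def fit_kinetic_model(
    dist: JumpLengthDistribution,
    spec: KineticModelSpec,
    cell_id: Optional[str] = None,
) -> KineticFit:
    """Fit the state mixture to stacked empirical jump-length CDFs.

    Deterministic given (``dist``, ``spec``): multi-start box-constrained
    least squares with Latin-hypercube starting points from
    ``spec.starts_seed``; the lowest-residual solution is kept, ties broken
    in favour of the smaller fast fraction.  Lags with fewer than
    ``spec.min_jumps_per_lag`` displacements are dropped from the residual
    stack.
    """
    counts = dist.counts()
    lags = [n for n in dist.lags if counts[n] >= spec.min_jumps_per_lag]
    dropped = [n for n in dist.lags if n not in lags]
    if dropped:
        logger.warning("dropping lag(s) %s with < %d displacements",
                       dropped, spec.min_jumps_per_lag)
    if 1 not in lags:
        raise EmptyDistributionError(
            f"lag-1 displacements are required for fitting "
            f"(have {counts.get(1, 0)}, need {spec.min_jumps_per_lag})")
    dt = dist.frame_interval_s
    grid = spec.radius_grid
    targets = np.stack([dist.empirical_cdf(n, grid) for n in lags])

    k = spec.n_states
    n_mix = k - 1
    d_lo = np.array([b[0] for b in spec.d_bounds_um2s])
    d_hi = np.array([b[1] for b in spec.d_bounds_um2s])
    lo = np.concatenate([np.zeros(n_mix), d_lo])
    hi = np.concatenate([np.ones(n_mix), d_hi])

    def objective(theta: np.ndarray) -> np.ndarray:
        f, d = _unpack(theta, k)
        return _model_residuals(f, d, spec, dt, lags, targets)

    sampler = qmc.LatinHypercube(d=lo.size, seed=spec.starts_seed)
    starts = qmc.scale(sampler.random(spec.n_starts), lo + 1e-6, hi - 1e-6)

    candidates = []
    for x0 in starts:
        try:
            res = least_squares(objective, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not np.isfinite(res.cost):
            continue
        f, d = _unpack(res.x, k)
        candidates.append((2.0 * res.cost, float(f[-1]), f, d))
    if not candidates:
        raise RuntimeError(
            "kinetic model fit failed to converge from any start "
            f"(n_starts={spec.n_starts}, n_states={k})")
    # lowest RSS wins; near-ties (within 1e-10) resolved toward lower F_fast
    candidates.sort(key=lambda c: (round(c[0], 10), c[1]))
    rss, _, f, d = candidates[0]

    order = np.argsort(d, kind="stable")
    f, d = f[order], d[order]
    f = np.clip(f, 0.0, 1.0)
    f = f / f.sum()

    ll, n_total = _sample_loglik(f, d, spec, dist, lags)
    n_par = 2 * k - 1  # (k-1) mixture weights + k diffusivities; sigma fixed
    bic = -2.0 * ll + n_par * math.log(max(n_total, 2))

    return KineticFit(
        fractions=tuple(float(x) for x in f),
        diffusion_um2s=tuple(float(x) for x in d),
        localization_error_um=spec.localization_error_um,
        rss=float(rss),
        n_jumps={n: counts[n] for n in lags},
        bic=float(bic),
        n_states=k,
        cell_id=cell_id,
    )


def compare_models(
    dist: JumpLengthDistribution,
    spec2: KineticModelSpec,
    spec3: KineticModelSpec,
) -> ModelComparison:
    """Fit 2- and 3-state models to the same distribution and prefer the
    one with the lower information criterion (see ModelComparison)."""
    if spec2.n_states != 2 or spec3.n_states != 3:
        raise ValueError("compare_models expects a 2-state and a 3-state spec")
    fit2 = fit_kinetic_model(dist, spec2)
    fit3 = fit_kinetic_model(dist, spec3)
    delta = fit3.bic - fit2.bic
    return ModelComparison(fit2, fit3, float(delta), 3 if delta < 0 else 2)


def summarize_bound_fraction(
    fits: Sequence[KineticFit],
    groups: Optional[Sequence[str]] = None,
):
    """Per-group mean, SD, SEM and n of the per-cell bound fraction.

    Group order follows first appearance (time-course order is preserved
    when labels are supplied in acquisition order).  With a single cell in
    a group SD and SEM are reported as NaN (no degrees of freedom).
    """
    import pandas as pd

    if not fits:
        raise ValueError("no fits to summarize")
    if groups is None:
        groups = ["all"] * len(fits)
    if len(groups) != len(fits):
        raise ValueError("one group label per fit is required")
    df = pd.DataFrame({
        "group": list(groups),
        "bound_fraction": [f.bound_fraction for f in fits],
    })
    order = list(dict.fromkeys(groups))
    rows = []
    for g in order:
        vals = df.loc[df["group"] == g, "bound_fraction"].to_numpy()
        if vals.size == 0:
            raise ValueError(f"empty group {g!r}")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        sem = sd / math.sqrt(vals.size) if vals.size > 1 else float("nan")
        rows.append({"group": g, "n": int(vals.size),
                     "mean_bound_fraction": float(vals.mean()),
                     "sd": sd, "sem": sem})
    return pd.DataFrame(rows)
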