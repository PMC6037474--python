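"""FRAP recovery quantification: double normalization, bleach-depth
rescaling, cross-cell aggregation, and time-to-90%-recovery (T90).

A FRAP record carries three intensity channels over time: the bleached
region of interest, a reference region (whole cell/nucleus) that reports
acquisition photobleaching, and the camera background.  Normalization is
the standard double ratio

    I(t) = (bleach(t) - bg(t)) / (ref(t) - bg(t)),  rescaled so the
    pre-bleach mean equals 1,

which cancels acquisition bleaching to first order.  Bleach-depth
normalization then maps the first post-bleach point to 0,

    I'(t) = (I(t) - I(0+)) / (1 - I(0+)),

making recovery *kinetics* comparable across conditions whose bound
fractions (hence bleach depths) differ.  T90 is the first time the mean
curve crosses 90% of its plateau, by linear interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "FrapCurve",
    "NormalizedFrap",
    "FrapSummary",
    "NormalizationError",
    "normalize_frap",
    "normalize_bleach_depth",
    "aggregate_frap",
    "compute_t90",
    "prebleach_cv",
    "read_frap_table",
    "write_frap_table",
]

PlateauMethod = Literal["last_decile", "fitted", "fixed"]


class NormalizationError(ValueError):
    """Raised when a FRAP trace cannot be normalized."""


def _validated_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if (np.diff(t) <= 0).any():
        raise ValueError("time axis must be strictly increasing")
    if (t < 0).sum() < 2:
        raise ValueError("need at least 2 pre-bleach (t < 0) points")
    return t


@dataclass(frozen=True)
class FrapCurve:
    """Raw intensity traces for one cell.  Bleach occurs at t = 0; points
    with t < 0 are pre-bleach."""

    t_s: np.ndarray
    bleach: np.ndarray
    ref: np.ndarray
    bg: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = _validated_time(self.t_s)
        object.__setattr__(self, "t_s", t)
        for name in ("bleach", "ref", "bg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} length does not match time axis")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class NormalizedFrap:
    """Normalized recovery trace; pre-bleach mean is 1 by construction."""

    t_s: np.ndarray
    intensity: np.ndarray
    bleach_depth: float
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = _validated_time(self.t_s)
        object.__setattr__(self, "t_s", t)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", i)
        pre = i[t < 0]
        if abs(pre.mean() - 1.0) > 1e-6:
            raise ValueError("pre-bleach mean must equal 1 after normalization")
        if not (0.0 <= self.bleach_depth <= 1.0):
            raise ValueError("bleach depth must lie in [0, 1]")

    @property
    def degenerate(self) -> bool:
        """True when no bleach is detectable (flat trace)."""
        return self.bleach_depth <= 0.0


@dataclass(frozen=True)
class FrapSummary:
    """Mean recovery across cells with SEM, plus plateau and T90 once
    computed (None until :func:`compute_t90` is applied)."""

    t_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_cells: int
    plateau: Optional[float] = None
    t90_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("summary needs at least one cell")
        if (np.asarray(self.sem) < 0).any():
            raise ValueError("SEM must be nonnegative")


def prebleach_cv(curve: FrapCurve) -> float:
    """Coefficient of variation of the pre-bleach bleach-ROI intensity,
    used as a stability QC (default acceptance threshold: 5%)."""
    pre = curve.bleach[curve.t_s < 0]
    return float(pre.std(ddof=0) / pre.mean())


def normalize_frap(curve: FrapCurve) -> NormalizedFrap:
    """Double normalization: background-subtracted bleach ROI over
    background-subtracted reference, scaled to a pre-bleach mean of 1."""
    denom = curve.ref - curve.bg
    if (denom <= 0).any():
        raise NormalizationError("reference channel reaches background level")
    if ((curve.bleach - curve.bg) < 0).any():
        raise NormalizationError("bleach ROI drops below background")
    ratio = (curve.bleach - curve.bg) / denom
    pre = ratio[curve.t_s < 0].mean()
    if pre <= 0:
        raise NormalizationError("non-positive pre-bleach intensity")
    intensity = ratio / pre
    post = intensity[curve.t_s >= 0]
    depth = float(np.clip(1.0 - post[0], 0.0, 1.0)) if post.size else 0.0
    return NormalizedFrap(curve.t_s, intensity, depth, dict(curve.metadata))


def normalize_bleach_depth(curve: NormalizedFrap) -> NormalizedFrap:
    """Rescale so the first post-bleach point is 0 and full recovery is 1.

    Idempotent: applying it twice is the identity (the post-bleach origin
    is a fixed point)."""
    if curve.bleach_depth <= 0:
        raise NormalizationError("bleach depth is zero; nothing to rescale")
    t = curve.t_s
    i0 = curve.intensity[t >= 0][0]
    rescaled = (curve.intensity - i0) / (1.0 - i0)
    # pre-bleach points map to 1 exactly only for an ideal trace; re-pin the
    # pre-bleach mean to 1 so the type invariant holds for noisy data
    pre = rescaled[t < 0].mean()
    rescaled = np.where(t < 0, rescaled - (pre - 1.0), rescaled)
    post0 = rescaled[t >= 0][0]
    return NormalizedFrap(t, rescaled, float(np.clip(1.0 - post0, 0.0, 1.0)),
                          dict(curve.metadata))


def aggregate_frap(
    curves: Sequence[NormalizedFrap],
    grid: Optional[np.ndarray] = None,
) -> FrapSummary:
    """Pointwise mean and SEM across cells.

    Curves are linearly interpolated onto a common grid (default: the first
    curve's time axis).  Extrapolation beyond any curve's record is refused.
    """
    if not curves:
        raise ValueError("no curves to aggregate")
    if grid is None:
        grid = curves[0].t_s
    grid = np.asarray(grid, dtype=float)
    stack = np.empty((len(curves), grid.size))
    for i, c in enumerate(curves):
        if grid[0] < c.t_s[0] - 1e-9 or grid[-1] > c.t_s[-1] + 1e-9:
            raise ValueError(
                f"curve {i} spans [{c.t_s[0]}, {c.t_s[-1]}] s but the common "
                f"grid requires extrapolation to [{grid[0]}, {grid[-1]}] s")
        stack[i] = np.interp(grid, c.t_s, c.intensity)
    mean = stack.mean(axis=0)
    sem = (stack.std(axis=0, ddof=1) / math.sqrt(len(curves))
           if len(curves) > 1 else np.zeros_like(mean))
    return FrapSummary(grid, mean, sem, len(curves))


def _fitted_plateau(t: np.ndarray, y: np.ndarray) -> float:
    params = lmfit.Parameters()
    params.add("plateau", value=float(y[-1]), min=0.0, max=2.0)
    params.add("amplitude", value=float(max(y[-1] - y[0], 1e-6)), min=0.0, max=2.0)
    params.add("rate", value=1.0 / max(t[-1] / 5.0, 1e-9), min=1e-6 / max(t[-1], 1.0),
               max=1e3)

    def resid(p):
        return p["plateau"].value - p["amplitude"].value * np.exp(-p["rate"].value * t) - y

    res = lmfit.minimize(resid, params, method="least_squares")
    return float(res.params["plateau"].value)


def compute_t90(
    summary: FrapSummary,
    plateau_method: PlateauMethod = "last_decile",
    plateau_value: Optional[float] = None,
) -> FrapSummary:
    """Time for the mean post-bleach curve to reach 90% of its plateau.

    ``plateau_method``:
      - ``"last_decile"``: plateau = mean of the final 10% of post-bleach
        points (deterministic, noise-robust default);
      - ``"fitted"``: asymptote of a single-exponential recovery fit;
      - ``"fixed"``: caller-supplied ``plateau_value``.

    The crossing is located by linear interpolation between samples.
    Returns a copy of the summary with ``plateau`` and ``t90_s`` set;
    ``t90_s`` is None when the curve never reaches the 90% level within
    the record ("unresolved within record").
    """
    post = summary.t_s >= 0
    t, y = summary.t_s[post], summary.mean[post]
    if t.size < 2:
        raise ValueError("need at least two post-bleach points")
    if plateau_method == "fixed":
        if plateau_value is None:
            raise ValueError("plateau_method='fixed' requires plateau_value")
        plateau = float(plateau_value)
    elif plateau_method == "fitted":
        plateau = _fitted_plateau(t, y)
    elif plateau_method == "last_decile":
        k = max(1, int(math.ceil(0.1 * t.size)))
        plateau = float(y[-k:].mean())
    else:
        raise ValueError(f"unknown plateau_method {plateau_method!r}")

    level = 0.9 * plateau
    above = y >= level
    if not above.any():
        return replace(summary, plateau=plateau, t90_s=None)
    j = int(np.argmax(above))
    if j == 0:
        t90 = float(t[0])
    else:
        # linear interpolation between the straddling samples
        t90 = float(t[j - 1] + (level - y[j - 1]) * (t[j] - t[j - 1]) / (y[j] - y[j - 1]))
    return replace(summary, plateau=plateau, t90_s=t90)


def read_frap_table(path: Union[str, Path],
                    metadata: Optional[Mapping[str, object]] = None) -> FrapCurve:
    """Read a delimited FRAP trace with header ``t_s,bleach,ref,bg``."""
    df = pd.read_csv(Path(path))
    missing = [c for c in ("t_s", "bleach", "ref", "bg") if c not in df.columns]
    if missing:
        raise NormalizationError(f"{path}: missing columns {missing}")
    return FrapCurve(df["t_s"].to_numpy(float), df["bleach"].to_numpy(float),
                     df["ref"].to_numpy(float), df["bg"].to_numpy(float),
                     dict(metadata or {}))


def write_frap_table(curve: FrapCurve, path: Union[str, Path]) -> None:
    pd.DataFrame({"t_s": curve.t_s, "bleach": curve.bleach,
                  "ref": curve.ref, "bg": curve.bg}).to_csv(Path(path), index=False)
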