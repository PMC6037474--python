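"""Seeded generators of spaSPT trajectories, dwell-time samples and FRAP
curves with known ground truth.

Raw single-molecule movies for these experiments are rarely shareable, so
every analysis stage in this package is validated by parameter recovery on
synthetic data generated here.  The spaSPT generator emulates the statistical structure
the fitters assume: a mixture of bound / slow / fast Brownian states,
3-D diffusion with loss of molecules that wander axially out of a finite
detection slab (defocalization), Gaussian localization error, single-frame
blinking gaps, exponential photobleaching, and gap-tolerant track linking.
Motion blur is deliberately absent: stroboscopic illumination makes frame
exposures effectively instantaneous, so positions are point-sampled at
frame times.

Identical (seed, configuration) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .trajectories import (AcquisitionSettings, Localization, Trajectory,
                           TrajectoryDataset)
from .dwell import DwellTimeSample
from .frap import FrapCurve

__all__ = [
    "StateModel",
    "ImagingModel",
    "DwellGroundTruth",
    "GroundTruthRecord",
    "simulate_spaspt",
    "simulate_spaspt_cells",
    "simulate_dwell",
    "simulate_bleach_control",
    "simulate_frap",
    "FAST_TRACKING",
    "SLOW_TRACKING",
    "DEFAULT_SPASPT_IMAGING",
    "DEFAULT_SLOW_IMAGING",
    "SPT_CONDITIONS",
    "DWELL_CONDITIONS",
]

#: Default fast-tracking acquisition (133 Hz stroboscopic imaging).
FAST_TRACKING = AcquisitionSettings(
    frame_interval_s=0.007477, exposure_s=0.001, localization_error_um=0.045,
    detection_depth_um=0.7, gaps_allowed=1, jumps_considered=4, d_max_um2s=20.0)

#: Default slow-tracking acquisition (2 Hz, long exposure).
SLOW_TRACKING = AcquisitionSettings(
    frame_interval_s=0.5, exposure_s=0.5, localization_error_um=0.03,
    detection_depth_um=0.7, gaps_allowed=1, jumps_considered=4, d_max_um2s=0.1)


@dataclass(frozen=True)
class StateModel:
    """Equilibrium mixture of diffusive states.

    ``fractions[k]`` is the occupancy of state k and ``diffusion_um2s[k]``
    its diffusion coefficient.  If ``transition_rates_per_s`` (a generator
    matrix Q with rows summing to 0) is given, molecules switch states as a
    continuous-time Markov chain whose stationary distribution must equal
    ``fractions``; otherwise each molecule keeps one state for life.
    """

    fractions: tuple[float, ...]
    diffusion_um2s: tuple[float, ...]
    transition_rates_per_s: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        d = np.asarray(self.diffusion_um2s, dtype=float)
        if f.size != d.size or f.size not in (1, 2, 3):
            raise ValueError("need matching fractions/diffusivities for 1-3 states")
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")
        if (d < 0).any():
            raise ValueError("diffusion coefficients must be nonnegative")
        if self.transition_rates_per_s is not None:
            q = np.asarray(self.transition_rates_per_s, dtype=float)
            object.__setattr__(self, "transition_rates_per_s", q)
            if q.shape != (f.size, f.size):
                raise ValueError("Q must be square with one row per state")
            off = q[~np.eye(f.size, dtype=bool)]
            if (off < 0).any() or np.abs(q.sum(axis=1)).max() > 1e-9:
                raise ValueError("Q rows must sum to 0 with nonnegative off-diagonals")
            if np.abs(f @ q).max() > 1e-6:
                raise ValueError("stationary distribution of Q must equal fractions")

    @property
    def n_states(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class ImagingModel:
    """Detection and photophysics parameters for the spaSPT generator.

    ``axial_range_um`` is the full axial extent available to molecules
    (reflecting boundaries), so the stationary axial distribution is
    uniform and the in-slab detection efficiency is
    detection_depth / axial_range.
    """

    settings: AcquisitionSettings
    bleach_rate_per_s: float = 0.0
    gap_probability: float = 0.0
    field_um: float = 10.0
    n_molecules: int = 1000
    n_frames: int = 300
    axial_range_um: float = 3.0

    def __post_init__(self) -> None:
        if self.bleach_rate_per_s < 0:
            raise ValueError("bleach_rate_per_s must be >= 0")
        if not (0.0 <= self.gap_probability < 1.0):
            raise ValueError("gap_probability must lie in [0, 1)")
        if self.n_molecules < 1 or self.n_frames < 1:
            raise ValueError("need at least one molecule and one frame")
        if self.axial_range_um < self.settings.detection_depth_um:
            raise ValueError("axial_range_um must cover the detection slab")


@dataclass(frozen=True)
class DwellGroundTruth:
    """True parameters behind a slow-tracking dwell-time sample: a mixture
    of specific (slow) and non-specific (fast) binding events, observed
    under exponential photobleaching."""

    f_specific: float
    k_off_specific_per_s: float
    k_off_nonspecific_per_s: float
    bleach_rate_per_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_specific <= 1.0):
            raise ValueError("f_specific must lie in [0, 1]")
        if not (self.k_off_nonspecific_per_s > self.k_off_specific_per_s > 0):
            raise ValueError("need k_off_nonspecific > k_off_specific > 0")
        if self.bleach_rate_per_s < 0:
            raise ValueError("bleach_rate_per_s must be >= 0")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Everything needed to regenerate and grade a synthetic dataset."""

    seed: int
    parameters: Mapping[str, object]
    state_per_molecule: Optional[np.ndarray] = None
    extras: Mapping[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "parameters": dict(self.parameters)}
        d.update({k: v for k, v in self.extras.items()})
        if self.state_per_molecule is not None:
            d["state_per_molecule"] = self.state_per_molecule.tolist()
        return d


def _reflect(z: np.ndarray, half_range: float) -> np.ndarray:
    """Fold coordinates into [-a, a] (reflecting boundaries)."""
    period = 4.0 * half_range
    q = np.mod(z + half_range, period)
    return np.where(q <= 2.0 * half_range, q - half_range, 3.0 * half_range - q)


def _simulate_positions(
    rng: np.random.Generator,
    model: StateModel,
    imaging: ImagingModel,
    n_steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """True positions of all molecules at frame times.

    Returns (pos, states): pos has shape (n_mol, n_steps + 1, 3); states is
    (n_mol,) for fixed-state runs or (n_mol, n_steps + 1) when switching.
    """
    dt = imaging.settings.frame_interval_s
    n_mol = imaging.n_molecules
    d = np.asarray(model.diffusion_um2s)
    x0 = np.empty((n_mol, 3))
    x0[:, 0] = rng.uniform(0.0, imaging.field_um, n_mol)
    x0[:, 1] = rng.uniform(0.0, imaging.field_um, n_mol)
    half = imaging.axial_range_um / 2.0
    x0[:, 2] = rng.uniform(-half, half, n_mol)

    if model.transition_rates_per_s is None:
        states = rng.choice(model.n_states, size=n_mol, p=np.asarray(model.fractions))
        sd = np.sqrt(2.0 * d[states] * dt)
        steps = rng.standard_normal((n_mol, n_steps, 3)) * sd[:, None, None]
        pos = np.concatenate([x0[:, None, :], x0[:, None, :] + np.cumsum(steps, axis=1)],
                             axis=1)
    else:
        # fine-step integration so state switches within a frame are
        # representable; 10 substeps per frame
        nsub = 10
        dt_sub = dt / nsub
        p_sub = expm(model.transition_rates_per_s * dt_sub)
        cum = np.cumsum(p_sub, axis=1)
        s = rng.choice(model.n_states, size=n_mol, p=np.asarray(model.fractions))
        states = np.empty((n_mol, n_steps + 1), dtype=np.int64)
        states[:, 0] = s
        pos = np.empty((n_mol, n_steps + 1, 3))
        pos[:, 0] = x0
        x = x0.copy()
        for step in range(n_steps):
            for _ in range(nsub):
                u = rng.random(n_mol)
                s = (u[:, None] > cum[s]).sum(axis=1)
                sd = np.sqrt(2.0 * d[s] * dt_sub)
                x = x + rng.standard_normal((n_mol, 3)) * sd[:, None]
            states[:, step + 1] = s
            pos[:, step + 1] = x
    pos[:, :, 2] = _reflect(pos[:, :, 2], half)
    return pos, states


def simulate_spaspt(
    state_model: StateModel,
    imaging: ImagingModel,
    seed: int,
    metadata: Optional[Mapping[str, object]] = None,
    keep_states: bool = False,
) -> tuple[TrajectoryDataset, GroundTruthRecord]:
    """Generate one cell's worth of fast-tracking trajectories.

    Each molecule photoactivates at a uniformly random frame, diffuses in
    3-D with its state's D, and is recorded on a frame only while it is
    unbleached, not blinking, and within ``detection_depth_um / 2`` of the
    focal plane.  Detections are linked into tracks tolerating up to
    ``gaps_allowed`` consecutive missed frames; observed x/y add Gaussian
    localization error.
    """
    settings = imaging.settings
    dt = settings.frame_interval_s
    rng = np.random.default_rng(seed)
    n_mol, n_frames = imaging.n_molecules, imaging.n_frames

    activation = rng.integers(0, n_frames, n_mol)
    if imaging.bleach_rate_per_s > 0:
        p_bleach = 1.0 - math.exp(-imaging.bleach_rate_per_s * dt)
        lifetime = rng.geometric(p_bleach, n_mol)  # frames visible, >= 1
    else:
        lifetime = np.full(n_mol, n_frames, dtype=np.int64)
    last_frame = np.minimum(activation + lifetime - 1, n_frames - 1)
    n_alive = last_frame - activation + 1
    max_alive = int(n_alive.max())

    pos, states = _simulate_positions(rng, state_model, imaging, max_alive - 1)
    noise = rng.standard_normal((n_mol, max_alive, 2)) * settings.localization_error_um
    blink = rng.random((n_mol, max_alive)) < imaging.gap_probability

    half_slab = settings.detection_depth_um / 2.0
    gaps = settings.gaps_allowed
    trajectories: list[Trajectory] = []
    for m in range(n_mol):
        na = int(n_alive[m])
        detected = (np.abs(pos[m, :na, 2]) <= half_slab) & ~blink[m, :na]
        idx = np.flatnonzero(detected)
        if idx.size == 0:
            continue
        # segment at runs of > gaps_allowed consecutive missed frames
        breaks = np.flatnonzero(np.diff(idx) > gaps + 1)
        seg_starts = np.concatenate([[0], breaks + 1])
        seg_ends = np.concatenate([breaks + 1, [idx.size]])
        for k, (a, b) in enumerate(zip(seg_starts, seg_ends)):
            tid = f"{m}.{k}"
            locs = []
            for j in idx[a:b]:
                frame = int(activation[m] + j)
                locs.append(Localization(
                    tid, frame, frame * dt,
                    float(pos[m, j, 0] + noise[m, j, 0]),
                    float(pos[m, j, 1] + noise[m, j, 1])))
            trajectories.append(Trajectory(tid, tuple(locs)))

    dataset = TrajectoryDataset(settings, tuple(trajectories), dict(metadata or {}))
    record = GroundTruthRecord(
        seed=seed,
        parameters={
            "fractions": list(state_model.fractions),
            "diffusion_um2s": list(state_model.diffusion_um2s),
            "bleach_rate_per_s": imaging.bleach_rate_per_s,
            "gap_probability": imaging.gap_probability,
            "n_molecules": n_mol,
            "n_frames": n_frames,
            "axial_range_um": imaging.axial_range_um,
            "frame_interval_s": dt,
            "localization_error_um": settings.localization_error_um,
            "detection_depth_um": settings.detection_depth_um,
        },
        state_per_molecule=(states if keep_states else None),
        extras={"n_trajectories": len(trajectories)},
    )
    return dataset, record


def simulate_spaspt_cells(
    state_model: StateModel,
    imaging: ImagingModel,
    n_cells: int,
    seed: int,
    condition: str = "synthetic",
) -> list[tuple[TrajectoryDataset, GroundTruthRecord]]:
    """Simulate ``n_cells`` independent cells of one condition, with
    per-cell seeds spawned deterministically from ``seed``."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cells) % (2**31)
    out = []
    for c in range(n_cells):
        meta = {"condition": condition, "cell_id": f"{condition}_cell{c:02d}"}
        out.append(simulate_spaspt(state_model, imaging, int(child_seeds[c]), meta))
    return out


def simulate_dwell(
    ground_truth: DwellGroundTruth,
    imaging: ImagingModel,
    n_events: int,
    seed: int,
    metadata: Optional[Mapping[str, object]] = None,
) -> tuple[DwellTimeSample, GroundTruthRecord]:
    """Draw slow-tracking dwell times directly (no spatial simulation).

    Each binding event is specific with probability ``f_specific``; its
    observed duration is min(unbinding time, photobleaching time),
    discretized down to the frame grid.  Events shorter than one frame are
    unobservable and dropped; events outliving the movie are censored at
    the movie span.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    dt = imaging.settings.frame_interval_s
    rng = np.random.default_rng(seed)
    specific = rng.random(n_events) < ground_truth.f_specific
    k = np.where(specific, ground_truth.k_off_specific_per_s,
                 ground_truth.k_off_nonspecific_per_s)
    t_unbind = rng.exponential(1.0 / k)
    if ground_truth.bleach_rate_per_s > 0:
        t_obs = np.minimum(t_unbind,
                           rng.exponential(1.0 / ground_truth.bleach_rate_per_s,
                                           n_events))
    else:
        t_obs = t_unbind
    frames = np.floor(t_obs / dt).astype(np.int64)
    horizon = imaging.n_frames - 1  # max measurable dwell in frames
    censored = frames >= horizon
    frames = np.minimum(frames, horizon)
    keep = frames >= 1
    sample = DwellTimeSample(frames[keep] * dt, censored[keep], dt,
                             dict(metadata or {}))
    record = GroundTruthRecord(
        seed=seed,
        parameters={
            "f_specific": ground_truth.f_specific,
            "k_off_specific_per_s": ground_truth.k_off_specific_per_s,
            "k_off_nonspecific_per_s": ground_truth.k_off_nonspecific_per_s,
            "bleach_rate_per_s": ground_truth.bleach_rate_per_s,
            "frame_interval_s": dt,
            "movie_frames": imaging.n_frames,
            "n_events": n_events,
        },
        extras={"n_observed": int(keep.sum()),
                "specific": specific[keep]},
    )
    return sample, record


def simulate_bleach_control(
    bleach_rate_per_s: float,
    imaging: ImagingModel,
    n_events: int,
    seed: int,
) -> tuple[DwellTimeSample, GroundTruthRecord]:
    """Histone-like control: effectively permanent binding, so observed
    track lengths reflect photobleaching alone."""
    gt = DwellGroundTruth(
        f_specific=1.0,
        k_off_specific_per_s=1e-9,  # effectively zero unbinding
        k_off_nonspecific_per_s=1e-8,
        bleach_rate_per_s=bleach_rate_per_s,
    )
    sample, record = simulate_dwell(gt, imaging, n_events, seed,
                                    metadata={"condition": "bleach_control"})
    return sample, record


def simulate_frap(
    plateau: float,
    components: Sequence[tuple[float, float]],
    noise_sd: float,
    t_grid: np.ndarray,
    seed: int,
    ref_level: float = 1000.0,
    bg_level: float = 100.0,
    acquisition_decay_rate_per_s: float = 0.0,
    metadata: Optional[Mapping[str, object]] = None,
) -> FrapCurve:
    """Reaction-dominant multi-exponential FRAP curve with synthetic
    reference and background channels.

    Pre-bleach intensity is 1; for t >= 0 the true normalized intensity is
    plateau - sum_i a_i exp(-r_i t).  ``acquisition_decay_rate_per_s``
    applies a common monotone decay to both bleach and reference channels
    (it cancels under double normalization).  Gaussian noise of standard
    deviation ``noise_sd`` (in normalized units) is added to the bleach
    channel.
    """
    t = np.asarray(t_grid, dtype=float)
    if (t < 0).sum() < 2:
        raise ValueError("t_grid must include at least 2 pre-bleach points")
    amps = np.array([a for a, _ in components], dtype=float)
    rates = np.array([r for _, r in components], dtype=float)
    if (amps < 0).any() or (rates < 0).any():
        raise ValueError("amplitudes and rates must be >= 0")
    if not (0.0 < plateau <= 1.0):
        raise ValueError("plateau must lie in (0, 1]")
    if plateau - amps.sum() < -1e-12:
        raise ValueError(
            f"post-bleach intensity would be negative: plateau {plateau} < "
            f"total amplitude {amps.sum()}")
    rng = np.random.default_rng(seed)
    post = t >= 0
    true = np.ones_like(t)
    if amps.size:
        true[post] = plateau - (amps[None, :]
                                * np.exp(-np.outer(t[post], rates))).sum(axis=1)
    else:
        true[post] = plateau
    observed = true + rng.standard_normal(t.size) * noise_sd
    decay = np.exp(-acquisition_decay_rate_per_s * (t - t[0]))
    ref = np.full_like(t, ref_level) * decay
    bg = np.full_like(t, bg_level)
    bleach = bg + (ref - bg) * observed
    return FrapCurve(t, bleach, ref, bg, dict(metadata or {}))


# --- condition presets -------------------------------------------------------
#
# Ground-truth bound fractions are the published per-condition estimates;
# fitted diffusion coefficients are not reported alongside them, so the
# slow/fast D values (and the bound/slow split of the non-bound mass) are
# fixed, field-realistic choices documented in the methods note.

def _three_state(f_bound: float, f_slow: float, d=(0.0025, 0.5, 5.0)) -> StateModel:
    return StateModel(fractions=(f_bound, f_slow, round(1.0 - f_bound - f_slow, 10)),
                      diffusion_um2s=d)


#: Fast-tracking imaging conditions used for condition-level benchmarks:
#: photobleaching tuned for spaSPT-typical track lengths (~10 frames) and a
#: molecule count yielding ~3,000 trajectories per simulated cell.
DEFAULT_SPASPT_IMAGING = ImagingModel(
    settings=FAST_TRACKING, bleach_rate_per_s=9.0, gap_probability=0.05,
    field_um=10.0, n_molecules=5000, n_frames=300, axial_range_um=3.0)

#: Slow-tracking imaging conditions (2 Hz, 600-frame movies).
DEFAULT_SLOW_IMAGING = ImagingModel(
    settings=SLOW_TRACKING, bleach_rate_per_s=0.01, gap_probability=0.0,
    field_um=10.0, n_molecules=1, n_frames=600, axial_range_um=3.0)

SPT_CONDITIONS: dict[str, StateModel] = {
    "tbp_interphase": _three_state(0.271, 0.30),
    "tbp_mitosis": _three_state(0.133, 0.30),
    "pol2_interphase": _three_state(0.293, 0.25),
    "pol2_mitosis": _three_state(0.154, 0.25),
    "halotag_only": _three_state(0.085, 0.10, d=(0.0025, 0.8, 8.0)),
}

DWELL_CONDITIONS: dict[str, DwellGroundTruth] = {
    # specific off-rates set so the corrected residence time (1/k) or
    # half-life (ln2/k) equals the per-condition estimate
    "tbp_interphase": DwellGroundTruth(0.8, 1.0 / 88.0, 10.0 / 88.0, 0.01),
    "tbp_mitosis": DwellGroundTruth(0.8, 1.0 / 118.0, 10.0 / 118.0, 0.01),
    "pol2_interphase": DwellGroundTruth(0.8, math.log(2) / 26.7,
                                        10.0 * math.log(2) / 26.7, 0.01),
    "pol2_mitosis": DwellGroundTruth(0.8, math.log(2) / 3.5,
                                     10.0 * math.log(2) / 3.5, 0.01),
}
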