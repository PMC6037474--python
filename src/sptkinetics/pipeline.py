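"""Configuration-driven orchestration: simulate → fit → summarize.

A single :class:`RunConfig` (YAML or JSON) describes one workflow —
simulating spaSPT / dwell / FRAP data, fitting them, and emitting a
machine-readable report.  Every numeric result in a report is traceable to
the config hash and the master seed recorded alongside it; one master seed
deterministically spawns independent per-stage, per-cell substreams.

Analyses can equally be driven from files: ``inputs`` lists trajectory
tables (fast or slow tracking) or FRAP tables, with ``condition_map``
assigning group labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import dwell as dwell_mod
from . import frap as frap_mod
from . import jumps as jumps_mod
from . import synthetic
from .trajectories import AcquisitionSettings, read_trajectory_table

__version__ = "0.1.0"

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "Report", "load_config", "run", "timecourse"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionBlock(_Block):
    frame_interval_s: float = 0.007477
    exposure_s: float = 0.001
    localization_error_um: float = 0.045
    detection_depth_um: float = 0.7
    gaps_allowed: int = 1
    jumps_considered: int = 4
    d_max_um2s: float = 20.0

    def to_settings(self) -> AcquisitionSettings:
        return AcquisitionSettings(**self.model_dump())


class SimulateBlock(_Block):
    """spaSPT generator settings; ``conditions`` names ground-truth presets
    (see ``synthetic.SPT_CONDITIONS``) or supplies explicit state models."""

    conditions: dict[str, Optional[dict]] = Field(default_factory=dict)
    n_cells: int = 8
    n_molecules: int = 5000
    n_frames: int = 300
    bleach_rate_per_s: float = 9.0
    gap_probability: float = 0.05
    field_um: float = 10.0
    axial_range_um: float = 3.0

    def state_model(self, name: str) -> synthetic.StateModel:
        override = self.conditions.get(name)
        if override is None:
            if name not in synthetic.SPT_CONDITIONS:
                raise KeyError(
                    f"unknown condition {name!r}: not a preset and no "
                    f"explicit state model given")
            return synthetic.SPT_CONDITIONS[name]
        return synthetic.StateModel(
            fractions=tuple(override["fractions"]),
            diffusion_um2s=tuple(override["diffusion_um2s"]))


class FitBlock(_Block):
    n_states: int = 3
    use_z_correction: bool = True
    d_bounds_um2s: Optional[list[list[float]]] = None
    radius_max_um: float = 3.0
    n_radius: int = 200
    n_starts: int = 10
    starts_seed: int = 0
    min_jumps_per_lag: int = 50

    def to_spec(self, acq: AcquisitionBlock) -> jumps_mod.KineticModelSpec:
        return jumps_mod.KineticModelSpec(
            n_states=self.n_states,
            d_bounds_um2s=(tuple(tuple(b) for b in self.d_bounds_um2s)
                           if self.d_bounds_um2s else None),
            localization_error_um=acq.localization_error_um,
            dz_um=acq.detection_depth_um if self.use_z_correction else None,
            gaps_allowed=acq.gaps_allowed,
            radius_max_um=self.radius_max_um,
            n_radius=self.n_radius,
            n_starts=self.n_starts,
            starts_seed=self.starts_seed,
            min_jumps_per_lag=self.min_jumps_per_lag,
        )


class DwellBlock(_Block):
    conditions: list[str] = Field(default_factory=lambda: ["tbp_interphase"])
    n_events: int = 5000
    movie_frames: int = 600
    frame_interval_s: float = 0.5
    bleach_rate_per_s: float = 0.01
    bound_criterion_um: float = 0.22
    min_frames: int = 2


class FrapBlock(_Block):
    plateau: float = 1.0
    components: list[list[float]] = Field(default_factory=lambda: [[0.8, 0.03]])
    noise_sd: float = 0.02
    n_cells: int = 30
    t_pre_s: float = 5.0
    t_post_s: float = 600.0
    dt_s: float = 1.0
    plateau_method: Literal["last_decile", "fitted", "fixed"] = "last_decile"
    plateau_value: Optional[float] = None
    normalize_depth: bool = False
    max_prebleach_cv: float = 0.05


class TimepointBlock(_Block):
    minutes: float
    bound_fraction: float
    slow_fraction: float = 0.25


class TimecourseBlock(_Block):
    timepoints: list[TimepointBlock]
    n_cells: int = 4


class RunConfig(_Block):
    """Validated pipeline configuration (unknown fields are rejected with
    the offending field named)."""

    mode: Literal["simulate", "jumps-fit", "dwell-fit", "frap", "timecourse",
                  "report"]
    seed: int = 0
    output_dir: Optional[str] = None
    inputs: list[str] = Field(default_factory=list)
    condition_map: dict[str, str] = Field(default_factory=dict)
    acquisition: AcquisitionBlock = Field(default_factory=AcquisitionBlock)
    simulate: Optional[SimulateBlock] = None
    fit: FitBlock = Field(default_factory=FitBlock)
    dwell: Optional[DwellBlock] = None
    frap: Optional[FrapBlock] = None
    timecourse: Optional[TimecourseBlock] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mode in ("jumps-fit", "dwell-fit", "frap") and not self.inputs \
                and self.simulate is None and self.dwell is None and self.frap is None:
            raise ValueError(f"mode {self.mode!r} needs inputs or a simulate block")
        for p in self.inputs:
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


@dataclass
class Report:
    """Machine-readable result of one pipeline run."""

    mode: str
    seed: int
    config_hash: str
    version: str = __version__
    bound_fractions: Optional[list[dict]] = None
    per_cell: Optional[list[dict]] = None
    residence: Optional[dict] = None
    frap: Optional[dict] = None
    timecourse: Optional[list[dict]] = None
    exclusions: list[dict] = dc_field(default_factory=list)
    outputs: list[str] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    h = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _simulated_cells(config: RunConfig):
    sim = config.simulate
    acq = config.acquisition.to_settings()
    for cond in sim.conditions or {}:
        model = sim.state_model(cond)
        imaging = synthetic.ImagingModel(
            settings=acq, bleach_rate_per_s=sim.bleach_rate_per_s,
            gap_probability=sim.gap_probability, field_um=sim.field_um,
            n_molecules=sim.n_molecules, n_frames=sim.n_frames,
            axial_range_um=sim.axial_range_um)
        for c in range(sim.n_cells):
            seed = _stage_seed(config.seed, f"spaspt:{cond}", c)
            meta = {"condition": cond, "cell_id": f"{cond}_cell{c:02d}"}
            yield synthetic.simulate_spaspt(model, imaging, seed, meta)


def _input_cells(config: RunConfig):
    acq = config.acquisition.to_settings()
    for p in config.inputs:
        cond = config.condition_map.get(p, "all")
        meta = {"condition": cond, "cell_id": Path(p).stem}
        yield read_trajectory_table(p, acq, meta), None


def run_jumps_fit(config: RunConfig) -> Report:
    """Per-cell jump-length mixture fits and per-condition bound-fraction
    summaries.  A failed cell-level fit is logged and excluded; exclusion
    counts appear in the report."""
    spec = config.fit.to_spec(config.acquisition)
    cells = (_simulated_cells(config) if config.simulate is not None
             else _input_cells(config))
    fits, groups, per_cell, exclusions = [], [], [], []
    for dataset, _record in cells:
        cell_id = str(dataset.metadata.get("cell_id", "?"))
        cond = str(dataset.metadata.get("condition", "all"))
        try:
            dist = jumps_mod.collect_jumps(dataset)
            fit = jumps_mod.fit_kinetic_model(dist, spec, cell_id=cell_id)
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            logger.warning("excluding cell %s: %s", cell_id, exc)
            exclusions.append({"cell_id": cell_id, "reason": str(exc)})
            continue
        fits.append(fit)
        groups.append(cond)
        per_cell.append({
            "cell_id": cell_id, "condition": cond,
            "bound_fraction": fit.bound_fraction,
            "fractions": list(fit.fractions),
            "diffusion_um2s": list(fit.diffusion_um2s),
            "rss": fit.rss, "bic": fit.bic,
            "n_jumps": {str(k): v for k, v in fit.n_jumps.items()},
        })
    if not fits:
        raise RuntimeError("every cell-level fit failed")
    summary = jumps_mod.summarize_bound_fraction(fits, groups)
    return Report(mode=config.mode, seed=config.seed,
                  config_hash=config.config_hash(),
                  bound_fractions=summary.to_dict(orient="records"),
                  per_cell=per_cell, exclusions=exclusions)


def run_dwell_fit(config: RunConfig) -> Report:
    """Residence-time analysis per condition with a shared histone-like
    photobleaching control."""
    dw = config.dwell or DwellBlock()
    settings = AcquisitionSettings(
        frame_interval_s=dw.frame_interval_s, exposure_s=dw.frame_interval_s,
        localization_error_um=0.03, detection_depth_um=0.7)
    imaging = synthetic.ImagingModel(settings=settings, n_molecules=1,
                                     n_frames=dw.movie_frames)
    ctrl_sample, _ = synthetic.simulate_bleach_control(
        dw.bleach_rate_per_s, imaging, dw.n_events,
        _stage_seed(config.seed, "dwell:control"))
    control_fit = dwell_mod.fit_biexp(dwell_mod.survival(ctrl_sample))
    results = {}
    for cond in dw.conditions:
        gt = synthetic.DWELL_CONDITIONS[cond]
        sample, _ = synthetic.simulate_dwell(
            gt, imaging, dw.n_events, _stage_seed(config.seed, f"dwell:{cond}"))
        fit = dwell_mod.fit_biexp(dwell_mod.survival(sample))
        res = dwell_mod.correct_and_summarize(fit, control_fit)
        results[cond] = res.to_dict()
        results[cond]["n_events"] = len(sample)
    results["control"] = {"k_bleach_per_s": control_fit.k_slow_per_s,
                          "n_events": len(ctrl_sample)}
    return Report(mode=config.mode, seed=config.seed,
                  config_hash=config.config_hash(), residence=results)


def run_frap(config: RunConfig) -> Report:
    """Normalize, QC-filter, aggregate and T90-summarize FRAP curves."""
    fr = config.frap or FrapBlock()
    if config.inputs:
        curves_raw = [frap_mod.read_frap_table(p) for p in config.inputs]
    else:
        t = np.arange(-fr.t_pre_s, fr.t_post_s + fr.dt_s / 2, fr.dt_s)
        comps = [(a, r) for a, r in fr.components]
        curves_raw = [
            synthetic.simulate_frap(fr.plateau, comps, fr.noise_sd, t,
                                    _stage_seed(config.seed, "frap", c),
                                    metadata={"cell_id": f"cell{c:02d}"})
            for c in range(fr.n_cells)]
    normalized, exclusions = [], []
    for i, raw in enumerate(curves_raw):
        cv = frap_mod.prebleach_cv(raw)
        if cv > fr.max_prebleach_cv:
            logger.warning("rejecting FRAP curve %d: pre-bleach CV %.3f", i, cv)
            exclusions.append({"curve": i,
                               "reason": f"pre-bleach CV {cv:.3f} exceeds "
                                         f"{fr.max_prebleach_cv}"})
            continue
        nf = frap_mod.normalize_frap(raw)
        if fr.normalize_depth:
            nf = frap_mod.normalize_bleach_depth(nf)
        normalized.append(nf)
    if not normalized:
        raise RuntimeError("no FRAP curve passed QC")
    summary = frap_mod.aggregate_frap(normalized)
    summary = frap_mod.compute_t90(summary, fr.plateau_method, fr.plateau_value)
    mean_depth = float(np.mean([c.bleach_depth for c in normalized]))
    return Report(mode=config.mode, seed=config.seed,
                  config_hash=config.config_hash(),
                  frap={"n_cells": summary.n_cells,
                        "plateau": summary.plateau,
                        "t90_s": summary.t90_s,
                        "mean_bleach_depth": mean_depth,
                        "t_s": summary.t_s.tolist(),
                        "mean": summary.mean.tolist(),
                        "sem": summary.sem.tolist()},
                  exclusions=exclusions)


def timecourse(config: RunConfig) -> Report:
    """Bound fraction vs time after mitotic release: per-timepoint
    simulate-and-fit summaries, ordered by minutes post release."""
    tc = config.timecourse
    if tc is None:
        raise ValueError("timecourse mode requires a timecourse block")
    sim = config.simulate or SimulateBlock()
    acq = config.acquisition.to_settings()
    spec = config.fit.to_spec(config.acquisition)
    rows = []
    for tp in sorted(tc.timepoints, key=lambda t: t.minutes):
        model = synthetic.StateModel(
            fractions=(tp.bound_fraction, tp.slow_fraction,
                       round(1.0 - tp.bound_fraction - tp.slow_fraction, 12)),
            diffusion_um2s=(0.0025, 0.5, 5.0))
        imaging = synthetic.ImagingModel(
            settings=acq, bleach_rate_per_s=sim.bleach_rate_per_s,
            gap_probability=sim.gap_probability, field_um=sim.field_um,
            n_molecules=sim.n_molecules, n_frames=sim.n_frames,
            axial_range_um=sim.axial_range_um)
        fits = []
        for c in range(tc.n_cells):
            seed = _stage_seed(config.seed, f"timecourse:{tp.minutes}", c)
            ds, _ = synthetic.simulate_spaspt(model, imaging, seed)
            fits.append(jumps_mod.fit_kinetic_model(
                jumps_mod.collect_jumps(ds), spec))
        vals = np.array([f.bound_fraction for f in fits])
        sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append({"minutes": tp.minutes, "n": len(vals),
                     "mean_bound_fraction": float(vals.mean()), "sem": sem,
                     "true_bound_fraction": tp.bound_fraction})
    return Report(mode=config.mode, seed=config.seed,
                  config_hash=config.config_hash(), timecourse=rows)


def run_simulate(config: RunConfig) -> Report:
    """Generate trajectory tables plus ground-truth JSON sidecars."""
    from .trajectories import write_trajectory_table

    if config.simulate is None:
        raise ValueError("simulate mode requires a simulate block")
    outdir = Path(config.output_dir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for dataset, record in _simulated_cells(config):
        stem = str(dataset.metadata["cell_id"])
        table = outdir / f"{stem}.csv"
        write_trajectory_table(dataset, table)
        sidecar = outdir / f"{stem}.groundtruth.json"
        sidecar.write_text(json.dumps(record.to_dict(), indent=2))
        outputs += [str(table), str(sidecar)]
    return Report(mode=config.mode, seed=config.seed,
                  config_hash=config.config_hash(), outputs=outputs)


_RUNNERS = {
    "simulate": run_simulate,
    "jumps-fit": run_jumps_fit,
    "dwell-fit": run_dwell_fit,
    "frap": run_frap,
    "timecourse": timecourse,
}


def run(config: RunConfig) -> Report:
    """Execute the workflow named by ``config.mode`` and return (and, when
    ``output_dir`` is set, write) its report."""
    if config.mode == "report":
        # combined report: every stage whose block is present
        combined = Report(mode="report", seed=config.seed,
                          config_hash=config.config_hash())
        if config.simulate is not None:
            sub = run_jumps_fit(config)
            combined.bound_fractions = sub.bound_fractions
            combined.per_cell = sub.per_cell
            combined.exclusions += sub.exclusions
        if config.dwell is not None:
            combined.residence = run_dwell_fit(config).residence
        if config.frap is not None:
            sub = run_frap(config)
            combined.frap = sub.frap
            combined.exclusions += sub.exclusions
        if config.timecourse is not None:
            combined.timecourse = timecourse(config).timecourse
        report = combined
    else:
        report = _RUNNERS[config.mode](config)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json())
        if report.bound_fractions:
            import pandas as pd
            pd.DataFrame(report.bound_fractions).to_csv(
                outdir / "bound_fractions.csv", index=False)
        if report.frap:
            import pandas as pd
            pd.DataFrame({"t_s": report.frap["t_s"],
                          "mean": report.frap["mean"],
                          "sem": report.frap["sem"]}).to_csv(
                outdir / "frap_mean_sem.csv", index=False)
    return report
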