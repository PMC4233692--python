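"""Canned measurement protocols for the published benchmark scenarios.

Each function runs the full simulate → image → track → analyse chain (or the
ground-truth shortcut where the published quantity is defined on true
states) at the study conditions and returns the measured quantities.  These
are the protocols the acceptance tests and the reproduction script drive;
run sizes are chosen so each measurement completes in tens of seconds on
one CPU while keeping enough tracks for stable fits (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import engine, presets, tracking
from .config import SimulationConfig
from .interactions import AITTableCache


def _flat_beam(cfg: SimulationConfig) -> SimulationConfig:
    return dataclasses.replace(
        cfg, illumination=dataclasses.replace(cfg.illumination,
                                              beam_fwhm_um=200.0))


def _tracks(result, d_expect: float, min_len: int = tracking.MIN_TRACK_LEN):
    cfg = result.config
    gate = tracking.linking_gate_px(d_expect, 1.0 / cfg.fps,
                                    cfg.optics.pixel_size_um)
    return tracking.track_movie(result.stack.recorded, cfg.optics,
                                max_disp_px=gate,
                                noise_rms=cfg.camera.noise_rms,
                                min_len=min_len)


@dataclass
class MobilityMeasurement:
    d_mean_um2_s: float           # mean of per-track diffusion coefficients
    d_per_track: np.ndarray
    off_rate_s: float
    n_tracks: int


def measure_membrane_mobility(seeds: Sequence[int], d_um2_s: float = 0.3,
                              duration_s: float = 10.0,
                              flat_beam: bool = True,
                              barrier_permeability: Optional[float] = None,
                              raft_ratio: Optional[float] = None,
                              ) -> MobilityMeasurement:
    """Tracked mobility of free membrane molecules under TIRF.

    ``barrier_permeability`` switches on the 1 × 1 µm² fence grid;
    ``raft_ratio`` the 1 × 1 µm² raft pattern (recorded from uniform
    seeding, so the published crowding transient is part of the record).
    """
    all_d = []
    rates = []
    n_tracks = 0
    for seed in seeds:
        cfg = presets.scenario_preset("S4", duration_s=duration_s,
                                      seed=int(seed), truth_every=10)
        cfg = dataclasses.replace(
            cfg, classes=[dataclasses.replace(cfg.classes[0],
                                              d_um2_s=d_um2_s)])
        if flat_beam:
            cfg = _flat_beam(cfg)
        if barrier_permeability is not None:
            cfg = dataclasses.replace(cfg, membrane_features=dataclasses.replace(
                cfg.membrane_features, barrier_pitch_um=1.0,
                barrier_permeability=barrier_permeability))
        if raft_ratio is not None:
            cfg = dataclasses.replace(cfg, membrane_features=dataclasses.replace(
                cfg.membrane_features, raft_size_um=1.0, raft_gap_um=1.0,
                raft_mobility_ratio=raft_ratio))
        res = engine.run(cfg)
        tracks = _tracks(res, d_expect=d_um2_s)
        n_tracks += len(tracks)
        if tracks:
            m = tracking.msd_analysis(tracks, 1.0 / cfg.fps,
                                      cfg.optics.pixel_size_um)
            all_d.append(m.d_per_track[~np.isnan(m.d_per_track)])
            if len(tracks) > 10:
                rates.append(tracking.off_rate(
                    tracks, 1.0 / cfg.fps).rate_s)
    d = np.concatenate(all_d) if all_d else np.array([np.nan])
    return MobilityMeasurement(
        d_mean_um2_s=float(np.nanmean(d)), d_per_track=d,
        off_rate_s=float(np.mean(rates)) if rates else float("nan"),
        n_tracks=n_tracks)


def measure_raft_occupancy(seed: int, raft_ratio: float = 0.1,
                           duration_s: float = 15.0) -> float:
    """Ground-truth fraction of coverslip-face molecules inside raft patches
    at the end of a record started from uniform seeding."""
    from .motion import in_raft

    cfg = presets.scenario_preset("S6", duration_s=duration_s, seed=int(seed),
                                  render=False, truth_every=10)
    cfg = dataclasses.replace(cfg, membrane_features=dataclasses.replace(
        cfg.membrane_features, raft_mobility_ratio=raft_ratio))
    res = engine.run(cfg)
    mem = res.truth.class_mask("membrane")
    on0 = res.truth.face[-1][mem] == 0
    pos = res.truth.pos_um[-1][mem][on0]
    return float(in_raft(pos[:, 0], pos[:, 1],
                         cfg.membrane_features).mean())


def measure_ph_domain_binding(seeds: Sequence[int], duration_s: float = 60.0,
                              t_min: float = 30.0,
                              r_bind: float = 1e6) -> float:
    """Steady-state fraction of cytoplasmic PH-domain-like molecules bound
    to membrane targets (ground truth, time-averaged after equilibration)."""
    vals = []
    cache = AITTableCache()
    for seed in seeds:
        cfg = presets.scenario_preset("S7", duration_s=duration_s,
                                      seed=int(seed), render=False,
                                      truth_every=10)
        cfg.classes[0].bindings[0].r_bind = r_bind
        res = engine.Simulation(cfg, ait_cache=cache).run()
        vals.append(res.truth.bound_fraction("cytoplasmic", t_min=t_min))
    return float(np.mean(vals))


def measure_anchor_binding(seeds: Sequence[int], r_bind: float = 1e5,
                           duration_s: float = 30.0,
                           t_min: float = 10.0) -> float:
    """Steady-state fraction of mobile membrane molecules bound to immobile
    anchors (ground truth, time-averaged after equilibration)."""
    vals = []
    cache = AITTableCache()
    for seed in seeds:
        cfg = presets.scenario_preset("S8", duration_s=duration_s,
                                      seed=int(seed), render=False,
                                      truth_every=10)
        cfg.classes[0].bindings[0].r_bind = r_bind
        res = engine.Simulation(cfg, ait_cache=cache).run()
        vals.append(res.truth.bound_fraction("membrane", t_min=t_min))
    return float(np.mean(vals))


def run_gated_experiment(seeds: Sequence[int] = (1,),
                         duty_ratios=(0.1, 0.2, 0.5, 1.0),
                         durations_s=(70.0, 60.0, 60.0, 60.0)
                         ) -> tracking.GatedResult:
    """The duty-ratio titration separating photobleaching from dissociation
    in the PH-domain scenario (time-lapse TIRF at 10 fps)."""
    base = presets.scenario_preset("S7")
    return tracking.gated_dissociation_experiment(
        base, duty_ratios=duty_ratios, durations_s=durations_s, seeds=seeds)


def measure_bound_time_distribution(seeds: Sequence[int],
                                    duration_s: float = 10.0
                                    ) -> tracking.BoundTimeResult:
    """Immobilisation-episode durations in the anchor scenario, pooled over
    runs, classified by rolling MSD within tracked trajectories."""
    all_tracks = []
    cache = AITTableCache()
    for seed in seeds:
        cfg = presets.scenario_preset("S8", duration_s=duration_s,
                                      seed=int(seed), truth_every=10)
        res = engine.Simulation(cfg, ait_cache=cache).run()
        all_tracks.extend(_tracks(res, d_expect=0.3))
    return tracking.bound_time_analysis(
        all_tracks, 1.0 / 33.0, 0.1)


def measure_intensity_cv(seed: int, beam_fwhm_um: float,
                         duration_s: float = 6.0) -> float:
    """Coefficient of variation of tracked per-spot intensities for a given
    illuminating beam width (the uneven-illumination artifact)."""
    cfg = presets.scenario_preset("S4", duration_s=duration_s, seed=int(seed))
    cfg = dataclasses.replace(cfg, illumination=dataclasses.replace(
        cfg.illumination, beam_fwhm_um=beam_fwhm_um))
    res = engine.run(cfg)
    tracks = _tracks(res, d_expect=0.3)
    _, cv = tracking.intensity_distribution(tracks)
    return cv
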