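"""Simulation engine: the per-substep iteration loop.

Each model substep advances the population in a fixed order — move, binding
trials, dissociation trials, then (if the illumination gate is open)
emission/rendering followed by photobleaching — and ``substeps_per_frame``
substeps are summed into one camera frame.  Ground truth (true positions,
binding state, active tags) is recorded alongside the rendered stack so
analyses can be validated against what actually happened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import interactions, motion
from .config import (FACES, FACE_TANGENTS, ConfigurationError, RngStreams,
                     SimulationConfig, abundance_to_count)
from .illumination import IlluminationField
from .imaging import (FrameStack, bleach_step, emitted_photons, finalize_frame,
                      psf_fwhm_um, splat_photons)

logger = logging.getLogger(__name__)

MAX_TAGS = 8


# ---------------------------------------------------------------------------
# population state (structure-of-arrays)

class Population:
    """Mutable state of all molecules in the cell."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        geom = config.geometry
        counts = [abundance_to_count(c, geom) for c in config.classes]
        n = sum(counts)
        self.n = n
        self.class_id = np.repeat(np.arange(len(counts)), counts).astype(np.int16)
        self.pos = np.zeros((n, 3))
        self.face = np.full(n, -1, dtype=np.int8)
        self.partner = np.full(n, -1, dtype=np.int64)
        self.tags = np.zeros((n, MAX_TAGS), dtype=bool)
        self.class_d = np.array([c.d_um2_s for c in config.classes])
        self.class_compartment = [c.compartment for c in config.classes]

        face_areas = np.array([geom.face_area_um2(f) for f in range(6)])
        face_p = face_areas / face_areas.sum()
        start = 0
        for ci, (spec, cnt) in enumerate(zip(config.classes, counts)):
            sl = slice(start, start + cnt)
            if spec.compartment == "membrane":
                faces = rng.choice(6, size=cnt, p=face_p)
                self.face[sl] = faces
                u = rng.random(cnt)
                v = rng.random(cnt)
                for k in range(cnt):
                    f = faces[k]
                    normal, side = FACES[f]
                    ta, tb = FACE_TANGENTS[f]
                    p = np.zeros(3)
                    p[normal] = geom.edges[normal] if side else 0.0
                    p[ta] = u[k] * geom.edges[ta]
                    p[tb] = v[k] * geom.edges[tb]
                    self.pos[start + k] = p
            else:  # cytoplasm and static objects fill the volume uniformly
                self.pos[sl] = rng.random((cnt, 3)) * geom.edges
            self.tags[sl, :spec.n_tags] = True
            start += cnt

    def indices_of_class(self, ci: int) -> np.ndarray:
        return np.nonzero(self.class_id == ci)[0]

    @property
    def bound(self) -> np.ndarray:
        return self.partner >= 0

    @property
    def active_tag_count(self) -> np.ndarray:
        return self.tags.sum(axis=1).astype(np.uint8)


# ---------------------------------------------------------------------------
# reactions

@dataclass
class _Rule:
    """One resolved reaction channel between two classes."""

    index: int
    ci_a: int
    ci_b: int
    r_bind: float
    r_diss: float
    id_nm: float
    ndim: int
    d_sum: float
    same_class: bool
    mixed: bool                  # cytoplasm <-> membrane/static geometry
    table: interactions.AITTable = None
    cutoff_um: float = 0.0
    # bound pairs of this rule, parallel lists of molecule indices
    pairs_i: list = field(default_factory=list)
    pairs_j: list = field(default_factory=list)

    def refresh_cutoff(self) -> None:
        self.cutoff_um = self.table.cutoff_nm(self.r_bind) * 1e-3


def _resolve_rules(config: SimulationConfig) -> list[_Rule]:
    rules: list[_Rule] = []
    names = [c.name for c in config.classes]
    for ia, spec in enumerate(config.classes):
        for b in spec.bindings:
            ib = names.index(b.partner)
            other = config.classes[ib]
            comp_a, comp_b = spec.compartment, other.compartment
            membrane_pair = (comp_a != "cytoplasm" and comp_b != "cytoplasm")
            ndim = 2 if membrane_pair else 3
            if membrane_pair:
                d_sum = spec.d_um2_s + other.d_um2_s
            else:
                # mixed-compartment reaction: relative motion is dominated by
                # the cytoplasmic molecule, separation measured in 3D
                d_sum = spec.d_um2_s if comp_a == "cytoplasm" else other.d_um2_s
            rules.append(_Rule(index=len(rules), ci_a=ia, ci_b=ib,
                               r_bind=b.r_bind, r_diss=b.r_diss,
                               id_nm=b.id_nm, ndim=ndim, d_sum=d_sum,
                               same_class=(ia == ib),
                               mixed=not membrane_pair))
    return rules


# ---------------------------------------------------------------------------
# results

@dataclass
class GroundTruth:
    """Per-substep (optionally thinned) true state of every molecule."""

    times_s: np.ndarray                  # (R,)
    pos_um: np.ndarray                   # (R, N, 3) float32
    face: np.ndarray                     # (R, N) int8
    partner: np.ndarray                  # (R, N) int32
    tags_active: np.ndarray              # (R, N) uint8
    class_id: np.ndarray                 # (N,)
    class_names: list[str]

    def class_mask(self, name: str) -> np.ndarray:
        ci = self.class_names.index(name)
        return self.class_id == ci

    def bound_fraction(self, name: str, t_min: float = 0.0,
                       t_max: Optional[float] = None) -> float:
        """Time-averaged fraction of molecules of a class that are bound."""
        m = self.class_mask(name)
        sel = self.times_s >= t_min
        if t_max is not None:
            sel &= self.times_s <= t_max
        if not sel.any():
            raise ValueError("no ground-truth records in the requested window")
        return float((self.partner[sel][:, m] >= 0).mean())

    def bound_fraction_series(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.class_mask(name)
        return self.times_s, (self.partner[:, m] >= 0).mean(axis=1)

    def to_dataframe(self, every: int = 1) -> pd.DataFrame:
        """Long-form table: one row per molecule per recorded substep."""
        r_idx = np.arange(0, len(self.times_s), every)
        n = self.pos_um.shape[1]
        rows = {
            "time_s": np.repeat(self.times_s[r_idx], n),
            "molecule_id": np.tile(np.arange(n), r_idx.size),
            "class": np.tile(np.asarray(self.class_names, dtype=object)[
                self.class_id], r_idx.size),
            "x_um": self.pos_um[r_idx, :, 0].ravel(),
            "y_um": self.pos_um[r_idx, :, 1].ravel(),
            "z_um": self.pos_um[r_idx, :, 2].ravel(),
            "face": self.face[r_idx].ravel(),
            "bound_partner": self.partner[r_idx].ravel(),
            "tags_active": self.tags_active[r_idx].ravel(),
        }
        return pd.DataFrame(rows)


@dataclass
class RunResult:
    config: SimulationConfig
    stack: Optional[FrameStack]
    truth: GroundTruth
    events: pd.DataFrame
    population: Population
    photons_emitted: int = 0
    photons_dropped: int = 0
    stacks: list = field(default_factory=list)      # one FrameStack per colour
    colours_nm: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return 0 if self.stack is None else len(self.stack)


# ---------------------------------------------------------------------------
# the simulation proper

class Simulation:
    def __init__(self, config: SimulationConfig,
                 ait_cache: Optional[interactions.AITTableCache] = None):
        self.config = config
        dt = config.dt_s
        if abs(dt * config.substeps_per_frame * config.fps - 1.0) > 1e-9:
            raise ConfigurationError("dt × substeps_per_frame must equal 1/fps")
        self.rng = RngStreams.from_seed(config.seed)
        self.population = Population(config, self.rng.placement)
        self.rules = _resolve_rules(config)
        self.ait_cache = ait_cache or interactions.AITTableCache()
        for rule in self.rules:
            rule.table = self.ait_cache.get(rule.d_sum, rule.id_nm, dt,
                                            rule.ndim)
            rule.refresh_cutoff()
        self.field = IlluminationField(
            config.illumination, centre_um=config.field_centre_um,
            z_focus_um=config.optics.z_focus_um)
        self._pending_rate_changes = sorted(config.rate_changes,
                                            key=lambda r: r.time_s)
        #: distinct tag colours among fluorescent classes -> one channel each
        self.colours_nm = sorted({c.tag_colour_nm for c in config.classes
                                  if c.n_tags > 0}) or [532.0]
        class_colour = np.array([c.tag_colour_nm for c in config.classes])
        self._colour_channel = np.searchsorted(np.asarray(self.colours_nm),
                                               class_colour)

    # -- substep pieces ----------------------------------------------------

    def _move_all(self) -> None:
        pop = self.population
        cfg = self.config
        dt = cfg.dt_s
        d_eff = pop.class_d[pop.class_id].copy()
        comp = np.array([{"cytoplasm": 0, "membrane": 1, "static": 2}[c]
                         for c in pop.class_compartment])[pop.class_id]

        is_bound = pop.bound
        leader = np.zeros(pop.n, dtype=bool)
        follower_of = {}
        for rule in self.rules:
            for i, j in zip(rule.pairs_i, rule.pairs_j):
                di, dj = pop.class_d[pop.class_id[i]], pop.class_d[pop.class_id[j]]
                ldr, flw = i, j
                if comp[j] != 0 and comp[i] == 0:      # membrane partner leads
                    ldr, flw = j, i
                if rule.mixed:
                    d_pair = pop.class_d[pop.class_id[ldr]]  # membrane D rules
                else:
                    d_pair = motion.pair_mobility(di, dj)
                leader[ldr] = True
                d_eff[ldr] = d_pair
                follower_of[ldr] = flw

        movable = ~is_bound | leader
        mem = movable & (comp == 1)
        cyt = movable & (comp == 0) & (d_eff > 0)
        mem_idx = np.nonzero(mem)[0]
        if mem_idx.size:
            new_pos, new_face = motion.step_membrane(
                pop.pos[mem_idx], pop.face[mem_idx], d_eff[mem_idx], dt,
                cfg.geometry, self.rng.motion, cfg.membrane_features)
            pop.pos[mem_idx] = new_pos
            pop.face[mem_idx] = new_face
        cyt_idx = np.nonzero(cyt)[0]
        if cyt_idx.size:
            pop.pos[cyt_idx] = motion.step_cytoplasm(
                pop.pos[cyt_idx], d_eff[cyt_idx], dt, cfg.geometry,
                self.rng.motion)
        # bound partners share coordinates exactly
        for ldr, flw in follower_of.items():
            pop.pos[flw] = pop.pos[ldr]
            if pop.face[flw] >= 0:
                pop.face[flw] = pop.face[ldr]

    def _attempt_bindings(self, t: float, events: list) -> None:
        pop = self.population
        rng = self.rng.interactions
        free = ~pop.bound
        for rule in self.rules:
            if rule.r_bind <= 0 or rule.cutoff_um <= 0:
                continue
            a_idx = np.nonzero(free & (pop.class_id == rule.ci_a))[0]
            if rule.same_class:
                if a_idx.size < 2:
                    continue
                ii, jj, dist = interactions.candidate_pairs(
                    pop.pos[a_idx], pop.pos[a_idx], rule.cutoff_um,
                    exclude_self=True)
                b_idx = a_idx
            else:
                b_idx = np.nonzero(free & (pop.class_id == rule.ci_b))[0]
                if a_idx.size == 0 or b_idx.size == 0:
                    continue
                ii, jj, dist = interactions.candidate_pairs(
                    pop.pos[a_idx], pop.pos[b_idx], rule.cutoff_um)
            if ii.size == 0:
                continue
            p = np.clip(rule.table.ait_at(dist) * rule.r_bind, 0.0, 1.0)
            wins = rng.random(ii.size) < p
            if not wins.any():
                continue
            # conflict resolution among winners only: closest pair first
            w = np.nonzero(wins)[0]
            w = w[np.argsort(dist[w], kind="stable")]
            taken_a = np.zeros(pop.n, dtype=bool)
            for k in w:
                i, j = int(a_idx[ii[k]]), int(b_idx[jj[k]])
                if taken_a[i] or taken_a[j] or pop.partner[i] >= 0 \
                        or pop.partner[j] >= 0 or i == j:
                    continue
                taken_a[i] = taken_a[j] = True
                self._bind(rule, i, j)
                events.append((t, "bind", i, j, float(dist[k]) * 1e3))

    def _bind(self, rule: _Rule, i: int, j: int) -> None:
        pop = self.population
        pop.partner[i] = j
        pop.partner[j] = i
        comp_i = pop.class_compartment[pop.class_id[i]]
        comp_j = pop.class_compartment[pop.class_id[j]]
        di = pop.class_d[pop.class_id[i]]
        dj = pop.class_d[pop.class_id[j]]
        if comp_i == "cytoplasm" and comp_j != "cytoplasm":
            pop.pos[i] = pop.pos[j]
        elif comp_j == "cytoplasm" and comp_i != "cytoplasm":
            pop.pos[j] = pop.pos[i]
        elif di == dj and pop.face[i] >= 0 and pop.face[i] == pop.face[j]:
            # symmetric pair (e.g. dimerisation): meet at the midpoint
            mid = 0.5 * (pop.pos[i] + pop.pos[j])
            pop.pos[i] = pop.pos[j] = mid
        elif dj <= di:
            # co-locate at the less mobile partner so immobile anchors
            # never drift through repeated bind/release cycles
            pop.pos[i] = pop.pos[j]
            if pop.face[i] >= 0 and pop.face[j] >= 0:
                pop.face[i] = pop.face[j]
        else:
            pop.pos[j] = pop.pos[i]
            if pop.face[i] >= 0 and pop.face[j] >= 0:
                pop.face[j] = pop.face[i]
        rule.pairs_i.append(i)
        rule.pairs_j.append(j)

    def _attempt_dissociations(self, t: float, events: list) -> None:
        pop = self.population
        rng = self.rng.interactions
        dt = self.config.dt_s
        for rule in self.rules:
            if not rule.pairs_i or rule.r_diss <= 0:
                continue
            pair_idx = np.arange(len(rule.pairs_i))
            hits = interactions.attempt_dissociations(pair_idx, rule.r_diss,
                                                      dt, rng)
            if hits.size == 0:
                continue
            for k in sorted(hits.tolist(), reverse=True):
                i, j = rule.pairs_i.pop(k), rule.pairs_j.pop(k)
                pop.partner[i] = -1
                pop.partner[j] = -1
                events.append((t, "dissociate", i, j, 0.0))

    def _apply_rate_changes(self, t: float) -> None:
        while self._pending_rate_changes and \
                self._pending_rate_changes[0].time_s <= t:
            ch = self._pending_rate_changes.pop(0)
            names = [c.name for c in self.config.classes]
            for rule in self.rules:
                if (names[rule.ci_a] == ch.class_name
                        and names[rule.ci_b] == ch.partner):
                    if ch.r_bind is not None:
                        rule.r_bind = ch.r_bind
                        rule.refresh_cutoff()
                    if ch.r_diss is not None:
                        rule.r_diss = ch.r_diss

    def _render_substep(self, photon_images: list[np.ndarray], t: float,
                        events: list) -> tuple[int, int]:
        pop = self.population
        cfg = self.config
        cam = cfg.camera
        rng = self.rng.imaging
        dt = cfg.dt_s
        n_tags = pop.active_tag_count
        idx = np.nonzero(n_tags > 0)[0]
        emitted = dropped = 0
        if idx.size:
            inten = self.field.intensity(pop.pos[idx])
            mean = inten * cam.photons_per_s * dt * n_tags[idx]
            if cfg.illumination.mode == "confocal":
                dz = pop.pos[idx, 2] - cfg.optics.z_focus_um
                mean = mean / (1.0 + cfg.optics.gamma_pinhole_per_um2 * dz * dz)
            n_ph = emitted_photons(mean, cam, rng)
            emitted = int(n_ph.sum())
            fwhm = psf_fwhm_um(pop.pos[idx, 2], cfg.optics)
            chan = self._colour_channel[pop.class_id[idx]]
            for ch, image in enumerate(photon_images):
                sel = chan == ch
                if not sel.any():
                    continue
                dropped += splat_photons(image, pop.pos[idx[sel], 0],
                                         pop.pos[idx[sel], 1], n_ph[sel],
                                         fwhm[sel], cfg.optics.pixel_size_um,
                                         rng)
            # photobleaching after emission: a tag still emits during the
            # substep in which it bleaches
            before = pop.tags[idx].sum(axis=1)
            pop.tags[idx] = bleach_step(pop.tags[idx], inten, cam.r_bleach,
                                        dt, rng)
            after = pop.tags[idx].sum(axis=1)
            for m in np.nonzero(after < before)[0]:
                events.append((t, "bleach", int(idx[m]), -1, 0.0))
        return emitted, dropped

    # -- main loop ---------------------------------------------------------

    def run(self) -> RunResult:
        cfg = self.config
        pop = self.population
        n_frames = cfg.n_frames
        spf = cfg.substeps_per_frame
        dt = cfg.dt_s
        total_sub = n_frames * spf
        h, w = cfg.frame_shape

        n_rec = len(range(0, total_sub, cfg.truth_every))
        truth_t = np.zeros(n_rec)
        truth_pos = np.zeros((n_rec, pop.n, 3), dtype=np.float32)
        truth_face = np.zeros((n_rec, pop.n), dtype=np.int8)
        truth_partner = np.zeros((n_rec, pop.n), dtype=np.int32)
        truth_tags = np.zeros((n_rec, pop.n), dtype=np.uint8)

        n_ch = len(self.colours_nm)
        frames_ch = [np.zeros((n_frames, h, w), dtype=np.uint16)
                     for _ in range(n_ch)] if cfg.render else None
        frame_times = np.zeros(n_frames)
        frame_lit = np.zeros(n_frames, dtype=bool)
        events: list = []
        emitted_total = dropped_total = 0
        rec = 0
        sub_global = 0

        for f in range(n_frames):
            frame_times[f] = f / cfg.fps
            settled = frame_times[f] >= cfg.equilibration_s
            lit = self.field.gate(f) and cfg.render and settled
            frame_lit[f] = self.field.gate(f) and settled
            photon_images = [np.zeros((h, w), dtype=np.int64)
                             for _ in range(n_ch)] if lit else None
            for s in range(spf):
                t = (f * spf + s + 1) * dt
                self._apply_rate_changes(t)
                self._move_all()
                self._attempt_bindings(t, events)
                self._attempt_dissociations(t, events)
                if lit:
                    em, dr = self._render_substep(photon_images, t, events)
                    emitted_total += em
                    dropped_total += dr
                if sub_global % cfg.truth_every == 0:
                    truth_t[rec] = t
                    truth_pos[rec] = pop.pos
                    truth_face[rec] = pop.face
                    truth_partner[rec] = pop.partner
                    truth_tags[rec] = pop.active_tag_count
                    rec += 1
                sub_global += 1
            if lit:
                for ch in range(n_ch):
                    frames_ch[ch][f] = finalize_frame(
                        photon_images[ch], cfg.camera, self.rng.imaging)
            if (f + 1) % 100 == 0:
                logger.info("frame %d/%d, %d events so far", f + 1, n_frames,
                            len(events))

        stack = None
        stacks = []
        if cfg.render:
            z_f = np.full(n_frames, cfg.optics.z_focus_um)
            stacks = [FrameStack(frames=fr, times_s=frame_times,
                                 illuminated=frame_lit, z_focus_um=z_f)
                      for fr in frames_ch]
            stack = stacks[0]
        truth = GroundTruth(
            times_s=truth_t[:rec], pos_um=truth_pos[:rec],
            face=truth_face[:rec], partner=truth_partner[:rec],
            tags_active=truth_tags[:rec], class_id=pop.class_id,
            class_names=[c.name for c in cfg.classes])
        ev = pd.DataFrame(events, columns=["time_s", "event", "molecule_i",
                                           "molecule_j", "separation_nm"])
        return RunResult(config=cfg, stack=stack, truth=truth, events=ev,
                         population=pop, photons_emitted=emitted_total,
                         photons_dropped=dropped_total, stacks=stacks,
                         colours_nm=list(self.colours_nm))


def run(config: SimulationConfig,
        ait_cache: Optional[interactions.AITTableCache] = None) -> RunResult:
    """Build and run a simulation in one call."""
    return Simulation(config, ait_cache=ait_cache).run()
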