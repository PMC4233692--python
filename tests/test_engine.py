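import dataclasses

import numpy as np
import pytest

from virtucell import engine, tracking
from virtucell.config import (BindingRule, ConfigurationError,
                              IlluminationSpec, MoleculeClassSpec,
                              RateChange, SimulationConfig)
from virtucell.presets import scenario_preset


def mini_binding_config(**over):
    """Tiny anchor-binding system for fast kinetics tests."""
    base = dict(
        classes=[
            MoleculeClassSpec(name="movers", compartment="membrane",
                              d_um2_s=0.3, density_per_um2=0.5,
                              bindings=[BindingRule(partner="anchors",
                                                    r_bind=1e5, r_diss=1.0)]),
            MoleculeClassSpec(name="anchors", compartment="membrane",
                              d_um2_s=0.0, density_per_um2=0.5, n_tags=0),
        ],
        illumination=IlluminationSpec(mode="tirf"),
        duration_s=2.0, seed=3, render=False)
    base.update(over)
    return SimulationConfig(**base)


class TestRunBasics:
    def test_frame_count_is_duration_times_fps(self, small_membrane_config):
        res = engine.run(small_membrane_config)
        assert res.n_frames == 66        # 2 s at 33 fps

    def test_identical_seeds_are_bitwise_identical(self):
        cfg = scenario_preset("S4", duration_s=1.0, seed=9)
        r1 = engine.run(cfg)
        r2 = engine.run(cfg)
        assert np.array_equal(r1.stack.frames, r2.stack.frames)
        assert np.array_equal(r1.truth.pos_um, r2.truth.pos_um)
        assert r1.events.equals(r2.events)

    def test_molecule_count_conserved_and_tags_monotone(self):
        res = engine.run(mini_binding_config(render=True, duration_s=1.0,
                                             seed=5))
        n = res.population.n
        assert res.truth.pos_um.shape[1] == n
        tags = res.truth.tags_active.astype(int)
        assert np.all(np.diff(tags, axis=0) <= 0)

    def test_inconsistent_timing_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(fps=0.0, substeps_per_frame=10)

    def test_spot_count_matches_surface_density(self, small_membrane_config):
        # 1 molecule/um^2 on the 100 um^2 coverslip face under TIRF
        res = engine.run(small_membrane_config)
        dets = tracking.detect_spots(res.stack.frames[0],
                                     small_membrane_config.optics,
                                     noise_rms=2.0)
        # ~100 on the face, minus the detector's 3 px border margin
        assert 55 <= len(dets) <= 135

    def test_ground_truth_thinning(self):
        cfg = scenario_preset("S4", duration_s=1.0, seed=2, truth_every=10,
                              render=False)
        res = engine.run(cfg)
        assert len(res.truth.times_s) == 33


class TestBindingDynamics:
    def test_bound_pairs_share_coordinates(self):
        res = engine.run(mini_binding_config())
        part = res.truth.partner
        pos = res.truth.pos_um
        checked = 0
        for t in range(0, part.shape[0], 37):
            for i in np.nonzero(part[t] >= 0)[0]:
                j = part[t, i]
                np.testing.assert_array_equal(pos[t, i], pos[t, j])
                checked += 1
        assert checked > 50

    def test_site_bookkeeping_is_symmetric(self):
        res = engine.run(mini_binding_config(seed=8))
        part = res.truth.partner
        for t in range(0, part.shape[0], 53):
            bound = np.nonzero(part[t] >= 0)[0]
            for i in bound:
                assert part[t, part[t, i]] == i

    def test_static_anchors_never_move(self):
        res = engine.run(mini_binding_config(seed=4))
        anchors = res.truth.class_mask("anchors")
        pos = res.truth.pos_um[:, anchors]
        assert np.all(pos[0] == pos[-1])

    def test_equilibrium_monotone_in_rates(self):
        """Bound fraction rises with R_bind and falls with R_diss."""
        fractions = {}
        for rb in (3e3, 3e4, 3e5):
            for rd in (0.5, 2.0, 8.0):
                cfg = mini_binding_config(seed=6, duration_s=3.0)
                cfg.classes[0].bindings[0].r_bind = rb
                cfg.classes[0].bindings[0].r_diss = rd
                res = engine.run(cfg)
                fractions[(rb, rd)] = res.truth.bound_fraction(
                    "movers", t_min=1.5)
        for rd in (0.5, 2.0, 8.0):
            assert fractions[(3e3, rd)] < fractions[(3e4, rd)] \
                < fractions[(3e5, rd)]
        for rb in (3e4, 3e5):
            assert fractions[(rb, 0.5)] > fractions[(rb, 2.0)] \
                > fractions[(rb, 8.0)]

    def test_mid_run_rate_change_takes_effect(self):
        cfg = mini_binding_config(seed=11, duration_s=2.0)
        cfg.classes[0].bindings[0].r_bind = 0.0
        cfg = dataclasses.replace(cfg, rate_changes=[
            RateChange(time_s=1.0, class_name="movers", partner="anchors",
                       r_bind=1e5)])
        res = engine.run(cfg)
        binds = res.events[res.events.event == "bind"]
        assert len(binds) > 0
        assert binds.time_s.min() >= 1.0

    def test_cytoplasmic_molecule_rides_its_membrane_partner(self):
        cfg = SimulationConfig(
            classes=[
                MoleculeClassSpec(name="ph", compartment="cytoplasm",
                                  d_um2_s=5.0, count=500,
                                  bindings=[BindingRule(partner="lipid",
                                                        r_bind=1e7,
                                                        r_diss=0.0)]),
                MoleculeClassSpec(name="lipid", compartment="membrane",
                                  d_um2_s=0.001, density_per_um2=1.0,
                                  n_tags=0),
            ],
            duration_s=1.0, seed=13, render=False)
        res = engine.run(cfg)
        part = res.truth.partner[-1]
        ph = np.nonzero(res.truth.class_mask("ph") & (part >= 0))[0]
        assert ph.size > 0
        # bound cytoplasmic molecules sit exactly at their partner
        np.testing.assert_array_equal(res.truth.pos_um[-1, ph],
                                      res.truth.pos_um[-1, part[ph]])


class TestSchedulesAndPresets:
    def test_gated_frames_are_dark(self):
        cfg = scenario_preset("S7", duration_s=2.0, seed=1)
        cfg = dataclasses.replace(cfg, illumination=dataclasses.replace(
            cfg.illumination, duty_ratio=0.2, period_frames=5))
        res = engine.run(cfg)
        lit = res.stack.illuminated
        assert lit.sum() == res.n_frames // 5
        dark = res.stack.frames[~lit]
        assert dark.max() <= 20          # background noise only

    def test_equilibration_period_is_unilluminated(self):
        cfg = scenario_preset("S4", duration_s=1.0, seed=1,
                              equilibration_s=1.0)
        res = engine.run(cfg)
        assert res.n_frames == 66
        assert not res.stack.illuminated[:33].any()
        assert res.stack.illuminated[33:].all()

    def test_preset_S5_barriers(self):
        cfg = scenario_preset("S5")
        assert cfg.membrane_features.barrier_pitch_um == 1.0
        assert cfg.membrane_features.barrier_permeability == 0.0

    def test_preset_S7_rates(self):
        cfg = scenario_preset("S7")
        rule = cfg.classes[0].bindings[0]
        assert rule.r_bind == 1e6 and rule.r_diss == 0.05
        assert cfg.fps == 10.0
        assert cfg.class_named("targets").d_um2_s == 0.001

    def test_preset_S8_densities(self):
        cfg = scenario_preset("S8")
        assert cfg.classes[0].density_per_um2 == 0.5
        assert cfg.class_named("anchors").density_per_um2 == 0.5
        rule = cfg.classes[0].bindings[0]
        assert rule.r_bind == 1e5 and rule.r_diss == 1.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            scenario_preset("S99")

    def test_two_colour_classes_render_to_separate_channels(self):
        cfg = SimulationConfig(
            classes=[
                MoleculeClassSpec(name="green", compartment="membrane",
                                  d_um2_s=0.1, count=20,
                                  tag_colour_nm=532.0),
                MoleculeClassSpec(name="red", compartment="membrane",
                                  d_um2_s=0.1, count=20, tag_colour_nm=640.0),
            ],
            illumination=IlluminationSpec(mode="tirf"),
            duration_s=0.5, seed=2)
        res = engine.run(cfg)
        assert len(res.stacks) == 2
        assert res.colours_nm == [532.0, 640.0]
        assert res.stacks[0].frames.shape == res.stacks[1].frames.shape
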