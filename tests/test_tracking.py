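import math

import numpy as np
import pytest

from virtucell import io, tracking
from virtucell.config import CameraSpec, OpticsSpec
from virtucell.tracking import (Track, bound_time_analysis, detect_spots,
                                intensity_distribution, link_tracks,
                                mobility_bimodality, msd_analysis, off_rate)


def synthetic_walk_tracks(rng, d, n_tracks, n_frames, fps=33.0, pixel=0.1,
                          noise_um=0.0):
    out = []
    for _ in range(n_tracks):
        steps = rng.normal(0, math.sqrt(2 * d / fps), size=(n_frames - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if noise_um:
            pos = pos + rng.normal(0, noise_um, size=pos.shape)
        out.append(Track(frames=np.arange(n_frames), x_px=pos[:, 0] / pixel,
                         y_px=pos[:, 1] / pixel,
                         intensity=np.ones(n_frames)))
    return out


class TestDetection:
    def test_single_spot_localised_within_30nm(self):
        fx = io.make_fixture("single_spot", seed=0)
        errs = []
        for frame in fx["frames"]:
            det = detect_spots(frame, fx["optics"],
                               noise_rms=fx["camera"].noise_rms)
            assert len(det) >= 1
            # rare noise maxima may pass the k=4 threshold; measure the
            # localisation of the detection at the true spot
            k = np.argmin(np.sum((det[:, :2] * 0.1
                                  - fx["truth_um"][0, 0]) ** 2, axis=1))
            errs.append(det[k, :2] * 0.1 - fx["truth_um"][0, 0])
        rms = np.sqrt(np.mean(np.sum(np.square(errs), axis=1)))
        assert rms < 0.030

    def test_blank_noise_false_positive_rate(self):
        fx = io.make_fixture("blank_noise", seed=1)
        n_fp = sum(len(detect_spots(f, fx["optics"],
                                    noise_rms=fx["camera"].noise_rms))
                   for f in fx["frames"])
        assert n_fp / len(fx["frames"]) < 1.0

    def test_two_resolvable_spots(self):
        fx = io.make_fixture("two_spots", seed=2)
        det = detect_spots(fx["frames"][0], fx["optics"],
                           noise_rms=fx["camera"].noise_rms)
        assert len(det) == 2

    def test_subdiffraction_pair_reports_one_spot(self, rng):
        from virtucell.imaging import finalize_frame, splat_photons
        img = np.zeros((40, 40), dtype=np.int64)
        # two emitters 100 nm apart: unresolved at a 250 nm PSF
        splat_photons(img, np.array([2.0, 2.1]), np.array([2.0, 2.0]),
                      np.array([5000, 5000]), np.array([0.25, 0.25]), 0.1,
                      rng)
        frame = finalize_frame(img, CameraSpec(), rng)
        det = detect_spots(frame, OpticsSpec(), noise_rms=2.0)
        bright = det[det[:, 2] > 50]      # ignore threshold-level noise blips
        assert len(bright) == 1

    def test_border_margin_rejects_clipped_spots(self, rng):
        from virtucell.imaging import finalize_frame, splat_photons
        img = np.zeros((40, 40), dtype=np.int64)
        splat_photons(img, np.array([0.1]), np.array([2.0]),
                      np.array([20_000]), np.array([0.25]), 0.1, rng)
        frame = finalize_frame(img, CameraSpec(), rng)
        assert len(detect_spots(frame, OpticsSpec(), noise_rms=2.0)) == 0


class TestLinking:
    def test_static_molecule_yields_one_full_track(self):
        fx = io.make_fixture("single_spot", seed=3)
        dets = [detect_spots(f, fx["optics"], noise_rms=2.0)
                for f in fx["frames"]]
        tracks = link_tracks(dets, max_disp_px=3.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 50

    def test_minimum_length_twenty_enforced(self):
        fx = io.make_fixture("single_spot", seed=4)
        dets = [detect_spots(f, fx["optics"], noise_rms=2.0)
                for f in fx["frames"][:19]]
        assert link_tracks(dets, max_disp_px=3.0) == []

    def test_five_walkers_recovered(self):
        fx = io.make_fixture("five_track_movie", seed=5)
        dets = [detect_spots(f, fx["optics"], noise_rms=2.0)
                for f in fx["frames"]]
        gate = tracking.linking_gate_px(0.1, 1 / fx["fps"], 0.1)
        tracks = link_tracks(dets, max_disp_px=gate)
        assert 4 <= len(tracks) <= 7
        m = msd_analysis(tracks, 1 / fx["fps"], 0.1)
        assert 0.05 < m.d_mean_um2_s < 0.16


class TestMsd:
    def test_recovers_d_on_ideal_tracks(self, rng):
        tracks = synthetic_walk_tracks(rng, 0.3, 250, 120)
        m = msd_analysis(tracks, 1 / 33, 0.1)
        d = m.d_per_track[~np.isnan(m.d_per_track)]
        se = d.std() / math.sqrt(len(d))
        assert abs(m.d_mean_um2_s - 0.3) < 3 * se + 0.003
        assert abs(d.mean() - 0.3) < 3 * se + 0.003

    def test_localisation_noise_goes_into_intercept(self, rng):
        sigma = 0.030
        tracks = synthetic_walk_tracks(rng, 0.0, 150, 100, noise_um=sigma)
        m = msd_analysis(tracks, 1 / 33, 0.1)
        # static molecules: slope ~ 0, intercept ~ 4 sigma^2
        assert abs(m.d_mean_um2_s) < 0.002
        assert m.intercept_um2 == pytest.approx(4 * sigma ** 2, rel=0.15)

    def test_msd_curve_counts_non_increasing(self, rng):
        tracks = synthetic_walk_tracks(rng, 0.1, 30, 50)
        tracks += synthetic_walk_tracks(rng, 0.1, 30, 25)
        m = msd_analysis(tracks, 1 / 33, 0.1, max_lag=40)
        assert np.all(np.diff(m.curve.n_tracks) <= 0)

    def test_empty_input_flagged(self):
        with pytest.raises(ValueError):
            msd_analysis([], 1 / 33, 0.1)


class TestOffRate:
    def test_recovers_exponential_survival_rate(self, rng):
        rate, fps = 1.0, 33.0
        tracks = []
        for _ in range(3000):
            n = 20 + rng.geometric(1 - math.exp(-rate / fps))
            tracks.append(Track(frames=np.arange(n), x_px=np.zeros(n),
                                y_px=np.zeros(n), intensity=np.ones(n)))
        fit = off_rate(tracks, 1 / fps)
        assert fit.rate_s == pytest.approx(rate, rel=0.10)

    def test_immortal_tracks_have_near_zero_off_rate(self):
        tracks = [Track(frames=np.arange(100), x_px=np.zeros(100),
                        y_px=np.zeros(100), intensity=np.ones(100))
                  for _ in range(60)]
        fit = off_rate(tracks, 1 / 33)
        assert abs(fit.rate_s) < 1e-6


class TestBoundTime:
    def test_recovers_rate_on_labelled_tracks(self, rng):
        """Mobile-immobile-mobile episodes with known exponential durations."""
        fps, d_free = 33.0, 0.3
        durations = []
        tracks = []
        for _ in range(400):
            segs = []
            true_dur = []
            for k in range(3):
                mob = rng.normal(0, math.sqrt(2 * d_free / fps), size=(30, 2))
                segs.append(mob)
                if k < 2:
                    n_imm = max(3, int(rng.exponential(1.0) * fps))
                    true_dur.append(n_imm)
                    segs.append(np.zeros((n_imm, 2)))
            steps = np.vstack(segs)
            pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            pos += rng.normal(0, 0.018, size=pos.shape)
            tracks.append(Track(frames=np.arange(len(pos)),
                                x_px=pos[:, 0] / 0.1, y_px=pos[:, 1] / 0.1,
                                intensity=np.ones(len(pos))))
            durations.extend(true_dur)
        res = bound_time_analysis(tracks, 1 / fps, 0.1)
        true_rate = 1.0 / (np.mean(durations) / fps)
        assert res.n_episodes > 400
        assert res.rate_s == pytest.approx(true_rate, rel=0.35)

    def test_no_binding_means_no_episodes(self, rng):
        tracks = synthetic_walk_tracks(rng, 0.3, 50, 80)
        res = bound_time_analysis(tracks, 1 / 33, 0.1)
        assert res.n_episodes == 0


class TestPipelineRecovery:
    @pytest.mark.parametrize("d_true", [0.1, 0.3])
    def test_full_pipeline_recovers_d_within_ten_percent(self, d_true):
        """simulate -> image -> track -> MSD returns the input mobility."""
        from virtucell import experiments
        m = experiments.measure_membrane_mobility(seeds=(5,), d_um2_s=d_true)
        assert m.n_tracks > 50
        assert m.d_mean_um2_s == pytest.approx(d_true, rel=0.10)

    def test_slow_diffusion_sits_at_the_localisation_noise_floor(self):
        """At D = 0.01 um^2/s the per-frame displacement is ~0.35 px and
        centroid pixel-locking inflates the fitted slope; the measured
        value stays the right order of magnitude but not within the 10%
        achieved at higher mobilities (documented detector property)."""
        from virtucell import experiments
        m = experiments.measure_membrane_mobility(seeds=(5,), d_um2_s=0.01)
        assert 0.008 < m.d_mean_um2_s < 0.02


class TestDistributions:
    def test_bimodality_detects_two_populations(self, rng):
        d = np.concatenate([rng.normal(0.03, 0.015, 150),
                            rng.normal(0.30, 0.08, 150)])
        assert mobility_bimodality(d)["bimodal"]

    def test_single_population_not_bimodal(self, rng):
        d = rng.normal(0.30, 0.08, 300)
        assert not mobility_bimodality(d)["bimodal"]

    def test_intensity_cv_zero_for_identical_tracks(self):
        tracks = [Track(frames=np.arange(25), x_px=np.zeros(25),
                        y_px=np.zeros(25), intensity=np.full(25, 7.0))
                  for _ in range(5)]
        vals, cv = intensity_distribution(tracks)
        assert cv == pytest.approx(0.0, abs=1e-12)
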