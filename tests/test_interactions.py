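import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import erfc, exp1

from virtucell.interactions import (AITTable, AITTableCache, candidate_pairs,
                                    attempt_bindings, attempt_dissociations,
                                    compute_ait, green_density,
                                    interaction_measure)


def ait_closed_form(x_um, d, id_nm, dt, ndim):
    """Independent oracle: the time integral of the propagator-times-measure
    in closed form (exponential-integral / erfc expressions)."""
    meas = interaction_measure(id_nm, ndim)
    a = x_um * x_um / (4.0 * d)
    if ndim == 2:
        return meas / (4 * math.pi * d) * exp1(a / dt)
    if ndim == 3:
        return meas * (4 * math.pi * d) ** -1.5 * math.sqrt(math.pi / a) \
            * erfc(math.sqrt(a / dt))
    return meas * (4 * math.pi * d) ** -0.5 * (
        2 * math.sqrt(dt) * math.exp(-a / dt)
        - 2 * math.sqrt(math.pi * a) * erfc(math.sqrt(a / dt)))


class TestGreenDensity:
    def test_vanishes_at_large_separation(self):
        assert green_density(50.0, 1e-3, 0.1, 2, 5.0) == pytest.approx(0.0)

    def test_mode_at_origin_1d(self):
        xs = np.linspace(0, 1, 50)
        g = green_density(xs, 1e-3, 0.1, 1, 5.0)
        assert np.argmax(g) == 0

    def test_matches_independent_quadrature_to_1e10(self):
        # 2D, D=0.1, ID=5 nm, x=50 nm, t=1 ms
        d, id_nm, x, t = 0.1, 5.0, 0.05, 1e-3
        expected = (4 * math.pi * d * t) ** -1 * math.exp(
            -x * x / (4 * d * t)) * math.pi * (id_nm * 5e-4) ** 2
        assert green_density(x, t, d, 2, id_nm) == pytest.approx(
            expected, rel=1e-10)

    def test_invalid_time_raises(self):
        with pytest.raises(ValueError):
            green_density(0.1, 0.0, 0.1, 2, 5.0)


class TestComputeAit:
    def test_coincident_pair_interacts_whole_step(self):
        assert compute_ait(0.0, 0.1, 5.0, 0.1, 2) == 0.1

    def test_negligible_beyond_one_micron(self):
        for d, ndim in [(0.1, 2), (1.0, 3)]:
            assert compute_ait(2.0, d, 5.0, 0.1, ndim) < 1e-9

    @pytest.mark.parametrize("d,dt,x_nm,ndim", [
        (0.1, 0.1, 50, 2), (0.2, 0.1, 100, 2), (0.5, 0.01, 40, 2),
        (1.0, 0.1, 300, 2), (0.1, 0.005, 30, 3), (1.0, 0.1, 100, 3),
        (2.0, 0.01, 60, 3), (0.1, 0.05, 80, 1),
    ])
    def test_quadrature_matches_closed_form(self, d, dt, x_nm, ndim):
        x = x_nm * 1e-3
        assert compute_ait(x, d, 5.0, dt, ndim) == pytest.approx(
            ait_closed_form(x, d, 5.0, dt, ndim), rel=5e-3)

    def test_quadrature_matches_adaptive_integration(self):
        d, id_nm, dt, x = 0.1, 5.0, 0.1, 0.05
        ref, _ = integrate.quad(
            lambda t: green_density(x, t, d, 2, id_nm), 1e-12, dt,
            limit=200)
        assert compute_ait(x, d, id_nm, dt, 2) == pytest.approx(ref, rel=5e-3)

    def test_monotone_decrease_beyond_near_field(self):
        x = np.arange(25, 1000) * 1e-3
        for d in (0.1, 0.2, 0.5, 1.0):
            ait = compute_ait(x, d, 5.0, 0.1, 2)
            assert np.all(np.diff(ait) <= 1e-15)

    def test_shorter_time_step_gives_smaller_ait(self):
        x = np.arange(25, 500) * 1e-3
        prev = None
        for dt in (1e-3, 5e-3, 1e-2, 5e-2, 1e-1):
            ait = compute_ait(x, 0.1, 5.0, dt, 2)
            if prev is not None:
                assert np.all(ait >= prev - 1e-18)
            prev = ait


class TestAitTable:
    def test_lookup_matches_direct_evaluation(self):
        table = AITTable.build(0.3, 5.0, 3e-3, 2)
        x = np.array([0.01, 0.05, 0.123])
        np.testing.assert_allclose(
            table.ait_at(x), compute_ait(x, 0.3, 5.0, 3e-3, 2), rtol=1e-6)

    def test_rate_change_reuses_cached_table(self):
        cache = AITTableCache()
        t1 = cache.get(0.3, 5.0, 3e-3, 2)
        t2 = cache.get(0.3, 5.0, 3e-3, 2)   # same physics, new rate
        assert t1 is t2 and cache.builds == 1
        cache.get(0.3, 5.0, 1e-3, 2)        # new time step -> rebuild
        assert cache.builds == 2

    def test_cutoff_grows_with_binding_rate(self):
        table = AITTable.build(0.3, 5.0, 3e-3, 2)
        assert table.cutoff_nm(1e6) > table.cutoff_nm(1e4) > 0
        assert table.cutoff_nm(0.0) == 0

    def test_export_two_column_text(self, tmp_path):
        table = AITTable.build(0.1, 5.0, 1e-3, 2)
        path = tmp_path / "ait.txt"
        table.to_text(path)
        data = np.loadtxt(path)
        assert data.shape[1] == 2
        np.testing.assert_allclose(data[:, 1], table.values_s, rtol=1e-6)


class TestCandidatePairs:
    def test_distant_pair_not_reported(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[3.0, 0.0, 0.0]])
        i, j, d = candidate_pairs(a, b, 2.0)
        assert len(i) == 0

    def test_equals_brute_force_enumeration(self, rng):
        a = rng.random((60, 3)) * 2
        b = rng.random((40, 3)) * 2
        i, j, d = candidate_pairs(a, b, 0.5)
        got = set(zip(i.tolist(), j.tolist()))
        expected = {(ii, jj) for ii in range(60) for jj in range(40)
                    if np.linalg.norm(a[ii] - b[jj]) <= 0.5}
        assert got == expected

    def test_same_class_pairs_unordered_unique(self, rng):
        a = rng.random((50, 3))
        i, j, _ = candidate_pairs(a, a, 0.4, exclude_self=True)
        assert np.all(i < j)
        assert len(set(zip(i.tolist(), j.tolist()))) == len(i)


class TestBindingTrials:
    def test_zero_rate_never_binds(self, rng):
        table = AITTable.build(0.3, 5.0, 3e-3, 2)
        i = np.arange(10)
        j = np.arange(10)
        d = np.full(10, 0.01)
        free = np.ones(10, dtype=bool)
        events = attempt_bindings(i, j, d, table, 0.0, free, free.copy(), rng)
        assert events == []

    def test_occupied_sites_excluded_and_first_success_wins(self, rng):
        table = AITTable.build(0.3, 5.0, 3e-3, 2)
        # two candidate pairs share molecule 0; huge rate -> both would fire
        i = np.array([0, 0])
        j = np.array([1, 2])
        d = np.array([0.002, 0.001])
        free_i = np.ones(3, dtype=bool)
        events = attempt_bindings(i, j, d, table, 1e9, free_i, free_i, rng)
        assert len(events) == 1
        assert events[0][1] == 2          # the closer partner wins

    def test_dissociation_probability_formula(self):
        rng = np.random.default_rng(0)
        n = 200_000
        hits = attempt_dissociations(np.arange(n), 1.0, 3.03e-3, rng)
        assert hits.size / n == pytest.approx(3.03e-3, rel=0.05)

    def test_zero_dissociation_rate_is_permanent(self, rng):
        assert attempt_dissociations(np.arange(100), 0.0, 1e-3, rng).size == 0

    def test_bound_lifetimes_are_exponential(self):
        # R_diss = 1/s sampled at 3 ms steps: lifetime mean 1 s +- 3 s.e.
        rng = np.random.default_rng(2)
        dt, n = 3e-3, 10_000
        alive = np.ones(n, dtype=bool)
        lifetime = np.zeros(n)
        for step in range(1, 4000):
            idx = np.nonzero(alive)[0]
            if idx.size == 0:
                break
            hits = attempt_dissociations(idx, 1.0, dt, rng)
            lifetime[idx[hits]] = step * dt
            alive[idx[hits]] = False
        lifetime = lifetime[lifetime > 0]
        se = lifetime.std() / math.sqrt(len(lifetime))
        assert abs(lifetime.mean() - 1.0) < 3 * se + dt
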