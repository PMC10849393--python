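"""Reduced spine model: geometry, voltage/calcium dynamics, detector."""

import numpy as np
import pytest

from matchcontrol import (
    CalciumTrace,
    SpikeTrain,
    bap_arrivals,
    build_geometry,
    detector_integral,
    simulate_scores,
    simulate_spine,
)


class TestGeometry:
    def test_default_counts(self, geometry):
        assert geometry.n_groups == 150
        assert geometry.n_spines == 1500
        assert geometry.n_branches == 6

    def test_trivial_geometry(self):
        g = build_geometry(1, 1, n_branches=1, spines_per_branch=1)
        assert g.n_spines == 1
        assert g.latencies[0] == pytest.approx(4.0, abs=0.01)

    def test_latencies_monotone_along_each_branch(self, geometry):
        for b in range(geometry.n_branches):
            lat = geometry.latencies[geometry.branch_of_group == b]
            assert np.all(np.diff(lat) >= 0)
            assert np.all(lat >= 0)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            build_geometry(150, 10, n_branches=7)
        with pytest.raises(ValueError):
            build_geometry(150, 10, n_branches=6, spines_per_branch=100)

    def test_symmetric_branches_tie_broken_by_branch_index(self, geometry):
        g0 = geometry.latencies[geometry.branch_of_group == 0]
        g1 = geometry.latencies[geometry.branch_of_group == 1]
        assert np.all(g1 > g0)


class TestBapArrivals:
    def test_zero_latency_is_identity(self):
        g = build_geometry(2, 10, n_branches=1, spines_per_branch=20,
                           latency_min=0.0, latency_max=0.0)
        soma = SpikeTrain(np.array([0.1, 0.4]), 1.0)
        out = bap_arrivals(soma, g, 0)
        np.testing.assert_allclose(out.times, soma.times)

    def test_three_ms_latency_shift(self):
        g = build_geometry(1, 10, n_branches=1, spines_per_branch=10,
                           latency_min=3.0, latency_max=3.0)
        out = bap_arrivals(SpikeTrain(np.array([0.1]), 1.0), g, 0)
        assert out.times[0] == pytest.approx(0.103)

    def test_count_preserved(self, geometry):
        soma = SpikeTrain(np.sort(np.random.default_rng(0).uniform(0, 1, 17)), 1.0)
        for group in (0, 70, 149):
            assert len(bap_arrivals(soma, geometry, group)) == 17


class TestSimulateSpine:
    def test_silent_inputs_give_zero_calcium(self, quiet_params):
        empty = SpikeTrain(np.empty(0), 0.2)
        _, ca = simulate_spine(empty, empty, quiet_params)
        assert np.all(ca.values == 0)

    def test_mg_block_suppresses_glutamate_without_bap(self, quiet_params):
        pre = SpikeTrain(np.array([0.1]), 0.3)
        empty = SpikeTrain(np.empty(0), 0.3)
        bap = SpikeTrain(np.array([0.107]), 0.3)
        _, ca_alone = simulate_spine(pre, empty, quiet_params)
        _, ca_coinc = simulate_spine(pre, bap, quiet_params)
        assert detector_integral(ca_alone) < detector_integral(ca_coinc)
        # coincidence dominates by orders of magnitude under the 4th power
        assert detector_integral(ca_coinc) > 10 * detector_integral(ca_alone)

    def test_optimal_offset_beats_late_offset(self, quiet_params):
        pre = SpikeTrain(np.array([0.1]), 0.3)
        near = SpikeTrain(np.array([0.107]), 0.3)
        far = SpikeTrain(np.array([0.130]), 0.3)
        _, ca_near = simulate_spine(pre, near, quiet_params)
        _, ca_far = simulate_spine(pre, far, quiet_params)
        assert detector_integral(ca_near) > 2 * detector_integral(ca_far)

    def test_score_non_decreasing_in_coincident_pairs(self, quiet_params):
        scores = []
        for n_pairs in (1, 2, 3):
            t = 0.1 + 0.1 * np.arange(n_pairs)
            pre = SpikeTrain(t, 0.5)
            bap = SpikeTrain(t + 0.007, 0.5)
            _, ca = simulate_spine(pre, bap, quiet_params)
            scores.append(detector_integral(ca))
        assert scores[0] < scores[1] < scores[2]

    def test_coarse_dt_rejected(self, quiet_params):
        pre = SpikeTrain(np.array([0.1]), 0.2)
        with pytest.raises(ValueError, match="dt"):
            simulate_spine(pre, pre, quiet_params, dt=1.0)

    def test_noise_streams_reproducible(self, params):
        pre = SpikeTrain(np.array([0.05]), 0.2)
        bap = SpikeTrain(np.array([0.057]), 0.2)
        v1, ca1 = simulate_spine(pre, bap, params, seed=42)
        v2, ca2 = simulate_spine(pre, bap, params, seed=42)
        np.testing.assert_array_equal(ca1.values, ca2.values)
        np.testing.assert_array_equal(v1, v2)


class TestDetectorIntegral:
    def test_zero_trace(self):
        assert detector_integral(CalciumTrace(0.1, np.zeros(100))) == 0.0

    def test_degree_four_homogeneity(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 2, 500)
        s1 = detector_integral(CalciumTrace(0.1, v))
        s2 = detector_integral(CalciumTrace(0.1, 2 * v))
        assert s2 == pytest.approx(16 * s1, rel=1e-12)

    def test_constant_trace_closed_form(self):
        # constant c over Delta seconds -> c^4 * Delta
        c, dt, n = 1.7, 0.1, 3000
        s = detector_integral(CalciumTrace(dt, np.full(n, c)))
        assert s == pytest.approx(c**4 * n * dt * 1e-3, rel=1e-9)

    def test_non_finite_trace_rejected(self):
        with pytest.raises(ValueError):
            detector_integral(CalciumTrace(0.1, np.array([1.0, np.inf])))


class TestSimulateScores:
    def test_matches_single_spine_path(self, quiet_params):
        """The batched engine and the single-spine API agree exactly."""
        rng = np.random.default_rng(3)
        pre = np.sort(rng.uniform(0, 1, 6))
        bap = np.sort(rng.uniform(0, 1, 5))
        s_batch = simulate_scores([pre], [bap], 1.0, quiet_params, seed=0)[0]
        _, ca = simulate_spine(
            SpikeTrain(pre, 1.0), SpikeTrain(bap, 1.0), quiet_params, duration=1.0
        )
        assert s_batch == pytest.approx(detector_integral(ca), rel=1e-5)

    def test_batching_independence(self, params):
        rng = np.random.default_rng(4)
        pres = [np.sort(rng.uniform(0, 1, 6)) for _ in range(7)]
        bap = [np.sort(rng.uniform(0, 1, 6))]
        a = simulate_scores(pres, bap, 1.0, params, seed=5)
        b = simulate_scores(pres, bap, 1.0, params, seed=5, max_block_elements=20_000)
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_bap_shift_equals_shifted_train(self, quiet_params):
        rng = np.random.default_rng(5)
        pre = [np.sort(rng.uniform(0, 0.8, 6))]
        bap = np.sort(rng.uniform(0, 0.8, 5))
        lat = 0.0031
        shifted = simulate_scores(pre, [bap], 1.0, quiet_params, seed=0,
                                  bap_shifts=np.array([lat]))
        # compose the shift on the integer step grid, as the engine does
        dt_s = quiet_params.dt * 1e-3
        grid_times = (np.floor(bap / dt_s) + round(lat / dt_s)) * dt_s + dt_s / 2
        explicit = simulate_scores(pre, [grid_times], 1.0, quiet_params, seed=0)
        np.testing.assert_allclose(shifted, explicit, rtol=1e-5)
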