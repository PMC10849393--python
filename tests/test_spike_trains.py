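"""Spike-train generation, transforms and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matchcontrol import (
    SpikeTrain,
    TrainEnsemble,
    concatenate_phases,
    generate_ensemble,
    jitter,
    load_ensemble,
    make_matched_train,
    sample_poisson_refractory,
    save_ensemble,
)


class TestSpikeTrain:
    def test_rejects_unsorted_and_out_of_window(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.2, 0.1]), 1.0)
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.5, 1.0]), 1.0)
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.1]), 0.0)

    def test_shift_drops_spikes_leaving_window(self, toy_train):
        shifted = toy_train.shift(0.5)
        np.testing.assert_allclose(shifted.times, [0.6, 0.8])


class TestPoissonSampler:
    def test_zero_rate_gives_empty_train(self):
        tr = sample_poisson_refractory(0, 0.05, 1.0, seed=1)
        assert len(tr) == 0 and tr.duration == 1.0

    def test_dead_time_spanning_window_allows_at_most_one_spike(self):
        for seed in range(30):
            tr = sample_poisson_refractory(6, 0.05, 0.05, seed=seed)
            assert len(tr) <= 1

    def test_compensated_sampler_realizes_nominal_rate(self):
        # dead-time compensation: long-run empirical rate ~ 6 Hz
        tr = sample_poisson_refractory(6, 0.05, 1000.0, seed=3)
        assert tr.rate == pytest.approx(6.0, abs=0.1)

    def test_uncompensated_rate_is_lower(self):
        tr = sample_poisson_refractory(6, 0.05, 1000.0, seed=3,
                                       compensate_dead_time=False)
        # thinned by the dead time: expected ~ 6/(1 + 6*0.05) = 4.6 Hz
        assert 4.2 < tr.rate < 5.0

    def test_unreachable_rate_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            sample_poisson_refractory(21, 0.05, 1.0, seed=0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_refractory_dead_time_never_violated(self, seed):
        tr = sample_poisson_refractory(6, 0.05, 5.0, seed=seed)
        if len(tr) > 1:
            assert np.diff(tr.times).min() >= 0.05
        assert tr.refractory == 0.05


class TestMatchedTrain:
    def test_empty_arrivals_give_empty_train(self):
        out = make_matched_train(SpikeTrain(np.empty(0), 1.0))
        assert len(out) == 0

    def test_elementwise_shift(self):
        arr = SpikeTrain(np.array([0.100, 0.300]), 1.0)
        out = make_matched_train(arr, lead=0.007)
        np.testing.assert_allclose(out.times, [0.093, 0.293])

    def test_arrival_before_lead_is_dropped(self):
        arr = SpikeTrain(np.array([0.005]), 1.0)
        assert len(make_matched_train(arr, lead=0.007)) == 0


class TestJitter:
    def test_sigma_zero_is_identity(self, toy_train):
        out = jitter(toy_train, 0.0, seed=5)
        np.testing.assert_array_equal(out.times, toy_train.times)

    def test_monte_carlo_sd_matches_sigma(self):
        tr = SpikeTrain(np.array([0.5]), 1.0)
        shifted = [jitter(tr, 0.001, seed=s).times[0] for s in range(400)]
        assert np.std(shifted) == pytest.approx(0.001, rel=0.15)

    def test_output_sorted_and_in_window(self):
        tr = SpikeTrain(np.array([0.1, 0.2]), 1.0)
        for s in range(20):
            out = jitter(tr, 0.002, seed=s)
            assert len(out) == 2
            assert np.all(np.diff(out.times) > 0)

    def test_boundary_clipping(self):
        tr = SpikeTrain(np.array([0.0001, 0.9999]), 1.0)
        out = jitter(tr, 0.01, seed=11)
        assert len(out) == 2
        assert out.times[0] >= 0 and out.times[-1] < 1.0


class TestConcatenatePhases:
    def test_offset_arithmetic(self):
        key = SpikeTrain(np.array([0.1]), 1.0)
        value = SpikeTrain(np.array([0.2]), 1.0)
        out = concatenate_phases(key, value, gap=0.5)
        np.testing.assert_allclose(out.times, [0.1, 1.7])
        assert out.duration == 2.5

    def test_empty_value_pads_duration(self):
        key = SpikeTrain(np.array([0.1]), 1.0)
        out = concatenate_phases(key, SpikeTrain(np.empty(0), 1.0), gap=0.5)
        np.testing.assert_allclose(out.times, [0.1])
        assert out.duration == 2.5

    def test_zero_gap(self):
        key = SpikeTrain(np.array([0.9]), 1.0)
        value = SpikeTrain(np.array([0.0]), 1.0)
        out = concatenate_phases(key, value, gap=0.0)
        np.testing.assert_allclose(out.times, [0.9, 1.0])


class TestEnsemble:
    def test_mixed_durations_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            TrainEnsemble(
                [SpikeTrain(np.empty(0), 1.0), SpikeTrain(np.empty(0), 2.0)]
            )

    def test_generate_ensemble_marks_matched_axons(self):
        q = sample_poisson_refractory(6, 0.05, 1.0, seed=0)
        ens = generate_ensemble(20, 6, 0.05, 1.0, matched=1, seed=4, query=q)
        assert ens.matched_indices == (0,)
        assert len(ens.trains) == 20
        # matched train leads the query by 7 ms
        np.testing.assert_allclose(
            ens.trains[0].times, q.times[q.times >= 0.007] - 0.007, atol=1e-12
        )

    def test_ensemble_is_seed_deterministic(self):
        q = sample_poisson_refractory(6, 0.05, 1.0, seed=0)
        a = generate_ensemble(10, 6, 0.05, 1.0, 0, seed=9, query=q)
        b = generate_ensemble(10, 6, 0.05, 1.0, 0, seed=9, query=q)
        for ta, tb in zip(a.trains, b.trains):
            np.testing.assert_array_equal(ta.times, tb.times)

    def test_csv_round_trip_is_lossless_to_1us(self, tmp_path):
        q = sample_poisson_refractory(6, 0.05, 1.0, seed=0)
        ens = generate_ensemble(5, 6, 0.05, 1.0, matched=1, seed=2, query=q)
        path = tmp_path / "ens.csv"
        save_ensemble(ens, path)
        back = load_ensemble(path)
        assert back.matched_indices == ens.matched_indices
        assert back.window == ens.window
        for ta, tb in zip(ens.trains, back.trains):
            assert ta.duration == tb.duration
            np.testing.assert_allclose(ta.times, tb.times, atol=1e-6)
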