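"""Kernel model, least-squares fit, outlier rule and the offset sweep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matchcontrol import (
    Kernel,
    SpikeTrain,
    fit_kernel,
    offset_sweep,
    predict_kernel_model,
    remove_outliers,
    score_ensemble,
    generate_ensemble,
    sample_poisson_refractory,
)
from matchcontrol.match_phase import _envelope
import pandas as pd


def gaussian_kernel(peak_ms=7.0, width_ms=6.0, height=1.0):
    g = np.arange(-60, 61, 1.0)
    return Kernel(g, height * np.exp(-0.5 * ((g - peak_ms) / width_ms) ** 2))


def brute_force_overlap(kernel, pre, post):
    """O(n^2) oracle: explicit loop over all spike pairs."""
    total = 0.0
    for tp in pre:
        for ta in post:
            total += kernel((ta - tp) * 1e3)
    return total


class TestEnvelope:
    def test_exponential_decay_outside_window(self):
        # beyond +-30 ms the envelope is bounded by exp(-(|dt|-30)/10) and
        # approaches that decay rate asymptotically
        x = np.arange(35.0, 101.0, 5.0)
        assert np.all(_envelope(x) <= np.exp(-(x - 30.0) / 10.0) + 1e-12)
        e80, e90 = _envelope(np.array([80.0]))[0], _envelope(np.array([90.0]))[0]
        assert e90 / e80 == pytest.approx(np.exp(-1.0), rel=0.02)
        assert _envelope(np.array([-90.0]))[0] == pytest.approx(e90, rel=1e-9)


class TestPredictKernelModel:
    def test_empty_train_gives_zero(self):
        k = gaussian_kernel()
        assert predict_kernel_model(k, np.empty(0), np.array([0.1])) == 0.0

    def test_single_pair_evaluates_kernel(self):
        k = gaussian_kernel()
        pre, post = np.array([0.100]), np.array([0.107])
        assert predict_kernel_model(k, pre, post) == pytest.approx(k(7.0), rel=1e-9)

    def test_two_by_two_sums_four_pairwise_terms(self):
        k = gaussian_kernel()
        pre, post = np.array([0.1, 0.2]), np.array([0.105, 0.21])
        expected = sum(
            k((ta - tp) * 1e3) for tp in pre for ta in post
        )
        assert predict_kernel_model(k, pre, post) == pytest.approx(expected, rel=1e-12)

    @given(
        n_pre=st.integers(0, 6), n_post=st.integers(0, 6),
        seed=st.integers(0, 999),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_pairwise_oracle(self, n_pre, n_post, seed):
        rng = np.random.default_rng(seed)
        k = gaussian_kernel()
        pre = np.sort(rng.uniform(0, 0.3, n_pre))
        post = np.sort(rng.uniform(0, 0.3, n_post))
        assert predict_kernel_model(k, pre, post) == pytest.approx(
            brute_force_overlap(k, pre, post), rel=1e-9, abs=1e-12
        )

    def test_bilinear_superposition(self):
        rng = np.random.default_rng(7)
        k = gaussian_kernel()
        a, b = np.sort(rng.uniform(0, 0.5, 4)), np.sort(rng.uniform(0, 0.5, 3))
        post = np.sort(rng.uniform(0, 0.5, 5))
        joint = predict_kernel_model(k, np.sort(np.concatenate([a, b])), post)
        assert joint == pytest.approx(
            predict_kernel_model(k, a, post) + predict_kernel_model(k, b, post),
            rel=1e-9,
        )

    def test_delta_kernel_reduces_to_binned_inner_product(self):
        # 1-bin-wide kernel at 0: overlap = Euclidean inner product of the
        # 1 ms binned spike vectors (spikes aligned to bin centres)
        g = np.arange(-60, 61, 1.0)
        v = np.where(g == 0, 1.0, 0.0) / _envelope(np.array([0.0]))[0]
        k = Kernel(g, v)
        pre = np.array([0.100, 0.200, 0.399])
        post = np.array([0.100, 0.200, 0.350])
        binned_inner_product = 2.0  # bins 100 ms and 200 ms coincide
        assert predict_kernel_model(k, pre, post) == pytest.approx(
            binned_inner_product, rel=1e-9
        )


class TestRemoveOutliers:
    def test_constant_scores_kept(self):
        kept, n = remove_outliers([1, 1, 1, 1])
        assert n == 0 and len(kept) == 4

    def test_single_extreme_value_removed(self):
        scores = [0.0] * 999 + [100.0]
        kept, n = remove_outliers(scores)
        # brute-force check of the rule
        mu, sd = np.mean(scores), np.std(scores)
        assert 100.0 > mu + 4 * sd
        assert n == 1 and len(kept) == 999

    def test_infinite_k_sd_is_identity(self):
        kept, n = remove_outliers([1.0, 5.0, 100.0], k_sd=np.inf)
        assert n == 0 and len(kept) == 3

    def test_requires_two_scores(self):
        with pytest.raises(ValueError):
            remove_outliers([1.0])


class TestFitKernel:
    @staticmethod
    def _synthetic_dataset(kernel, n_rows, seed, noise_frac=0.0, rate=6.0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_rows):
            pre = np.sort(rng.uniform(0, 1, rng.poisson(rate)))
            post = np.sort(rng.uniform(0, 1, rng.poisson(rate)))
            rows.append((i // 150, i % 150, False, pre, post,
                         predict_kernel_model(kernel, pre, post)))
        df = pd.DataFrame(
            rows, columns=["sim", "axon", "matched", "pre", "post_arrivals", "score"]
        )
        if noise_frac:
            df["score"] += rng.normal(0, noise_frac * df["score"].std(), len(df))
        return df

    def test_planted_kernel_recovery_within_10pct_rms(self):
        planted = gaussian_kernel(peak_ms=7, width_ms=6, height=0.02)
        ds = self._synthetic_dataset(planted, 3000, seed=0, noise_frac=0.05)
        fitted, report = fit_kernel(ds, seed=1)
        inside = np.abs(planted.grid) <= 30
        err = fitted(planted.grid[inside]) - planted(planted.grid[inside])
        rms_ratio = np.sqrt(np.mean(err**2)) / np.sqrt(
            np.mean(planted(planted.grid[inside]) ** 2)
        )
        assert rms_ratio < 0.10
        assert report.test_r2 > 0.9

    def test_all_zero_scores_give_zero_kernel_and_flag(self):
        ds = self._synthetic_dataset(gaussian_kernel(height=0.0), 200, seed=2)
        kern, report = fit_kernel(ds, seed=0)
        assert np.all(kern.values == 0)
        assert report.degenerate

    def test_doubling_scores_doubles_the_kernel(self):
        planted = gaussian_kernel(height=0.01)
        ds = self._synthetic_dataset(planted, 800, seed=3, noise_frac=0.0)
        k1, _ = fit_kernel(ds, seed=5)
        ds2 = ds.copy()
        ds2["score"] *= 2
        k2, _ = fit_kernel(ds2, seed=5)
        np.testing.assert_allclose(k2.values, 2 * k1.values, rtol=1e-6, atol=1e-9)

    def test_r2_reported_on_heldout_split(self):
        planted = gaussian_kernel(height=0.01)
        ds = self._synthetic_dataset(planted, 1500, seed=4, noise_frac=0.3)
        _, report = fit_kernel(ds, seed=6, test_fraction=0.2)
        assert report.n_test > 0
        assert report.n_train + report.n_outliers_train + report.n_test \
            + report.n_outliers_test == len(ds)
        # train and test sims are disjoint by construction
        assert 0 <= report.test_r2 <= 1


class TestScoreEnsemble:
    def test_silent_noiseless_ensemble_scores_zero(self, quiet_params, geometry):
        empty = [SpikeTrain(np.empty(0), 1.0) for _ in range(150)]
        from matchcontrol import TrainEnsemble

        ens = TrainEnsemble(empty, None, 1.0)
        soma = sample_poisson_refractory(6, 0.05, 1.0, seed=1)
        scores = score_ensemble(ens, soma, geometry, quiet_params, seed=0)
        assert all(s.raw == 0 for s in scores)

    def test_mismatched_durations_rejected(self, quiet_params, geometry):
        from matchcontrol import TrainEnsemble

        ens = TrainEnsemble([SpikeTrain(np.empty(0), 1.0)] * 150, None, 1.0)
        soma = sample_poisson_refractory(6, 0.05, 2.0, seed=1)
        with pytest.raises(ValueError, match="window"):
            score_ensemble(ens, soma, geometry, quiet_params)

    def test_permutation_equivariance_noiseless(self, quiet_params):
        from matchcontrol import TrainEnsemble, build_geometry

        g = build_geometry(8, 10, n_branches=1, spines_per_branch=80,
                           latency_min=1.0, latency_max=1.0)
        soma = sample_poisson_refractory(6, 0.05, 1.0, seed=2)
        trains = [
            sample_poisson_refractory(6, 0.05, 1.0, seed=10 + i) for i in range(8)
        ]
        perm = [3, 1, 7, 0, 2, 6, 4, 5]
        s1 = score_ensemble(TrainEnsemble(trains, None, 1.0), soma, g,
                            quiet_params, seed=0)
        s2 = score_ensemble(
            TrainEnsemble([trains[i] for i in perm], None, 1.0), soma, g,
            quiet_params, seed=0,
        )
        for j, i in enumerate(perm):
            assert s2[j].raw == pytest.approx(s1[i].raw, rel=1e-6)

    def test_matched_axon_usually_wins(self, params, geometry):
        """The matched axon attains the top score in a clear majority of runs."""
        wins = 0
        n_runs = 30
        for r in range(n_runs):
            soma = sample_poisson_refractory(6, 0.05, 1.0, seed=1000 + r)
            arrivals = SpikeTrain(
                (soma.times + geometry.latency_s(0))[
                    soma.times + geometry.latency_s(0) < 1.0
                ],
                1.0,
            )
            ens = generate_ensemble(
                150, 6, 0.05, 1.0, matched=1, seed=2000 + r,
                matched_arrivals=arrivals,
            )
            scores = [s.raw for s in score_ensemble(ens, soma, geometry, params,
                                                    seed=3000 + r)]
            wins += int(np.argmax(scores) == 0)
        assert wins > n_runs * 0.6


class TestOffsetSweep:
    def test_noiseless_single_rep_is_deterministic(self, quiet_params):
        a = offset_sweep([0, 7], reps=1, params=quiet_params, seed=3)
        b = offset_sweep([0, 7], reps=1, params=quiet_params, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert a.loc[1, "mean_score"] > a.loc[0, "mean_score"]

    def test_far_offset_hits_the_floor(self, quiet_params):
        # far beyond the kernel window only accidental coincidences remain:
        # +100 ms sits at the same floor as -20 ms, well below the peak
        sw = offset_sweep([7, 100], reps=5, params=quiet_params, seed=4)
        peak, far = sw["mean_score"]
        assert far < 0.2 * peak
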