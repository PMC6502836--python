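"""State identification: STaSI, the HMM cross-check, Gaussian peak fits."""

import numpy as np
import pytest

import fretscape as fs
from fretscape.fret import EfficiencyTrace
from fretscape.states import (SegmentPool, _merge_path, _pool_segments,
                              build_histogram, fit_gaussians, mdl_cost)

from oracles import exhaustive_mdl_k


def make_trace(values, mol="m", bin_width=5.0):
    x = np.asarray(values, dtype=float)
    return EfficiencyTrace(mol, bin_width, x, x.copy(), (0.0, len(x) * bin_width))


def two_level_trace(n_per=40, lo=0.6, hi=0.9, reps=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.tile(np.concatenate([np.full(n_per, hi), np.full(n_per, lo)]), reps)
    return make_trace(x + noise * rng.standard_normal(len(x)))


class TestStasi:
    def test_noiseless_two_level_trace_recovered_exactly(self):
        model = fs.stasi_fit([two_level_trace()])
        assert model.n_states == 2
        np.testing.assert_allclose(model.state_efficiencies, [0.9, 0.6],
                                   atol=1e-12)
        # change points exact: assignments flip exactly at the level changes
        a = model.assignments["m"]
        flips = np.flatnonzero(np.diff(a)) + 1
        np.testing.assert_array_equal(flips, np.arange(40, 240, 40))

    def test_constant_trace_gives_single_state(self):
        model = fs.stasi_fit([make_trace(np.full(60, 0.75))])
        assert model.n_states == 1
        assert model.state_efficiencies[0] == pytest.approx(0.75)

    def test_occupancies_equal_time_fraction_and_sum_to_one(self, five_state_stasi):
        model = five_state_stasi
        total = sum(len(a) for a in model.assignments.values())
        counted = np.zeros(model.n_states)
        for a in model.assignments.values():
            counted += np.bincount(a, minlength=model.n_states)
        np.testing.assert_allclose(model.occupancies, counted / total, atol=1e-12)
        assert model.occupancies.sum() == pytest.approx(1.0)

    def test_invariant_under_trace_reordering(self, five_state_traces):
        fwd = fs.stasi_fit(five_state_traces)
        rev = fs.stasi_fit(list(reversed(five_state_traces)))
        assert fwd.n_states == rev.n_states
        np.testing.assert_allclose(fwd.state_efficiencies,
                                   rev.state_efficiencies, atol=1e-12)

    def test_mdl_selected_k_matches_exhaustive_partition_search(self):
        """The greedy merge path's MDL minimum equals the brute-force minimum
        over all contiguous partitions of the segment means."""
        traces = [two_level_trace(noise=0.03, seed=s) for s in range(3)]
        pool = _pool_segments(traces, use_denoised=True, t_threshold=3.0,
                              min_segment=3)
        levels = _merge_path(pool.means, pool.counts)
        greedy_k = min(
            ((k, mdl_cost(pool, *levels[k])) for k in levels),
            key=lambda t: t[1])[0]
        assert greedy_k == exhaustive_mdl_k(pool, mdl_cost)
        assert greedy_k == 2

    def test_mdl_cost_dips_at_true_state_count(self):
        """Across merge levels the description length decreases to the true
        K and increases beyond it (well-separated states)."""
        rng = np.random.default_rng(4)
        traces = []
        for s in range(4):
            seq = np.concatenate([np.full(50, e) for e in (0.9, 0.6, 0.3)])
            traces.append(make_trace(seq + 0.02 * rng.standard_normal(len(seq)),
                                     mol=f"m{s}"))
        pool = _pool_segments(traces, use_denoised=True, t_threshold=3.0,
                              min_segment=3)
        levels = _merge_path(pool.means, pool.counts)
        ks = sorted(k for k in levels if k <= 6)
        costs = [mdl_cost(pool, *levels[k]) for k in ks]
        k_best = ks[int(np.argmin(costs))]
        assert k_best == 3
        # monotone decrease up to the optimum for the visible low-k levels
        below = [c for k, c in zip(ks, costs) if k <= 3]
        assert all(np.diff(below) < 0)


class TestHmm:
    def test_two_level_trace_recovered(self):
        model = fs.hmm_fit([two_level_trace(noise=0.01, seed=1)], seed=0)
        assert model.n_states == 2
        np.testing.assert_allclose(model.state_efficiencies, [0.9, 0.6],
                                   atol=0.01)

    def test_single_state_noise_gives_one_state(self):
        rng = np.random.default_rng(2)
        model = fs.hmm_fit([make_trace(0.8 + 0.05 * rng.standard_normal(400))],
                           seed=0)
        assert model.n_states == 1
        assert model.state_efficiencies[0] == pytest.approx(0.8, abs=0.01)


class TestFitGaussians:
    def _histogram_from_samples(self, samples):
        return build_histogram([make_trace(samples)])

    def test_two_component_mixture_means_recovered(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.89, 0.04, 14000),
                            rng.normal(0.70, 0.04, 6000)])
        res = fit_gaussians(self._histogram_from_samples(x), [0.89, 0.70])
        assert res[0][0] == pytest.approx(0.89, abs=0.005)
        assert res[1][0] == pytest.approx(0.70, abs=0.005)
        assert sum(a for _, _, a in res) == pytest.approx(1.0, abs=0.02)

    def test_single_gaussian_area_is_one(self):
        rng = np.random.default_rng(1)
        res = fit_gaussians(
            self._histogram_from_samples(rng.normal(0.6, 0.05, 20000)), [0.6])
        assert res[0][2] == pytest.approx(1.0, abs=0.01)

    def test_narrower_input_gives_smaller_fwhm(self):
        rng = np.random.default_rng(2)
        fwhm = []
        for sigma in (0.06, 0.03):
            res = fit_gaussians(
                self._histogram_from_samples(rng.normal(0.7, sigma, 20000)),
                [0.7])
            fwhm.append(res[0][1])
        assert fwhm[1] < fwhm[0]

    def test_histogram_fractions_sum_to_one(self, five_state_traces):
        _, frac = build_histogram(five_state_traces)
        assert frac.sum() == pytest.approx(1.0)
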