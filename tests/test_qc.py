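"""Molecule selection: step detection, anticorrelation, acceptance logic."""

import numpy as np
import pytest

import fretscape as fs
from fretscape.qc import check_anticorrelation, detect_bleach_steps, select_molecule
from fretscape.sim import SimConfig
from fretscape.presets import stoichiometry_ensemble_config

from oracles import exhaustive_change_points


def _trace(donor, acceptor, direct=None, mol="m"):
    return fs.PhotonTrace(mol, 1.0, np.asarray(donor), np.asarray(acceptor),
                          None if direct is None else np.asarray(direct))


class TestDetectBleachSteps:
    def test_two_noiseless_steps_found_exactly(self):
        x = np.concatenate([np.full(50, 100.0), np.full(50, 50.0),
                            np.full(50, 0.0)])
        n, times = detect_bleach_steps(x)
        assert n == 2
        np.testing.assert_array_equal(times, [50.0, 100.0])

    def test_constant_series_has_no_steps(self):
        n, times = detect_bleach_steps(np.full(100, 42.0))
        assert n == 0 and times.size == 0

    def test_upward_change_not_counted_as_bleach(self):
        x = np.concatenate([np.full(50, 20.0), np.full(50, 60.0),
                            np.full(50, 5.0)])
        n, times = detect_bleach_steps(x)
        assert n == 1
        np.testing.assert_array_equal(times, [100.0])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            detect_bleach_steps(np.ones(10))

    def test_poisson_two_step_channel_count_and_times(self):
        """Two-fluorophore channel with Poisson noise: step count right in
        >= 95% of trials, detected times within +-10 ms of truth."""
        rng = np.random.default_rng(17)
        ok = 0
        for _ in range(200):
            t1, t2 = sorted(rng.uniform(100, 1900, size=2))
            means = np.full(2000, 2.0)
            means[: int(t2)] += 50.0
            means[: int(t1)] += 50.0
            n, times = detect_bleach_steps(rng.poisson(means))
            if n == 2 and abs(times[0] - int(t1)) <= 10 and abs(times[1] - int(t2)) <= 10:
                ok += 1
        assert ok / 200 >= 0.95

    def test_noiseless_change_points_match_exhaustive_oracle(self):
        """On noiseless piecewise-constant input the detected boundaries are
        exactly the brute-force segmentation."""
        x = np.concatenate([np.full(40, 80.0), np.full(55, 30.0),
                            np.full(60, 55.0), np.full(45, 10.0)])
        n, times = detect_bleach_steps(x)
        oracle = exhaustive_change_points(x)
        down = [c for c in oracle if x[c] < x[c - 1]]
        np.testing.assert_array_equal(times.astype(int), down)


class TestAnticorrelation:
    def test_perfect_two_level_pair_is_minus_one(self):
        d = np.tile([10.0, 40.0], 50)
        a = 50.0 - d
        r = check_anticorrelation(_trace(d, a), (0.0, 100.0))
        assert r == pytest.approx(-1.0)

    def test_independent_poisson_channels_near_zero(self):
        rng = np.random.default_rng(3)
        tr = _trace(rng.poisson(30, 10_000), rng.poisson(30, 10_000))
        assert abs(check_anticorrelation(tr, (0.0, 10_000.0))) < 0.2

    def test_dynamic_fret_trace_strongly_anticorrelated(self):
        cfg = SimConfig(state_efficiencies=(0.9, 0.5),
                        rate_matrix=np.array([[-0.02, 0.02], [0.02, -0.02]]),
                        bleach_rate_donor=0.0, bleach_rate_acceptor=0.0,
                        stoichiometry_weights=(0.0, 1.0, 0.0, 0.0),
                        duration=5_000.0)
        trace, _ = fs.simulate_trace(cfg, seed=8)
        assert check_anticorrelation(trace, (0.0, 5_000.0)) < -0.5

    def test_zero_variance_channel_flagged_nan(self):
        tr = _trace(np.full(100, 5.0), np.arange(100.0))
        assert np.isnan(check_anticorrelation(tr, (0.0, 100.0)))


class TestSelectMolecule:
    def test_single_pair_accepted_with_region_to_first_bleach(self):
        cfg = SimConfig(state_efficiencies=(0.85,),
                        stoichiometry_weights=(0.0, 1.0, 0.0, 0.0))
        for seed in range(6):
            trace, gt = fs.simulate_trace(cfg, seed=seed)
            rep = select_molecule(trace)
            if rep.accepted:
                assert rep.donor_steps == 1 and rep.acceptor_steps == 1
                assert rep.fret_region[1] == pytest.approx(
                    gt.fret_region_end, abs=10.0)
                break
        else:
            pytest.fail("no molecule accepted across seeds")

    def test_two_acceptor_molecule_rejected(self):
        rng = np.random.default_rng(5)
        n = 3000
        donor = np.full(n, 2.0)
        donor[:2500] += 10.0        # single donor bleaching at 2500 ms
        acceptor = np.full(n, 2.0)
        acceptor[:2500] += 38.0
        direct = np.full(n, 2.0)
        direct[:2000] += 50.0       # two acceptors bleach at 1000 and 2000 ms
        direct[:1000] += 50.0
        rep = select_molecule(_trace(rng.poisson(donor), rng.poisson(acceptor),
                                     rng.poisson(direct)))
        assert not rep.accepted
        assert rep.reject_reason == "multiple_acceptor_steps"

    def test_acceptance_fraction_matches_two_step_weight(self):
        """Mixed-stoichiometry ensemble: acceptance fraction tracks the
        two-fluorophore weight within binomial error."""
        n = 200
        accepted = sum(
            select_molecule(t).accepted
            for t, _ in fs.simulate_dataset(stoichiometry_ensemble_config(),
                                            n, seed=29))
        p = 0.35
        assert abs(accepted / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_acceptance_invariant_to_uniform_intensity_scaling(self):
        base_d = np.concatenate([np.full(600, 12.0), np.full(600, 60.0),
                                 np.full(300, 2.0)])
        base_a = np.concatenate([np.full(600, 50.0), np.full(600, 2.0),
                                 np.full(300, 2.0)])
        direct = np.concatenate([np.full(600, 52.0), np.full(900, 2.0)])
        r1 = select_molecule(_trace(base_d, base_a, direct))
        r2 = select_molecule(_trace(4 * base_d, 4 * base_a, 4 * direct))
        assert r1.accepted == r2.accepted
        assert (r1.donor_steps, r1.acceptor_steps) == \
               (r2.donor_steps, r2.acceptor_steps)
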