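"""Distances, transition maps, free energies, activation barriers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fretscape as fs
from fretscape.landscape import (activation_energies, build_landscape,
                                 count_transitions, distance_table,
                                 distance_to_efficiency, efficiency_to_distance,
                                 state_free_energies)


class TestDistanceConversion:
    def test_half_efficiency_gives_forster_radius(self):
        assert efficiency_to_distance(0.5, R0=51.0) == pytest.approx(51.0)

    @given(E=st.floats(0.01, 0.99), R0=st.floats(10.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_is_identity(self, E, R0):
        assert distance_to_efficiency(
            efficiency_to_distance(E, R0), R0) == pytest.approx(E, abs=1e-12)

    def test_distance_strictly_decreasing_in_efficiency(self):
        E = np.linspace(0.05, 0.95, 50)
        R = efficiency_to_distance(E, R0=51.0)
        assert (np.diff(R) < 0).all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_domain_error_outside_open_interval(self, bad):
        with pytest.raises(ValueError):
            efficiency_to_distance(bad)

    def test_distance_table_rounds_to_integer_angstrom(self):
        df = distance_table([0.89, 0.5], R0=51.0)
        assert df.distance_A_rounded.tolist() == [36, 51]


class TestCountTransitions:
    def test_hand_counted_sequence(self):
        counts, probs = count_transitions({"m": np.array([0, 0, 1, 1, 0])}, 2)
        np.testing.assert_array_equal(counts, [[0, 1], [1, 0]])
        assert probs[0, 1] == pytest.approx(1 / 3)  # 3 bins spent in state 0
        assert probs[1, 0] == pytest.approx(1 / 2)

    def test_no_transition_across_molecule_boundary(self):
        a = {"m1": np.array([0, 0, 1]), "m2": np.array([0, 1, 1])}
        counts, _ = count_transitions(a, 2)
        merged, _ = count_transitions(
            {"m": np.concatenate([a["m1"], a["m2"]])}, 2)
        np.testing.assert_array_equal(counts, [[0, 2], [0, 0]])
        assert merged[1, 0] == 1  # concatenation invents a boundary transition

    def test_additivity_over_molecules(self):
        a1 = {"m1": np.array([0, 1, 2, 1])}
        a2 = {"m2": np.array([2, 2, 0])}
        c1, _ = count_transitions(a1, 3)
        c2, _ = count_transitions(a2, 3)
        both, _ = count_transitions({**a1, **a2}, 3)
        np.testing.assert_array_equal(both, c1 + c2)

    def test_single_state_model_gives_empty_map(self):
        counts, probs = count_transitions({"m": np.zeros(10, dtype=int)}, 1)
        assert counts.sum() == 0 and probs.sum() == 0


class TestFreeEnergies:
    def test_equal_populations_are_degenerate(self):
        np.testing.assert_allclose(state_free_energies([0.5, 0.5]), [0.0, 0.0],
                                   atol=1e-15)

    def test_hand_evaluated_three_state_ladder(self):
        dg = state_free_energies([0.6, 0.3, 0.1])
        np.testing.assert_allclose(dg, [0.0, np.log(2.0), np.log(6.0)],
                                   atol=1e-12)

    def test_single_state_is_reference(self):
        np.testing.assert_array_equal(state_free_energies([1.0]), [0.0])

    def test_unvisited_state_flagged_infinite(self):
        dg = state_free_energies([0.7, 0.3, 0.0])
        assert np.isinf(dg[2]) and np.isfinite(dg[:2]).all()

    def test_ordering_reverses_occupancy_ordering(self):
        occ = np.array([0.4, 0.1, 0.3, 0.2])
        dg = state_free_energies(occ)
        np.testing.assert_array_equal(np.argsort(dg), np.argsort(-occ))


class TestActivationEnergies:
    def test_hand_evaluated_barrier(self):
        p = np.array([[0.0, 0.05], [0.05, 0.0]])
        Ea, Ea_sym = activation_energies(p, bin_width=5.0, A=10.0)
        assert Ea[0, 1] == pytest.approx(np.log(1000.0), abs=1e-12)
        assert Ea_sym[0, 1] == pytest.approx(np.log(1000.0), abs=1e-12)

    def test_rate_equal_to_preexponential_gives_zero_barrier(self):
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        Ea, _ = activation_energies(p, bin_width=0.1, A=10.0)
        assert Ea[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_halving_probability_adds_ln2(self):
        p1 = np.array([[0.0, 0.04], [0.04, 0.0]])
        Ea1, _ = activation_energies(p1, 5.0, 10.0)
        Ea2, _ = activation_energies(p1 / 2, 5.0, 10.0)
        assert Ea2[0, 1] - Ea1[0, 1] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_unobserved_transition_omitted_from_symmetrized(self):
        p = np.array([[0.0, 0.0], [0.05, 0.0]])
        Ea, Ea_sym = activation_energies(p, 5.0, 10.0)
        assert np.isinf(Ea[0, 1]) and np.isfinite(Ea[1, 0])
        assert np.isnan(Ea_sym[0, 1]) and np.isnan(Ea_sym[1, 0])


class TestLandscapeAssembly:
    def test_nearest_neighbor_chain_transitions_mostly_adjacent(
            self, five_state_stasi):
        """With only nearest-neighbor rates in the generator, the fitted
        transition map is dominated by adjacent-state transitions."""
        model = five_state_stasi
        counts, _ = count_transitions(model.assignments, model.n_states)
        adjacent = sum(counts[i, j] for i in range(model.n_states)
                       for j in range(model.n_states) if abs(i - j) == 1)
        assert counts.sum() > 50
        assert adjacent / counts.sum() >= 0.9

    def test_reference_state_zero_and_rest_positive(self, five_state_stasi):
        scape = build_landscape(five_state_stasi, bin_width=5.0)
        assert scape.delta_G.min() == 0.0
        assert (scape.delta_G >= 0.0).all()
        assert (np.diag(scape.transition_counts) == 0).all()

    def test_recovered_barriers_track_simulated_rate_ordering(
            self, five_state_stasi):
        """Adjacent transitions (fast in the generator) have lower barriers
        than the rarely observed skip transitions."""
        scape = build_landscape(five_state_stasi, bin_width=5.0)
        k = scape.Ea.shape[0]
        adj = [scape.Ea[i, j] for i in range(k) for j in range(k)
               if abs(i - j) == 1 and np.isfinite(scape.Ea[i, j])]
        skip = [scape.Ea[i, j] for i in range(k) for j in range(k)
                if abs(i - j) > 1 and np.isfinite(scape.Ea[i, j])]
        assert np.mean(adj) < (np.mean(skip) if skip else np.inf)
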