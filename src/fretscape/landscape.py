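"""Physical observables from a state model.

Converts state efficiencies to inter-fluorophore distances through the
Förster relation E = 1/(1 + (R/R0)^6), counts bin-to-bin transitions within
molecules into a transition map, and turns occupancies and transition
probabilities into a free-energy diagram: standard free energies
dG_i = -kBT ln(p_i/p_max) referenced to the most populated state, and
Arrhenius activation barriers Ea = -kBT ln(k/A) from first-order rates
k = p/dt with an assumed attempt frequency A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EnergyLandscape", "efficiency_to_distance", "distance_to_efficiency",
           "distance_table", "count_transitions", "state_free_energies",
           "activation_energies", "build_landscape", "KBT_KCAL_PER_MOL_298K"]

DEFAULT_R0 = 51.0          # Å; reproduces every reported (E, distance) pair
DEFAULT_PREEXPONENTIAL = 10.0   # ms^-1 attempt frequency for Arrhenius barriers
KBT_KCAL_PER_MOL_298K = 0.592485  # 1 kBT at 298 K in kcal/mol


def efficiency_to_distance(E, R0: float = DEFAULT_R0):
    """Donor-acceptor distance in Å from FRET efficiency.

    R = R0 * (1/E - 1)^(1/6).  E must lie strictly in (0, 1); the return
    value is unrounded (report tables round to the nearest Å).
    Accepts scalars or arrays.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0.0) or np.any(E >= 1.0):
        raise ValueError("efficiency must lie strictly inside (0, 1)")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    R = R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)
    return float(R) if R.ndim == 0 else R


def distance_to_efficiency(R, R0: float = DEFAULT_R0):
    """Inverse of :func:`efficiency_to_distance`: E = 1/(1 + (R/R0)^6)."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0.0) or R0 <= 0:
        raise ValueError("distances and R0 must be positive")
    E = 1.0 / (1.0 + (R / R0) ** 6)
    return float(E) if E.ndim == 0 else E


def distance_table(state_efficiencies, R0: float = DEFAULT_R0) -> pd.DataFrame:
    """Per-state distance table: E, R0, exact and nearest-Å distances."""
    effs = np.asarray(state_efficiencies, dtype=float)
    R = efficiency_to_distance(effs, R0)
    R = np.atleast_1d(R)
    return pd.DataFrame({
        "state": np.arange(len(effs)),
        "efficiency": np.round(effs, 6),
        "R0_A": R0,
        "distance_A": np.round(R, 3),
        "distance_A_rounded": np.round(R).astype(int),
    })


def count_transitions(assignments: dict[str, np.ndarray], n_states: int):
    """Bin-to-bin transition counts and per-bin transition probabilities.

    Transitions are counted within molecules only; molecule boundaries never
    contribute.  ``counts[i, j]`` is the number of i->j changes (diagonal 0);
    ``probs[i, j] = counts[i, j] / total bins spent in state i``, the per-bin
    probability of leaving i for j.  A single-state model yields empty
    (all-zero) maps, which is valid.
    """
    counts = np.zeros((n_states, n_states), dtype=int)
    bins_in_state = np.zeros(n_states, dtype=float)
    for a in assignments.values():
        a = np.asarray(a, dtype=int)
        if a.size == 0:
            continue
        bins_in_state += np.bincount(a, minlength=n_states)
        if a.size > 1:
            src, dst = a[:-1], a[1:]
            moved = src != dst
            np.add.at(counts, (src[moved], dst[moved]), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = np.where(bins_in_state[:, None] > 0,
                         counts / np.maximum(bins_in_state[:, None], 1e-300), 0.0)
    return counts, probs


def state_free_energies(occupancies) -> np.ndarray:
    """Standard free energies dG_i = -ln(p_i / p_max) in kBT units.

    The most populated state is the zero reference, so all values are >= 0.
    Zero-occupancy (unvisited) states get +inf.
    """
    p = np.asarray(occupancies, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("occupancies must sum to 1")
    if np.any(p < 0):
        raise ValueError("occupancies must be non-negative")
    pmax = p.max()
    with np.errstate(divide="ignore"):
        return -np.log(p / pmax)


def activation_energies(transition_probs: np.ndarray, bin_width: float = 5.0,
                        A: float = DEFAULT_PREEXPONENTIAL,
                        use_log_rate: bool = False):
    """Arrhenius barriers per ordered state pair, in kBT units.

    First-order rates k_ij = p_ij / bin_width (or ``-ln(1-p)/bin_width`` with
    ``use_log_rate``), then Ea_ij = -ln(k_ij / A).  Unobserved transitions
    (p = 0) get Ea = +inf and are omitted (NaN) from the symmetrized output
    ``(Ea_ij + Ea_ji) / 2``.  Diagonals are NaN.
    """
    if bin_width <= 0 or A <= 0:
        raise ValueError("bin_width and A must be positive")
    p = np.asarray(transition_probs, dtype=float)
    with np.errstate(divide="ignore"):
        if use_log_rate:
            k = -np.log1p(-p) / bin_width
        else:
            k = p / bin_width
        Ea = np.where(k > 0, -np.log(k / A), np.inf)
    np.fill_diagonal(Ea, np.nan)
    both = np.isfinite(Ea) & np.isfinite(Ea.T)
    Ea_sym = np.where(both, (Ea + Ea.T) / 2.0, np.nan)
    return Ea, Ea_sym


@dataclass
class EnergyLandscape:
    """Free-energy landscape of one condition, energies in kBT."""

    delta_G: np.ndarray            # per state; reference (most populated) = 0
    K_eq: np.ndarray               # pairwise occupancy ratios p_j / p_i
    transition_counts: np.ndarray
    transition_probs: np.ndarray
    rates: np.ndarray              # ms^-1
    Ea: np.ndarray
    Ea_symmetrized: np.ndarray
    pre_exponential_A: float
    bin_width: float

    def __post_init__(self):
        finite = np.isfinite(self.delta_G)
        if not np.any(finite) or abs(self.delta_G[finite].min()) > 1e-12:
            raise ValueError("reference state must have delta_G exactly 0")
        if np.any(self.delta_G[finite] < -1e-12):
            raise ValueError("delta_G must be >= 0 relative to the most "
                             "populated state")
        if np.any(np.diag(self.transition_counts) != 0):
            raise ValueError("transition count diagonal must be zero")

    def delta_G_kcal_per_mol(self, kBT_kcal: float = KBT_KCAL_PER_MOL_298K):
        """Convenience conversion of dG to kcal/mol (default 298 K)."""
        return self.delta_G * kBT_kcal


def build_landscape(state_model, bin_width: float | None = None,
                    A: float = DEFAULT_PREEXPONENTIAL,
                    use_log_rate: bool = False) -> EnergyLandscape:
    """Assemble the full landscape from a fitted state model."""
    occ = np.asarray(state_model.occupancies, dtype=float)
    counts, probs = count_transitions(state_model.assignments,
                                      state_model.n_states)
    if bin_width is None:
        bin_width = 5.0
    with np.errstate(divide="ignore", invalid="ignore"):
        K_eq = occ[None, :] / np.maximum(occ[:, None], 1e-300)
    rates = probs / bin_width
    Ea, Ea_sym = activation_energies(probs, bin_width=bin_width, A=A,
                                     use_log_rate=use_log_rate)
    return EnergyLandscape(
        delta_G=state_free_energies(occ), K_eq=K_eq,
        transition_counts=counts, transition_probs=probs, rates=rates,
        Ea=Ea, Ea_symmetrized=Ea_sym, pre_exponential_A=A,
        bin_width=bin_width)
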