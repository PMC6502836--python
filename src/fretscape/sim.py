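"""Synthetic two-channel smFRET photon-trace generator.

Emulates the statistical structure of single-molecule FRET acquisitions on
surface-isolated receptors: a continuous-time Markov chain over discrete
conformational states, Poisson photon emission partitioned between donor and
acceptor channels by the state's transfer efficiency, exponential
photobleaching of each fluorophore, and a labeling-stoichiometry mixture in
which only the one-donor/one-acceptor molecules are analyzable.

Ground truth (state path, bleach times, stoichiometry) is retained alongside
every trace so that downstream stages can be tested as parameter-recovery
problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import PhotonTrace

__all__ = ["SimConfig", "GroundTruth", "simulate_trace", "simulate_dataset",
           "stationary_distribution", "load_sim_config"]

#: bleach-step mixture printed for the receptor datasets: probability that a
#: molecule carries 1, 2, 3 or 4 fluorophores (5% / 35% / 50% / 10%).
DEFAULT_STOICHIOMETRY = (0.05, 0.35, 0.50, 0.10)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one experimental condition.

    Parameters
    ----------
    state_efficiencies
        True FRET efficiency of each conformational state, each strictly in
        (0, 1).
    rate_matrix
        K x K generator of the conformational Markov chain, in ms^-1.
        Off-diagonals are transition rates; each diagonal equals minus its
        row sum.  A single-state condition uses the 1 x 1 zero matrix.
    total_intensity
        Mean photons emitted per donor fluorophore per 1 ms bin (before
        partitioning between channels).
    background
        Mean background counts per channel per 1 ms bin.
    bleach_rate_donor, bleach_rate_acceptor
        Exponential photobleach hazard per fluorophore, ms^-1.  Defaults give
        FRETing regions averaging ~1.7 s, inside the 1-3 s range typical for
        these acquisitions, with the red dye bleaching faster than the green.
    stoichiometry_weights
        Probability that a molecule carries 1, 2, 3 or 4 fluorophores.
    duration
        Trace length in ms.
    bin_width
        Acquisition bin width in ms (native resolution 1 ms).
    direct_intensity
        Mean counts per alive acceptor per bin in the direct
        acceptor-excitation channel (label-verification channel only).
    """

    state_efficiencies: tuple[float, ...] = (0.89,)
    rate_matrix: np.ndarray | None = None
    total_intensity: float = 50.0
    background: float = 2.0
    bleach_rate_donor: float = 2.0e-4
    bleach_rate_acceptor: float = 4.0e-4
    stoichiometry_weights: tuple[float, float, float, float] = DEFAULT_STOICHIOMETRY
    duration: float = 20000.0
    bin_width: float = 1.0
    direct_intensity: float = 50.0
    seed: int = 0

    def __post_init__(self):
        effs = np.asarray(self.state_efficiencies, dtype=float)
        if effs.ndim != 1 or effs.size == 0:
            raise ValueError("state_efficiencies must be a non-empty 1-D sequence")
        if np.any(effs <= 0.0) or np.any(effs >= 1.0):
            raise ValueError("state efficiencies must lie strictly inside (0, 1)")
        Q = self.rate_matrix
        if Q is None:
            Q = np.zeros((effs.size, effs.size))
            object.__setattr__(self, "rate_matrix", Q)
        Q = np.asarray(Q, dtype=float)
        object.__setattr__(self, "rate_matrix", Q)
        if Q.shape != (effs.size, effs.size):
            raise ValueError("rate_matrix shape must match the number of states")
        if not np.all(np.isfinite(Q)):
            raise ValueError("rate_matrix contains non-finite entries")
        off = Q[~np.eye(effs.size, dtype=bool)]
        if np.any(off < 0.0):
            raise ValueError("rate_matrix off-diagonal rates must be >= 0")
        if not np.allclose(np.diag(Q), -(Q.sum(axis=1) - np.diag(Q)), atol=1e-10):
            raise ValueError("rate_matrix diagonal must equal minus the row sum "
                             "of off-diagonal rates")
        w = np.asarray(self.stoichiometry_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("stoichiometry_weights must be 4 non-negative "
                             "probabilities summing to 1")
        for name in ("total_intensity", "background", "bleach_rate_donor",
                     "bleach_rate_acceptor", "duration", "bin_width",
                     "direct_intensity"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.duration <= 0 or self.bin_width <= 0:
            raise ValueError("duration and bin_width must be positive")

    @property
    def n_states(self) -> int:
        return len(self.state_efficiencies)


@dataclass
class GroundTruth:
    """True generative quantities retained for parameter-recovery tests."""

    state_path: np.ndarray            # per-bin true state index (state at bin midpoint)
    bleach_times_donor: np.ndarray    # ms, one entry per donor fluorophore
    bleach_times_acceptor: np.ndarray # ms, one entry per acceptor fluorophore
    n_donors: int
    n_acceptors: int
    jump_times: np.ndarray            # CTMC event times (ms), starting at 0
    jump_states: np.ndarray           # state after each event

    @property
    def fret_region_end(self) -> float:
        """End of the FRETing region: the first bleach event in either channel (ms)."""
        times = np.concatenate([self.bleach_times_donor, self.bleach_times_acceptor])
        return float(times.min()) if times.size else 0.0


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution pi of a CTMC generator (pi Q = 0, pi >= 0, sum 1)."""
    Q = np.asarray(rate_matrix, dtype=float)
    k = Q.shape[0]
    if k == 1:
        return np.ones(1)
    # solve pi Q = 0 with the normalization row appended
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _sample_ctmc(Q: np.ndarray, duration: float, rng: np.random.Generator):
    """Gillespie path: event times (starting at 0) and the state after each."""
    k = Q.shape[0]
    pi = stationary_distribution(Q)
    state = int(rng.choice(k, p=pi))
    times = [0.0]
    states = [state]
    t = 0.0
    exit_rates = -np.diag(Q)
    while True:
        rate = exit_rates[state]
        if rate <= 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(k, p=probs))
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=int)


def _binned_mean_efficiency(jump_times, jump_states, effs, n_bins, bin_width):
    """Time-weighted mean state efficiency within each acquisition bin."""
    e = np.zeros(n_bins)
    bounds = np.append(jump_times, n_bins * bin_width)
    for i in range(len(jump_states)):
        t0, t1 = bounds[i], bounds[i + 1]
        if t1 <= t0:
            continue
        b0 = int(t0 // bin_width)
        b1 = min(int(np.ceil(t1 / bin_width)), n_bins)
        for b in range(b0, b1):
            lo = max(t0, b * bin_width)
            hi = min(t1, (b + 1) * bin_width)
            if hi > lo:
                e[b] += (hi - lo) / bin_width * effs[jump_states[i]]
    return e


def _alive_fraction(bleach_times, n_bins, bin_width):
    """Per-bin alive fraction for each fluorophore, shape (n_fluor, n_bins)."""
    starts = np.arange(n_bins) * bin_width
    tb = np.asarray(bleach_times)[:, None]
    return np.clip((tb - starts[None, :]) / bin_width, 0.0, 1.0)


def simulate_trace(config: SimConfig, seed: int,
                   molecule_id: str = "mol") -> tuple[PhotonTrace, GroundTruth]:
    """Simulate one molecule's two-channel photon trace.

    The molecule draws a fluorophore count from ``stoichiometry_weights``;
    a count of ``k`` is realized as ``ceil(k/2)`` donors and ``floor(k/2)``
    acceptors, so two-fluorophore molecules are exactly the analyzable
    donor/acceptor pairs.  While at least one acceptor is alive, each alive
    donor's photons are partitioned by the current state's efficiency between
    the donor and acceptor channels; after the last acceptor bleaches all
    donor-excitation photons route to the donor channel; after all donors
    bleach both FRET channels carry background only.  Identical seeds yield
    identical traces.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(config.duration // config.bin_width)
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")

    k_fluor = 1 + int(rng.choice(4, p=np.asarray(config.stoichiometry_weights)))
    n_don = (k_fluor + 1) // 2
    n_acc = k_fluor // 2

    def _bleach(rate, n):
        if n == 0:
            return np.empty(0)
        if rate <= 0.0:
            return np.full(n, np.inf)
        return rng.exponential(1.0 / rate, size=n)

    t_don = _bleach(config.bleach_rate_donor, n_don)
    t_acc = _bleach(config.bleach_rate_acceptor, n_acc)

    jump_times, jump_states = _sample_ctmc(config.rate_matrix, config.duration, rng)
    effs = np.asarray(config.state_efficiencies)
    e_bin = _binned_mean_efficiency(jump_times, jump_states, effs,
                                    n_bins, config.bin_width)
    # true state at bin midpoints, for ground-truth comparisons
    mids = (np.arange(n_bins) + 0.5) * config.bin_width
    state_path = jump_states[np.searchsorted(jump_times, mids, side="right") - 1]

    don_alive = _alive_fraction(t_don, n_bins, config.bin_width)  # (n_don, n_bins)
    acc_alive = _alive_fraction(t_acc, n_bins, config.bin_width)
    donor_emitting = don_alive.sum(axis=0)
    # FRET is on while any acceptor is alive: fraction of the bin before the
    # last acceptor bleach
    fret_on = acc_alive.max(axis=0) if n_acc else np.zeros(n_bins)
    e_eff = e_bin * fret_on

    mean_donor = config.total_intensity * donor_emitting * (1.0 - e_eff) + config.background
    mean_acceptor = config.total_intensity * donor_emitting * e_eff + config.background
    mean_direct = config.direct_intensity * acc_alive.sum(axis=0) + config.background

    trace = PhotonTrace(
        molecule_id=molecule_id,
        bin_width=config.bin_width,
        donor=rng.poisson(mean_donor),
        acceptor=rng.poisson(mean_acceptor),
        acceptor_direct=rng.poisson(mean_direct),
        provenance=f"simulated seed={seed} n_states={config.n_states}",
    )
    truth = GroundTruth(
        state_path=state_path,
        bleach_times_donor=t_don,
        bleach_times_acceptor=t_acc,
        n_donors=n_don,
        n_acceptors=n_acc,
        jump_times=jump_times,
        jump_states=jump_states,
    )
    return trace, truth


def simulate_dataset(config: SimConfig, n_molecules: int, seed: int,
                     out_dir=None, condition: str = "sim"):
    """Simulate ``n_molecules`` traces with per-molecule seeds derived from
    ``seed``.  If ``out_dir`` is given, traces and a manifest are written in
    the package's TSV trace format.

    Returns a list of ``(PhotonTrace, GroundTruth)`` pairs.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_molecules)
    out = []
    for i, s in enumerate(child_seeds):
        mol_id = f"{condition}_{i:04d}"
        out.append(simulate_trace(config, int(s), molecule_id=mol_id))
    if out_dir is not None:
        from .io import write_traces
        write_traces([t for t, _ in out], out_dir, condition=condition)
    return out


def load_sim_config(path) -> SimConfig:
    """Parse a ``key = value`` text config into a :class:`SimConfig`.

    Lists are comma-separated; ``rate_matrix`` rows are separated by ``;``.
    Lines starting with ``#`` are comments.
    """
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = line.split("=", 1)
            raw[key.strip()] = val.strip()

    kwargs: dict = {}
    if "state_efficiencies" in raw:
        kwargs["state_efficiencies"] = tuple(
            float(v) for v in raw.pop("state_efficiencies").split(","))
    if "rate_matrix" in raw:
        rows = [r for r in raw.pop("rate_matrix").split(";") if r.strip()]
        kwargs["rate_matrix"] = np.array(
            [[float(v) for v in r.split(",")] for r in rows])
    if "stoichiometry_weights" in raw:
        kwargs["stoichiometry_weights"] = tuple(
            float(v) for v in raw.pop("stoichiometry_weights").split(","))
    if "seed" in raw:
        kwargs["seed"] = int(raw.pop("seed"))
    for key, val in raw.items():
        kwargs[key] = float(val)
    return SimConfig(**kwargs)
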