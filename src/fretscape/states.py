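"""Conformational-state identification from efficiency time series.

Two independent routes, mirroring standard smFRET practice:

* **STaSI** (step transition and state identification): recursive t-test
  change-point splitting segments each denoised trace into constant levels;
  candidate state sets are formed by hierarchically merging nearest segment
  means across all molecules of a condition; the state count minimizing a
  minimum-description-length cost is selected.
* **Gaussian-emission HMM** fit on the *raw* (undenoised) efficiencies with
  multiple EM restarts and BIC model selection — an algorithmically unrelated
  cross-check that also validates the denoising.

States are fit globally across all molecules of a condition, matching pooled
histograms; per-molecule assignments are retained for transition counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .changepoint import find_change_points, segment_means
from .fret import EfficiencyTrace

__all__ = ["StateModel", "stasi_fit", "hmm_fit", "fit_gaussians",
           "build_histogram", "mdl_cost", "SegmentPool"]

MIN_STATE_SEPARATION = 0.03
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

HIST_BIN_WIDTH = 0.01
HIST_RANGE = (0.0, 1.05)


@dataclass
class StateModel:
    """A global state set with per-molecule, per-bin assignments."""

    n_states: int
    state_efficiencies: np.ndarray   # sorted descending
    state_halfwidths: np.ndarray     # Gaussian FWHM per state
    assignments: dict[str, np.ndarray]
    occupancies: np.ndarray          # fraction of bins per state, sums to 1
    method: str                      # "stasi" | "hmm"
    converged: bool = True

    def __post_init__(self):
        occ = np.asarray(self.occupancies, dtype=float)
        if not np.isclose(occ.sum(), 1.0, atol=1e-8):
            raise ValueError("occupancies must sum to 1")
        for mol, a in self.assignments.items():
            if a.size and (a.min() < 0 or a.max() >= self.n_states):
                raise ValueError(f"{mol}: assignment references invalid state")


# ---------------------------------------------------------------------------
# STaSI
# ---------------------------------------------------------------------------

@dataclass
class SegmentPool:
    """Pooled constant segments from all molecules, with sufficient statistics.

    ``means``/``counts``/``ss_within`` are computed on the *raw* series over
    each segment's trimmed interior (boundary bins of interior segments hold
    a mixture of the flanking states because transitions fall mid-bin, so
    they are excluded from the fit statistics), which lets the fit cost of
    any grouping of segments be evaluated without touching the series again.
    """

    molecule_ids: list[str]
    seg_molecule: np.ndarray   # index into molecule_ids per segment
    seg_start: np.ndarray      # untrimmed bounds, used for assignments
    seg_end: np.ndarray
    means: np.ndarray
    counts: np.ndarray         # trimmed interior size entering the fit term
    ss_within: np.ndarray
    sigma: float               # pooled noise scale of the raw data
    n_bins: int                # total points entering the fit term
    n_change_points: int

    @property
    def n_segments(self) -> int:
        return len(self.means)


BOUNDARY_TRIM_BINS = 1


def _pool_segments(traces, use_denoised, t_threshold, min_segment) -> SegmentPool:
    """Segment every trace and pool trimmed raw-series segment statistics.

    Change points are always searched on the raw series — wavelet smoothing
    suppresses dwells shorter than its coarsest scale, and every missed dwell
    becomes a mixed segment whose mean sits between states.  With
    ``use_denoised`` the denoised series is scanned as well and the union of
    change points is kept; extra splits are harmless because segments are
    re-merged during state clustering.
    """
    mol_ids, seg_mol, starts, ends, means, counts, ss = [], [], [], [], [], [], []
    finest_details = []
    for trace in traces:
        d = np.diff(trace.raw_efficiency)
        if d.size:
            finest_details.append(d)
    # pooled noise sigma of the raw efficiencies from finest-scale differences
    d = np.concatenate(finest_details) if finest_details else np.zeros(1)
    sigma = float(np.median(np.abs(d)) / 0.6745 / np.sqrt(2.0))

    n_cp = 0
    n_fit = 0
    for trace in traces:
        x_raw = trace.raw_efficiency
        cps = find_change_points(x_raw, sigma=sigma, t_threshold=t_threshold,
                                 min_segment=min_segment)
        if use_denoised:
            cps_den = find_change_points(trace.denoised_efficiency, sigma=sigma,
                                         t_threshold=t_threshold,
                                         min_segment=min_segment)
            # union, but never let an added change point create a segment
            # shorter than min_segment
            merged = list(cps)
            for c in cps_den:
                anchors = np.concatenate([[0], merged, [len(x_raw)]])
                if np.min(np.abs(anchors - c)) >= min_segment:
                    merged.append(int(c))
                    merged.sort()
            cps = np.asarray(merged, dtype=int)
        n_cp += len(cps)
        mol_ids.append(trace.molecule_id)
        for s, e, _, n in segment_means(x_raw, cps):
            s2 = s + BOUNDARY_TRIM_BINS if s > 0 else s
            e2 = e - BOUNDARY_TRIM_BINS if e < len(x_raw) else e
            if e2 - s2 < 1:
                s2, e2 = s, e
            seg = x_raw[s2:e2]
            mu = float(seg.mean())
            seg_mol.append(len(mol_ids) - 1)
            starts.append(s)
            ends.append(e)
            means.append(mu)
            counts.append(e2 - s2)
            ss.append(float(np.sum((seg - mu) ** 2)))
            n_fit += e2 - s2
    return SegmentPool(
        molecule_ids=mol_ids,
        seg_molecule=np.asarray(seg_mol, dtype=int),
        seg_start=np.asarray(starts, dtype=int),
        seg_end=np.asarray(ends, dtype=int),
        means=np.asarray(means), counts=np.asarray(counts, dtype=int),
        ss_within=np.asarray(ss), sigma=sigma, n_bins=n_fit,
        n_change_points=n_cp)


def mdl_cost(pool: SegmentPool, group_means: np.ndarray,
             group_of_segment: np.ndarray) -> float:
    """Description length (bits) of the pooled data under a state grouping.

    Goodness of fit is the Gaussian unknown-variance code length
    ``(N/2) log2(RSS/N)`` — the residual scale is re-estimated under every
    candidate model, so the criterion is self-calibrating against the photon
    noise floor.  Complexity adds half a log2(N) per state mean, one log2(N)
    per change-point position, and log2(k) per segment for the
    segment-to-state membership; the membership term keeps selection
    consistent when a condition contains many segments (splitting a true
    state's segment cloud always lowers the fit term a little, but
    re-labelling every segment costs more).
    """
    k = len(group_means)
    fitted = group_means[group_of_segment]
    rss = float(np.sum(pool.ss_within)
                + np.sum(pool.counts * (pool.means - fitted) ** 2))
    N = max(pool.n_bins, 2)
    rss = max(rss, N * 1e-12)
    G = 0.5 * N * np.log2(rss / N)
    log2N = np.log2(N)
    P = 0.5 * k * log2N + pool.n_change_points * log2N
    if k > 1:
        P += pool.n_segments * np.log2(k)
    return G + P


def _merge_path(means: np.ndarray, counts: np.ndarray):
    """Greedy nearest-mean agglomeration of segments.

    Yields, for every k from n_segments down to 1, the group means and the
    per-segment group index at that level (groups ordered by descending mean).
    """
    n = len(means)
    group_of = np.arange(n)
    g_means = means.astype(float).copy()
    g_counts = counts.astype(float).copy()
    alive = np.ones(n, dtype=bool)
    levels = {}

    def _snapshot():
        idx = np.flatnonzero(alive)
        order = idx[np.argsort(-g_means[idx])]
        remap = {int(g): r for r, g in enumerate(order)}
        levels[len(idx)] = (g_means[order].copy(),
                            np.array([remap[int(g)] for g in group_of]))

    _snapshot()
    while alive.sum() > 1:
        idx = np.flatnonzero(alive)
        order = idx[np.argsort(g_means[idx])]
        gaps = np.diff(g_means[order])
        j = int(np.argmin(gaps))
        a, b = int(order[j]), int(order[j + 1])
        tot = g_counts[a] + g_counts[b]
        g_means[a] = (g_means[a] * g_counts[a] + g_means[b] * g_counts[b]) / tot
        g_counts[a] = tot
        alive[b] = False
        group_of[group_of == b] = a
        _snapshot()
    return levels


def _model_from_grouping(pool: SegmentPool, traces, use_denoised,
                         state_means, group_of_segment, method) -> StateModel:
    k = len(state_means)
    # refit state means as count-weighted means of member segments
    refit = np.array([
        (np.sum(pool.means[group_of_segment == s] * pool.counts[group_of_segment == s])
         / max(np.sum(pool.counts[group_of_segment == s]), 1))
        if np.any(group_of_segment == s) else state_means[s]
        for s in range(k)])
    order = np.argsort(-refit)
    refit = refit[order]
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    group_of_segment = remap[group_of_segment]

    assignments = {}
    data_by_state = [[] for _ in range(k)]
    for m, mol in enumerate(pool.molecule_ids):
        trace = traces[m]
        x = trace.denoised_efficiency if use_denoised else trace.raw_efficiency
        a = np.empty(len(x), dtype=int)
        mask = pool.seg_molecule == m
        for s0, e0, g in zip(pool.seg_start[mask], pool.seg_end[mask],
                             group_of_segment[mask]):
            a[s0:e0] = g
            data_by_state[g].append(x[s0:e0])
        assignments[mol] = a

    bins = np.array([sum(len(c) for c in chunks) for chunks in data_by_state],
                    dtype=float)
    occ = bins / bins.sum()
    halfwidths = np.array([
        FWHM_PER_SIGMA * np.std(np.concatenate(chunks) if chunks else np.zeros(1))
        for chunks in data_by_state])
    return StateModel(n_states=k, state_efficiencies=refit,
                      state_halfwidths=halfwidths, assignments=assignments,
                      occupancies=occ, method=method)


def stasi_fit(traces: list[EfficiencyTrace], use_denoised: bool = True,
              t_threshold: float = 3.0, min_segment: int = 3,
              min_separation: float = MIN_STATE_SEPARATION,
              min_occupancy: float = 0.005) -> StateModel:
    """STaSI: change-point segmentation + MDL selection of the state count.

    All molecules of a condition are fit globally.  States closer than
    ``min_separation`` efficiency units are merged and refit, and states
    holding less than ``min_occupancy`` of the data (isolated outlier
    segments, unresolvable as conformations) are dissolved into their nearest
    neighbor.  A degenerate all-equal input returns a single state.
    """
    if not traces:
        raise ValueError("need at least one efficiency trace")
    n_total = sum(t.n_bins for t in traces)
    if n_total < 20:
        raise ValueError(f"need >= 20 bins total, got {n_total}")

    pool = _pool_segments(traces, use_denoised, t_threshold, min_segment)
    levels = _merge_path(pool.means, pool.counts)
    best_k, best_cost = None, np.inf
    for k in sorted(levels):
        g_means, group_of = levels[k]
        cost = mdl_cost(pool, g_means, group_of)
        if cost < best_cost:
            best_k, best_cost = k, cost
    g_means, group_of = levels[best_k]

    # enforce the minimum separation by walking further down the merge path
    while len(g_means) > 1 and np.min(np.diff(np.sort(g_means))) < min_separation:
        g_means, group_of = levels[len(g_means) - 1]

    # dissolve sub-occupancy states into their nearest surviving neighbor
    seg_bins = (pool.seg_end - pool.seg_start).astype(float)
    while len(g_means) > 1:
        occ = np.array([seg_bins[group_of == s].sum()
                        for s in range(len(g_means))])
        occ = occ / occ.sum()
        worst = int(np.argmin(occ))
        if occ[worst] >= min_occupancy:
            break
        keep = [s for s in range(len(g_means)) if s != worst]
        nearest = {worst: keep[int(np.argmin([abs(g_means[worst] - g_means[s])
                                              for s in keep]))]}
        group_of = np.array([nearest.get(g, g) for g in group_of])
        remap = {s: i for i, s in enumerate(keep)}
        group_of = np.array([remap[g] for g in group_of])
        g_means = np.array([
            np.average(pool.means[group_of == i], weights=pool.counts[group_of == i])
            for i in range(len(keep))])
    return _model_from_grouping(pool, traces, use_denoised, g_means,
                                group_of, method="stasi")


# ---------------------------------------------------------------------------
# HMM cross-check
# ---------------------------------------------------------------------------

def _hmm_n_parameters(k: int) -> int:
    # start probs (k-1) + transition rows (k*(k-1)) + means (k) + variances (k)
    return (k - 1) + k * (k - 1) + 2 * k


def hmm_fit(traces: list[EfficiencyTrace], n_states_max: int = 6,
            n_restarts: int = 10, seed: int = 0,
            n_iter: int = 200, min_separation: float = MIN_STATE_SEPARATION,
            min_occupancy: float = 0.005) -> StateModel:
    """Gaussian-emission HMM on raw efficiencies; K chosen by BIC.

    Each candidate K in 1..``n_states_max`` is fit by EM with ``n_restarts``
    deterministically seeded short restarts followed by one long refinement;
    the best log-likelihood per K enters a BIC comparison.  Because Gaussian
    emissions understate the tails of shot-noise efficiency distributions,
    BIC tends to split one conformational state into two strongly overlapping
    components; decoded states are therefore post-merged when their means are
    closer than the larger of ``min_separation`` and the smaller emission
    standard deviation, and states holding under ``min_occupancy`` of the
    bins are dissolved into their nearest neighbor.  Non-convergence after
    all restarts is flagged on the returned model rather than raised.
    """
    from hmmlearn.hmm import GaussianHMM

    if not traces:
        raise ValueError("need at least one efficiency trace")
    X = np.concatenate([t.raw_efficiency for t in traces])[:, None]
    lengths = [t.n_bins for t in traces]
    N = len(X)
    if N < 20:
        raise ValueError(f"need >= 20 bins total, got {N}")
    n_states_max = min(n_states_max, max(1, N // 10))

    rng = np.random.default_rng(seed)
    best = None  # (bic, model, converged, k)
    for k in range(1, n_states_max + 1):
        # cheap short-EM restarts to pick a basin, then one long refinement
        best_ll, best_model = -np.inf, None
        for _ in range(n_restarts if k > 1 else 1):
            model = GaussianHMM(n_components=k, covariance_type="diag",
                                n_iter=25, tol=1e-3,
                                random_state=int(rng.integers(2**31 - 1)),
                                min_covar=1e-5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    model.fit(X, lengths)
                    ll = model.score(X, lengths)
                except (ValueError, np.linalg.LinAlgError):
                    continue
            if ll > best_ll:
                best_ll, best_model = ll, model
        if best_model is None:
            continue
        model = GaussianHMM(n_components=k, covariance_type="diag",
                            n_iter=n_iter, tol=1e-4, min_covar=1e-5,
                            init_params="")
        model.startprob_ = best_model.startprob_
        model.transmat_ = best_model.transmat_
        model.means_ = best_model.means_
        model.covars_ = np.maximum(best_model.covars_.reshape(k, 1), 1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X, lengths)
                best_ll = model.score(X, lengths)
                conv = bool(model.monitor_.converged)
            except (ValueError, np.linalg.LinAlgError):
                model, conv = best_model, False
        bic = -2.0 * best_ll + _hmm_n_parameters(k) * np.log(N)
        if best is None or bic < best[0]:
            best = (bic, model, conv, k)
    if best is None:
        raise RuntimeError("HMM fitting failed for every candidate state count")
    _, model, converged, k = best

    means = model.means_.ravel()
    sigmas = np.sqrt(model.covars_.reshape(-1))
    order = np.argsort(-means)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    means, sigmas = means[order], sigmas[order]

    assignments = {t.molecule_id: remap[model.predict(t.raw_efficiency[:, None])]
                   for t in traces}

    def _recompute(k_now):
        counts = np.zeros(k_now)
        data = [[] for _ in range(k_now)]
        for t in traces:
            a = assignments[t.molecule_id]
            counts += np.bincount(a, minlength=k_now)
            for s in range(k_now):
                data[s].append(t.raw_efficiency[a == s])
        mu = np.array([np.mean(np.concatenate(c)) if counts[s] else means[s]
                       for s, c in enumerate(data)])
        sd = np.array([np.std(np.concatenate(c)) if counts[s] else 0.0
                       for s, c in enumerate(data)])
        return counts, mu, sd

    def _relabel(drop, into):
        # map the dropped label onto its target, then close the gap
        for mol, a in assignments.items():
            a = np.where(a == drop, into, a)
            assignments[mol] = np.where(a > drop, a - 1, a)

    # merge overlapping near-duplicate states, then sub-occupancy states
    while k > 1:
        counts, mu, sd = _recompute(k)
        pair = int(np.argmin(np.abs(np.diff(mu))))
        gap = abs(mu[pair + 1] - mu[pair])
        sd_pair = [s for s in (sd[pair], sd[pair + 1]) if s > 0]
        limit = max(min_separation, min(sd_pair) if sd_pair else 0.0)
        occ = counts / counts.sum()
        worst = int(np.argmin(occ))
        if gap < limit:
            keep = pair if counts[pair] >= counts[pair + 1] else pair + 1
            drop = pair + 1 if keep == pair else pair
            _relabel(drop, keep)
            means, k = mu, k - 1
            continue
        if occ[worst] < min_occupancy:
            others = [s for s in range(k) if s != worst]
            into = others[int(np.argmin([abs(mu[worst] - mu[s]) for s in others]))]
            _relabel(worst, into)
            means, k = mu, k - 1
            continue
        break

    counts, mu, sd = _recompute(k)
    occ = counts / counts.sum()
    return StateModel(n_states=k, state_efficiencies=mu,
                      state_halfwidths=FWHM_PER_SIGMA * sd,
                      assignments=assignments,
                      occupancies=occ, method="hmm", converged=converged)


# ---------------------------------------------------------------------------
# Histograms and Gaussian peak fitting
# ---------------------------------------------------------------------------

def build_histogram(traces: list[EfficiencyTrace], use_denoised: bool = True,
                    bin_width: float = HIST_BIN_WIDTH,
                    hist_range: tuple[float, float] = HIST_RANGE):
    """Pooled efficiency histogram: each count is one analysis bin, and the
    cumulative counts over all molecules are normalized to fractions.

    Returns ``(bin_centers, fraction)``.
    """
    edges = np.arange(hist_range[0], hist_range[1] + bin_width / 2, bin_width)
    x = np.concatenate([
        (t.denoised_efficiency if use_denoised else t.raw_efficiency)
        for t in traces])
    counts, _ = np.histogram(np.clip(x, edges[0], edges[-1] - 1e-12), bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts / counts.sum()


def _gauss_mixture(x, *params):
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        amp, mu, sig = params[i:i + 3]
        y = y + amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return y


def fit_gaussians(histogram, state_model_or_means, bin_width: float = HIST_BIN_WIDTH):
    """Least-squares Gaussian mixture fit to a normalized histogram.

    The component count is fixed; initial means come from a
    :class:`StateModel` or a plain sequence of efficiencies.  Returns a list
    of ``(peak_E, fwhm, area)`` sorted by descending peak position; areas are
    in fraction units and sum to ~1 for a normalized histogram.  A diverging
    fit raises with the residual attached.
    """
    centers, frac = histogram
    if isinstance(state_model_or_means, StateModel):
        means0 = np.asarray(state_model_or_means.state_efficiencies, dtype=float)
    else:
        means0 = np.asarray(state_model_or_means, dtype=float)
    k = len(means0)
    p0 = []
    for mu in means0:
        amp0 = max(float(np.interp(mu, centers, frac)), 1e-4)
        p0 += [amp0, float(mu), 0.03]
    lo = [0.0, centers[0] - 0.1, 1e-4] * k
    hi = [1.0, centers[-1] + 0.1, 0.5] * k
    try:
        popt, _ = optimize.curve_fit(_gauss_mixture, centers, frac, p0=p0,
                                     bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        resid = float(np.sum((frac - _gauss_mixture(centers, *p0)) ** 2))
        raise RuntimeError(f"Gaussian mixture fit diverged "
                           f"(initial residual {resid:.3g})") from exc
    out = []
    for i in range(0, 3 * k, 3):
        amp, mu, sig = popt[i:i + 3]
        area = amp * sig * np.sqrt(2.0 * np.pi) / bin_width
        out.append((float(mu), float(FWHM_PER_SIGMA * sig), float(area)))
    return sorted(out, key=lambda t: -t[0])
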