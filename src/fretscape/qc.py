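"""Molecule selection: photobleach-step counting and anticorrelation checks.

Only molecules with a clear single photobleach step in both the donor and
acceptor channels carry exactly one donor and one acceptor, so their
efficiency reports a single inter-fluorophore distance; everything else is
rejected.  The FRETing region of an accepted molecule runs from the start of
the trace to the first bleach event in either channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .changepoint import find_change_points, robust_noise_sigma, segment_means
from .io import PhotonTrace

__all__ = ["QCReport", "detect_bleach_steps", "check_anticorrelation",
           "select_molecule", "qc_table"]

MIN_SERIES_BINS = 20
MIN_REGION_BINS = 50


@dataclass
class QCReport:
    molecule_id: str
    donor_steps: int
    acceptor_steps: int
    donor_step_times: np.ndarray      # ms
    acceptor_step_times: np.ndarray   # ms
    anticorrelation: float            # Pearson r; NaN if undefined
    fret_region: tuple[float, float]  # [start_ms, end_ms)
    accepted: bool
    reject_reason: str                # "" when accepted

    def to_row(self) -> dict:
        return {
            "molecule_id": self.molecule_id,
            "donor_steps": self.donor_steps,
            "acceptor_steps": self.acceptor_steps,
            "donor_step_times_ms": ";".join(f"{t:g}" for t in self.donor_step_times),
            "acceptor_step_times_ms": ";".join(f"{t:g}" for t in self.acceptor_step_times),
            "anticorrelation": self.anticorrelation,
            "fret_start_ms": self.fret_region[0],
            "fret_end_ms": self.fret_region[1],
            "accepted": self.accepted,
            "reject_reason": self.reject_reason,
        }


def detect_bleach_steps(channel: np.ndarray, bin_width: float = 1.0,
                        t_threshold: float = 5.0, min_segment: int = 10):
    """Count downward intensity steps in one channel.

    Photon counts are Poisson, so their variance tracks the local mean; the
    series is first variance-stabilized with the Anscombe transform
    ``2*sqrt(x + 3/8)`` (unit noise standard deviation at any intensity), and
    change points are then located by recursive t-test splitting with the
    noise scale floored at the Anscombe value of 1.  Only downward level
    changes are counted as bleach steps (the donor channel *rises* at an
    acceptor bleach, which must not be counted).  Returns
    ``(step_count, step_times_ms)`` with times in ascending order.
    """
    x = np.asarray(channel, dtype=float)
    if len(x) < MIN_SERIES_BINS:
        raise ValueError(f"series too short for step detection "
                         f"({len(x)} < {MIN_SERIES_BINS} bins)")
    y = 2.0 * np.sqrt(x + 0.375)
    sigma = max(robust_noise_sigma(y), 1.0)
    cps = find_change_points(y, sigma=sigma, t_threshold=t_threshold,
                             min_segment=min_segment)
    segs = segment_means(y, cps)
    times = [segs[i + 1][0] * bin_width
             for i in range(len(segs) - 1)
             if segs[i + 1][2] < segs[i][2]]
    return len(times), np.asarray(times)


def check_anticorrelation(trace: PhotonTrace, region: tuple[float, float]) -> float:
    """Pearson correlation of donor vs acceptor counts over ``region`` (ms).

    Returns NaN when either channel has zero variance in the region
    (undefined; callers treat NaN as a failed check).
    """
    start = int(region[0] // trace.bin_width)
    end = int(region[1] // trace.bin_width)
    end = min(end, trace.n_bins)
    if end - start < MIN_REGION_BINS:
        raise ValueError(f"{trace.molecule_id}: anticorrelation region shorter "
                         f"than {MIN_REGION_BINS} bins")
    d = trace.donor[start:end].astype(float)
    a = trace.acceptor[start:end].astype(float)
    if np.std(d) == 0.0 or np.std(a) == 0.0:
        return float("nan")
    r, _ = stats.pearsonr(d, a)
    return float(r)


def select_molecule(trace: PhotonTrace, t_threshold: float = 5.0,
                    min_segment: int = 10, r_threshold: float = -0.3,
                    anticorr_extension_bins: int = 100) -> QCReport:
    """Accept or reject one molecule and delimit its FRETing region.

    Accepted molecules have exactly one donor and one acceptor bleach step
    and an anticorrelated donor/acceptor pair (Pearson r <= ``r_threshold``).

    Conformational transitions also step the individual FRET channels, so
    bleach events are counted on state-invariant series instead: the *summed*
    donor-excitation intensity is conserved under energy transfer and drops
    only when a donor bleaches, and the direct acceptor-excitation channel
    (when recorded) is efficiency-independent and drops only when an acceptor
    bleaches.  Without a direct-excitation channel the acceptor bleach count
    falls back to downward steps of the acceptor FRET channel, which is
    reliable only for conformationally quiet molecules.

    The anticorrelation window is the FRETing region, extended
    ``anticorr_extension_bins`` past the first bleach when that bleach is an
    acceptor bleach — the donor-rise signature at acceptor bleaching is the
    strongest anticorrelation evidence for conformationally static
    molecules.  Rejection is a result, not an error.
    """
    nd, td = detect_bleach_steps(trace.total, trace.bin_width,
                                 t_threshold, min_segment)
    if trace.acceptor_direct is not None:
        na, ta = detect_bleach_steps(trace.acceptor_direct, trace.bin_width,
                                     t_threshold, min_segment)
    else:
        na, ta = detect_bleach_steps(trace.acceptor, trace.bin_width,
                                     t_threshold, min_segment)
    all_times = np.concatenate([td, ta])
    end_ms = float(all_times.min()) if all_times.size else trace.n_bins * trace.bin_width
    region = (0.0, end_ms)

    def _report(accepted, reason, r=float("nan")):
        return QCReport(trace.molecule_id, nd, na, td, ta, r, region,
                        accepted, reason)

    if nd == 0:
        return _report(False, "no_donor_step")
    if na == 0:
        return _report(False, "no_acceptor_step")
    if nd > 1:
        return _report(False, "multiple_donor_steps")
    if na > 1:
        return _report(False, "multiple_acceptor_steps")

    # same-bin steps in both channels mean the donor bleached first; only an
    # acceptor-first bleach leaves the donor-rise signature worth including
    acceptor_first = ta.size and (not td.size or ta.min() < td.min())
    window_end = end_ms
    if acceptor_first:
        window_end = min(end_ms + anticorr_extension_bins * trace.bin_width,
                         trace.n_bins * trace.bin_width)
    if int(window_end // trace.bin_width) < MIN_REGION_BINS:
        return _report(False, "region_too_short")
    r = check_anticorrelation(trace, (0.0, window_end))
    if not np.isfinite(r) or r > r_threshold:
        return _report(False, "poor_anticorrelation", r)
    return _report(True, "", r)


def qc_table(reports) -> pd.DataFrame:
    """One row per molecule with all QC fields, suitable for TSV export."""
    return pd.DataFrame([r.to_row() for r in reports])
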