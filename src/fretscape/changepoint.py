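"""Mean-shift change-point detection by recursive t-test splitting.

Shared by the photobleach-step detector (QC) and the state-identification
stage: a segment is split at the position maximizing the two-sample
t-statistic of the flanking means; the split is accepted when |t| exceeds a
threshold, and both sides are searched recursively.  The noise scale sigma
is supplied by the caller (robustly estimated from finest-scale differences),
so the statistic is a z-like t with pooled known variance.
"""

from __future__ import annotations

import numpy as np

__all__ = ["find_change_points", "robust_noise_sigma", "segment_means"]

_TINY = 1e-300


def robust_noise_sigma(x: np.ndarray) -> float:
    """Noise standard deviation from the median absolute first difference.

    For white noise, successive differences have standard deviation
    sigma*sqrt(2); the MAD/0.6745 scaling makes the estimate robust to the
    sparse large differences contributed by genuine steps.
    """
    d = np.diff(np.asarray(x, dtype=float))
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d)) / 0.6745 / np.sqrt(2.0))


def _best_split(x: np.ndarray, start: int, end: int, min_segment: int,
                sigma: float):
    """Best split index k in (start, end) and its t value; (None, 0) if none fits."""
    n = end - start
    if n < 2 * min_segment:
        return None, 0.0
    seg = x[start:end]
    csum = np.cumsum(seg)
    total = csum[-1]
    k = np.arange(min_segment, n - min_segment + 1)  # left length
    mean_l = csum[k - 1] / k
    mean_r = (total - csum[k - 1]) / (n - k)
    se = sigma * np.sqrt(1.0 / k + 1.0 / (n - k)) + _TINY
    t = np.abs(mean_l - mean_r) / se
    i = int(np.argmax(t))
    return start + int(k[i]), float(t[i])


def find_change_points(x: np.ndarray, sigma: float | None = None,
                       t_threshold: float = 5.0,
                       min_segment: int = 10) -> np.ndarray:
    """Change-point positions (index of the first point of the right segment).

    With ``sigma=None`` the noise scale is estimated with
    :func:`robust_noise_sigma`.  Noise-free piecewise-constant input
    (sigma estimate 0) is segmented exactly at every level change.
    """
    x = np.asarray(x, dtype=float)
    if sigma is None:
        sigma = robust_noise_sigma(x)
    cps: list[int] = []
    stack = [(0, len(x))]
    while stack:
        start, end = stack.pop()
        k, t = _best_split(x, start, end, min_segment, sigma)
        if k is not None and t >= t_threshold:
            cps.append(k)
            stack.append((start, k))
            stack.append((k, end))
    return np.array(sorted(cps), dtype=int)


def segment_means(x: np.ndarray, change_points: np.ndarray):
    """Per-segment (start, end, mean, n) given sorted change points."""
    bounds = np.concatenate([[0], change_points, [len(x)]]).astype(int)
    out = []
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1]
        out.append((s, e, float(np.mean(x[s:e])), e - s))
    return out
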