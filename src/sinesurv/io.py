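"""Table I/O re-exports and the TTT (total time on test) hazard-shape diagnostic."""

from __future__ import annotations

import numpy as np

from .data import SurvivalDataset, read_survival_table, write_survival_table

__all__ = [
    "SurvivalDataset",
    "read_survival_table",
    "write_survival_table",
    "ttt_statistic",
]


def ttt_statistic(times) -> np.ndarray:
    """Scaled total-time-on-test transform.

    For order statistics t_(1) <= ... <= t_(n), the r-th coordinate pair is

        ( r/n,  [sum_{i<=r} t_(i) + (n - r) t_(r)] / sum_i t_(i) ),

    returned as an (n, 2) array whose last row is (1, 1).  The curvature of
    the resulting plot diagnoses the hazard shape: concave = increasing
    hazard, convex = decreasing, S-shaped = non-monotone.

    The transform is defined for complete samples; censored observations,
    if present, should be filtered by the caller (the CLI exposes a flag).
    """
    t = np.sort(np.asarray(times, dtype=float))
    n = t.size
    if n < 2:
        raise ValueError("TTT transform needs at least 2 observations")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    total = t.sum()
    if total == 0:
        raise ValueError("TTT transform undefined for all-zero times")
    r = np.arange(1, n + 1)
    cum = np.cumsum(t)
    scaled = (cum + (n - r) * t) / total
    return np.column_stack([r / n, scaled])
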