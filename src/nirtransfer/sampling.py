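"""SPXY calibration/prediction splitting.

Sample-set partitioning based on joint X-Y distances: Euclidean distances
in spectral space and in label space are each normalised by their maxima
and summed; selection starts from the most distant pair and greedily adds
the sample whose minimum joint distance to the already-selected set is
maximal. Deterministic (ties broken by lowest index), so the calibration
set for size k nests inside the one for k+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitResult", "spxy_split", "joint_distance_matrix"]


@dataclass(frozen=True)
class SplitResult:
    cal_idx: tuple[int, ...]
    pred_idx: tuple[int, ...]


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(i,j) = d_x(i,j)/max(d_x) + d_y(i,j)/max(d_y), Euclidean."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    dx = squareform(pdist(X))
    dy = squareform(pdist(y))
    mx = dx.max()
    my = dy.max()
    d = np.zeros_like(dx)
    if mx > 0:
        d += dx / mx
    if my > 0:
        d += dy / my
    return d


def spxy_split(X: np.ndarray, y: np.ndarray, n_cal: int) -> SplitResult:
    """Select ``n_cal`` calibration samples by the SPXY max-min rule."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if not 2 <= n_cal < n:
        raise ValueError(f"n_cal must be in [2, {n - 1}], got {n_cal}")
    d = joint_distance_matrix(X, y)

    # initial pair: maximal joint distance, lexicographically smallest on ties
    flat = np.argmax(d)  # argmax scans row-major -> smallest (i, j) wins
    i0, j0 = divmod(int(flat), n)
    selected = [min(i0, j0), max(i0, j0)]
    remaining = [k for k in range(n) if k not in selected]

    # min distance from each remaining sample to the selected set
    min_d = np.minimum(d[remaining, selected[0]], d[remaining, selected[1]])
    remaining = np.array(remaining)
    while len(selected) < n_cal:
        best = int(np.argmax(min_d))  # argmax -> lowest index on ties
        nxt = int(remaining[best])
        selected.append(nxt)
        remaining = np.delete(remaining, best)
        min_d = np.delete(min_d, best)
        if remaining.size:
            min_d = np.minimum(min_d, d[remaining, nxt])

    pred = tuple(k for k in range(n) if k not in set(selected))
    return SplitResult(cal_idx=tuple(selected), pred_idx=pred)
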