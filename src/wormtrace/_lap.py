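"""Rectangular linear assignment with a per-node non-link alternative.

Every linking step in the pipeline (frame-to-frame linking, gap closing,
atlas assignment, ground-truth matching) is the same problem: a rectangular
min-cost matching in which each element may instead stay unmatched at an
alternative cost, set to 1.05 * cmax where cmax is the largest finite
pairwise cost of the instance. Forbidden pairs are encoded as +inf.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

ALT_FACTOR = 1.05


def solve_assignment(
    cost: np.ndarray,
    alternative: float | None = None,
    alt_factor: float = ALT_FACTOR,
) -> list[tuple[int, int]]:
    """Solve min-cost matching with unmatched nodes allowed.

    Parameters
    ----------
    cost : (n, m) array
        Pairwise costs; ``np.inf`` marks forbidden pairs.
    alternative : float, optional
        Cost of leaving one node unmatched. Defaults to
        ``alt_factor * max(finite costs)``; if every cost is forbidden the
        alternative is undefined and nothing is matched.

    Returns
    -------
    list of (row, col) matched index pairs.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost must be a 2D matrix")
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    finite = cost[np.isfinite(cost)]
    if alternative is None:
        if finite.size == 0:
            return []
        alternative = alt_factor * float(finite.max())
    # a zero alternative would make "match at zero cost" and "stay alone"
    # tie; nudge so matching wins ties
    alternative = max(float(alternative), 1e-12)

    aug = np.full((n + m, n + m), np.inf)
    aug[:n, :m] = cost
    aug[np.arange(n), m + np.arange(n)] = alternative  # row i unmatched
    aug[n + np.arange(m), np.arange(m)] = alternative  # col j unmatched
    aug[n:, m:] = 0.0  # dummy-dummy absorbs the rest
    rows, cols = linear_sum_assignment(aug)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if r < n and c < m and np.isfinite(cost[r, c])]


def assignment_total_cost(
    cost: np.ndarray, pairs: list[tuple[int, int]], alternative: float
) -> float:
    """Objective value: matched costs plus alternative per unmatched node."""
    n, m = cost.shape
    matched = sum(cost[r, c] for r, c in pairs)
    unmatched = (n - len(pairs)) + (m - len(pairs))
    return float(matched + alternative * unmatched)
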