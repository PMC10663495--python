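"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's vectorised code paths: the AR(1)
recursion is an explicit Python loop, pointwise t-tests go through
scipy.stats.ttest_1samp, and run extraction scans every (start, end) pair.
Only the random-draw order contract (initial values first, then the
innovation matrix, one call pair per simulation) is shared, so that the
same seed drives both implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def exhaustive_longest_run(flags) -> int:
    """Longest all-True stretch by scanning every (start, end) pair."""
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    best = 0
    for i in range(n):
        for j in range(i, n):
            if flags[i : j + 1].all():
                best = max(best, j - i + 1)
    return best


def exhaustive_runs(flags) -> list[tuple[int, int]]:
    """All maximal all-True (start, end) index pairs, by exhaustive scan."""
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    out = []
    for i in range(n):
        for j in range(i, n):
            if not flags[i : j + 1].all():
                continue
            left_ok = i == 0 or not flags[i - 1]
            right_ok = j == n - 1 or not flags[j + 1]
            if left_ok and right_ok:
                out.append((i, j))
    return out


def brute_force_null_max_runs(
    n_subjects: int,
    n_points: int,
    phi: float,
    alpha: float,
    n_sims: int,
    seed: int,
) -> np.ndarray:
    """Null distribution of longest significant-run lengths, loop version."""
    rng = np.random.default_rng(seed)
    stat_sd = 1.0 / np.sqrt(1.0 - phi * phi)
    out = np.empty(n_sims, dtype=int)
    for s in range(n_sims):
        x0 = rng.standard_normal(n_subjects) * stat_sd
        eps = rng.standard_normal((n_subjects, n_points - 1))
        x = np.empty((n_subjects, n_points))
        x[:, 0] = x0
        for t in range(1, n_points):
            x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
        pvals = np.array(
            [stats.ttest_1samp(x[:, j], 0.0).pvalue for j in range(n_points)]
        )
        out[s] = exhaustive_longest_run(pvals < alpha)
    return out


def nearest_rank(values, percentile: float) -> int:
    v = sorted(values)
    k = int(np.ceil(percentile / 100.0 * len(v)))
    return int(v[max(k, 1) - 1])
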