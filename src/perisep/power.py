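"""A-priori power for the paired (one-sample) t-test.

For a standardized paired effect size dz, the test statistic under the
alternative follows a noncentral t distribution with df = n - 1 and
noncentrality dz * sqrt(n).  Power is the probability that |T'| exceeds
the two-tailed critical value; the required sample size is the smallest n
achieving a target power.
"""

from __future__ import annotations

from scipy import stats
import numpy as np


def paired_t_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-tailed paired t-test at effect size dz = d."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 1
    nc = d * np.sqrt(n)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc)
    return float(power)


def required_n(
    d: float, alpha: float = 0.05, target_power: float = 0.85, n_cap: int = 1_000_000
) -> int:
    """Smallest n >= 2 with paired_t_power(n, d, alpha) >= target_power."""
    if d == 0:
        raise ValueError("effect size must be non-zero for a sample-size query")
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    n = 2
    while n <= n_cap:
        if paired_t_power(n, d, alpha) >= target_power:
            return n
        n += 1
    raise ValueError(f"target power not reachable within n <= {n_cap}")
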