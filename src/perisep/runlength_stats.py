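"""Pointwise t-tests with an autocorrelation-matched run-length null.

Uncorrected one-sample t-tests at every time point inflate the familywise
error rate, but consecutive significant points are informative: under
temporally autocorrelated noise, long runs of significance are rare unless
a real effect is present.  The procedure simulates many null datasets of
Gaussian AR(1) series with the lag-1 autocorrelation estimated from the
observed contrast waveforms, the same number of subjects, and the same
number of sample points; in each it records the longest run of consecutive
significant t-tests.  Observed runs strictly longer than the 95th
percentile of that null distribution are declared statistically reliable.

t statistics are scale-free, so the simulated null uses unit innovation
variance; only the autocorrelation needs matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from perisep.preprocess import ContrastSeries
from perisep.synthetic_data import ar1_series


@dataclass(frozen=True)
class TSeries:
    """Pointwise one-sample t statistics over the analysis window."""

    times_ms: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    df: int
    alpha: float
    n_zero_variance: int = 0

    @property
    def dt_ms(self) -> float:
        return float(np.median(np.diff(self.times_ms)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "t": self.t,
                "p": self.p,
                "significant": self.significant,
            }
        )


@dataclass(frozen=True)
class RunNull:
    """Monte Carlo null distribution of longest significant-run lengths."""

    n_sims: int
    phi_used: float
    alpha: float
    percentile: float
    seed: int
    fs: float
    max_run_lengths: np.ndarray
    threshold_samples: int
    threshold_ms: float

    def summary(self) -> dict:
        lengths, counts = np.unique(self.max_run_lengths, return_counts=True)
        return {
            "n_sims": self.n_sims,
            "phi_used": self.phi_used,
            "alpha": self.alpha,
            "percentile": self.percentile,
            "seed": self.seed,
            "fs": self.fs,
            "threshold_samples": int(self.threshold_samples),
            "threshold_ms": float(self.threshold_ms),
            "max_run_histogram": {int(k): int(v) for k, v in zip(lengths, counts)},
        }


@dataclass(frozen=True)
class SignificantRun:
    """A maximal run of consecutive significant time points above threshold."""

    start_ms: float
    end_ms: float
    length_samples: int
    length_ms: float


def pointwise_t(contrasts: ContrastSeries, alpha: float = 0.05) -> TSeries:
    """Two-tailed one-sample t-test vs zero at every time point.

    Points with zero between-subject variance but a non-zero mean are
    treated as significant (|t| infinite) with a warning; an all-zero
    point leaves t undefined and is rejected as degenerate input.
    """
    x = contrasts.data
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a t-test")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero_var = sd == 0.0
    degenerate = zero_var & (mean == 0.0)
    if degenerate.any():
        raise ValueError(
            f"{int(degenerate.sum())} time points have all-zero contrasts; t undefined"
        )
    n_zero = int(zero_var.sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} time points have zero variance; treated as significant",
            stacklevel=2,
        )
    df = n - 1
    with np.errstate(divide="ignore"):
        t = np.where(zero_var, np.sign(mean) * np.inf, mean / (sd / np.sqrt(n)))
    p = np.where(zero_var, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return TSeries(
        times_ms=contrasts.times_ms,
        t=t,
        p=p,
        significant=p < alpha,
        df=df,
        alpha=alpha,
        n_zero_variance=n_zero,
    )


def estimate_phi(contrasts: ContrastSeries, clamp: bool = True) -> float:
    """Lag-1 autocorrelation of the contrast waveforms.

    Computed per subject as the Pearson correlation between the series and
    its one-sample lag, then combined across subjects by a Fisher-z mean.
    With ``clamp`` (the default) the estimate is clipped to [0, 0.999] —
    the simulated null assumes a non-negative, stationary AR(1) — with a
    warning when a negative estimate is clipped.
    """
    x = contrasts.data
    if x.shape[1] < 3:
        raise ValueError("need at least 3 time points to estimate autocorrelation")
    zs = []
    for i in range(x.shape[0]):
        a, b = x[i, :-1], x[i, 1:]
        if a.std() == 0.0 or b.std() == 0.0:
            warnings.warn(
                f"subject {contrasts.subjects[i]} has a constant waveform; skipped",
                stacklevel=2,
            )
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        r = min(max(r, -0.9999999), 0.9999999)
        zs.append(np.arctanh(r))
    if not zs:
        raise ValueError("all subjects have constant waveforms; phi inestimable")
    phi = float(np.tanh(np.mean(zs)))
    if clamp:
        if phi < 0.0:
            warnings.warn(
                f"negative autocorrelation estimate ({phi:.3f}) clamped to 0",
                stacklevel=2,
            )
        phi = min(max(phi, 0.0), 0.999)
    return phi


def _runs_from_flags(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_index, end_index) inclusive."""
    f = np.asarray(flags, dtype=bool)
    if f.size == 0:
        return []
    padded = np.concatenate(([False], f, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def longest_run(flags: np.ndarray) -> int:
    """Length (in samples) of the longest run of True."""
    runs = _runs_from_flags(flags)
    return max((e - s + 1 for s, e in runs), default=0)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Smallest value with at least ``percentile`` % of the data at or below it."""
    v = np.sort(np.asarray(values))
    k = int(np.ceil(percentile / 100.0 * v.size))
    k = min(max(k, 1), v.size)
    return float(v[k - 1])


def null_run_distribution(
    n_subjects: int,
    n_points: int,
    phi: float,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
    percentile: float = 95.0,
    fs: float = 500.0,
) -> RunNull:
    """Simulate the null distribution of longest significant-run lengths.

    Each simulation draws ``n_subjects`` independent stationary AR(1)
    series of ``n_points`` samples (unit innovation SD), applies the
    pointwise two-tailed t-test at ``alpha``, and records the longest run
    of consecutive significant points.  One Generator seeded with ``seed``
    supplies all draws, one ``ar1_series(..., size=n_subjects)`` call per
    simulation, so the full distribution is reproducible.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not abs(phi) < 1:
        raise ValueError("|phi| must be < 1")
    rng = np.random.default_rng(seed)
    df = n_subjects - 1
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    sqrt_n = np.sqrt(n_subjects)
    max_runs = np.empty(n_sims, dtype=int)
    for s in range(n_sims):
        x = ar1_series(n_points, phi, 1.0, rng, size=n_subjects)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        t = mean / (sd / sqrt_n)
        max_runs[s] = longest_run(np.abs(t) > t_crit)
    threshold = int(nearest_rank_percentile(max_runs, percentile))
    dt = 1000.0 / fs
    return RunNull(
        n_sims=n_sims,
        phi_used=float(phi),
        alpha=alpha,
        percentile=percentile,
        seed=seed,
        fs=fs,
        max_run_lengths=max_runs,
        threshold_samples=threshold,
        threshold_ms=threshold * dt,
    )


def find_significant_runs(tseries: TSeries, null: RunNull) -> list[SignificantRun]:
    """Maximal significant runs strictly longer than the null threshold.

    Run duration is length_samples * (1000/fs) ms and the comparison with
    the threshold is a strict inequality.
    """
    dt = 1000.0 / null.fs
    if not np.isclose(tseries.dt_ms, dt):
        raise ValueError("t-series grid spacing does not match the null's sampling rate")
    out = []
    for s, e in _runs_from_flags(tseries.significant):
        length = e - s + 1
        length_ms = length * dt
        if length_ms > null.threshold_ms:
            out.append(
                SignificantRun(
                    start_ms=float(tseries.times_ms[s]),
                    end_ms=float(tseries.times_ms[e]),
                    length_samples=length,
                    length_ms=length_ms,
                )
            )
    return out


def runs_to_frame(runs: list[SignificantRun]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_ms": r.start_ms,
                "end_ms": r.end_ms,
                "length_samples": r.length_samples,
                "length_ms": r.length_ms,
            }
            for r in runs
        ],
        columns=["start_ms", "end_ms", "length_samples", "length_ms"],
    )
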