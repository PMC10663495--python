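"""Collapsed-localizer component windows and per-component statistics.

Component latency windows are defined on the waveform averaged across
conditions (the "collapsed localizer"), which keeps window selection
unbiased with respect to the condition comparison.  Peaks of alternating
polarity become components, labelled by polarity letter and peak latency
(e.g. P286); window boundaries sit at the zero crossing of the collapsed
waveform between adjacent peaks, falling back to the latency midpoint when
no crossing exists.  Per-component mean amplitudes are then compared
between conditions with a paired two-tailed t-test, with Cohen's
dz = t/sqrt(n) and a Kolmogorov-Smirnov normality check on the paired
differences reported alongside (never used to gate the t-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from perisep.synthetic_data import CONDITIONS


@dataclass(frozen=True)
class ComponentWindow:
    """A polarity-labelled latency window around one SEP component."""

    label: str
    start_ms: float
    end_ms: float
    peak_latency_ms: float
    polarity: str

    def __post_init__(self) -> None:
        if not (self.start_ms <= self.peak_latency_ms <= self.end_ms):
            raise ValueError("peak latency must lie inside the window")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")


@dataclass(frozen=True)
class PairedTestResult:
    """Paired two-tailed t-test of a component's amplitude between conditions."""

    component: str
    n: int
    t: float
    df: int
    p: float
    dz: float
    mean_diff: float
    ks_D: float
    ks_p: float


def collapse_conditions(diffs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Grand-average difference wave across subjects and conditions."""
    g = diffs.groupby("time_ms", sort=True, observed=True)["amplitude_uv"].mean()
    return g.index.to_numpy(dtype=float), g.to_numpy()


def _alternating_peaks(
    wave: np.ndarray, prominence: float
) -> list[tuple[int, str]]:
    pos, _ = signal.find_peaks(wave, prominence=prominence)
    neg, _ = signal.find_peaks(-wave, prominence=prominence)
    peaks = sorted([(int(i), "+") for i in pos] + [(int(i), "-") for i in neg])
    # collapse consecutive same-polarity peaks, keeping the larger deflection
    out: list[tuple[int, str]] = []
    for idx, pol in peaks:
        if out and out[-1][1] == pol:
            prev_idx = out[-1][0]
            if abs(wave[idx]) > abs(wave[prev_idx]):
                out[-1] = (idx, pol)
        else:
            out.append((idx, pol))
    return out


def locate_components(
    times_ms: np.ndarray,
    collapsed: np.ndarray,
    search: tuple[float, float] = (202.0, 700.0),
    min_prominence_uv: float = 0.5,
) -> list[ComponentWindow]:
    """Identify alternating-polarity components on the collapsed waveform.

    Returns windows tiling the search interval: the first starts at the
    interval's lower bound, the last ends at its upper bound, and adjacent
    windows are separated by a single sampling step at the boundary (so a
    boundary near 355 ms on a 2 ms grid yields ...-354 and 356-... ms).
    """
    times = np.asarray(times_ms, dtype=float)
    a, b = search
    sel = (times >= a - 1e-9) & (times <= b + 1e-9)
    if sel.sum() < 3:
        raise ValueError("search interval too short on the grid")
    t = times[sel]
    w = np.asarray(collapsed, dtype=float)[sel]

    peaks = _alternating_peaks(w, min_prominence_uv)
    if not peaks:
        raise ValueError(
            "no components found; lower min_prominence_uv or widen the search interval"
        )

    boundaries: list[int] = []  # index of the last sample of each window but the final
    for (i, _), (j, _) in zip(peaks[:-1], peaks[1:]):
        seg = np.arange(i, j)
        crossings = seg[w[seg] * w[seg + 1] <= 0]
        if crossings.size:
            midpoint = 0.5 * (t[i] + t[j])
            k = int(crossings[np.argmin(np.abs(t[crossings] - midpoint))])
        else:
            k = int((i + j) // 2)
        boundaries.append(k)

    windows = []
    starts = [0] + [k + 1 for k in boundaries]
    ends = boundaries + [t.size - 1]
    for (pk, pol), s, e in zip(peaks, starts, ends):
        peak_ms = float(t[pk])
        label = f"{'P' if pol == '+' else 'N'}{int(round(peak_ms))}"
        windows.append(
            ComponentWindow(
                label=label,
                start_ms=float(t[s]),
                end_ms=float(t[e]),
                peak_latency_ms=peak_ms,
                polarity=pol,
            )
        )
    return windows


def mean_amplitudes(
    diffs: pd.DataFrame, windows: list[ComponentWindow]
) -> pd.DataFrame:
    """Per subject x condition x component mean difference-wave amplitude (µV)."""
    frames = []
    for win in windows:
        sel = diffs[
            (diffs["time_ms"] >= win.start_ms - 1e-9)
            & (diffs["time_ms"] <= win.end_ms + 1e-9)
        ]
        if sel.empty:
            raise ValueError(f"window {win.label} contains no grid points")
        keys = ["subject", "condition"]
        g = sel.groupby(keys, sort=True, observed=True)["amplitude_uv"].mean().reset_index()
        g.insert(0, "component", win.label)
        if "age_days" in diffs.columns:
            ages = diffs.groupby("subject", sort=True, observed=True)["age_days"].first()
            g = g.merge(ages.rename("age_days"), left_on="subject", right_index=True)
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def cohens_dz(t: float, n: int) -> float:
    """Cohen's dz for a paired comparison: t / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(t) / np.sqrt(n)


def _paired_differences(amps: pd.DataFrame, component: str) -> np.ndarray:
    sub = amps[amps["component"] == component]
    if sub.empty:
        raise ValueError(f"component '{component}' not found")
    wide = sub.pivot_table(
        index="subject", columns="condition", values="amplitude_uv", observed=True
    )
    for cond in CONDITIONS:
        if cond not in wide.columns or wide[cond].isna().any():
            raise ValueError(f"component '{component}' missing condition '{cond}'")
    return (wide["approaching"] - wide["receding"]).to_numpy()


def paired_component_test(
    amps: pd.DataFrame, component: str, ks_method: str = "fitted"
) -> PairedTestResult:
    """Paired two-tailed t-test (approaching vs receding) for one component.

    ``ks_method`` selects the normality diagnostic on the paired
    differences: ``"fitted"`` is a one-sample KS against a normal with the
    sample mean and SD (exact small-sample p, parameters treated as
    fixed); ``"lilliefors"`` corrects the p-value for the estimated
    parameters (statsmodels table/Monte Carlo).
    """
    d = _paired_differences(amps, component)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            # identical conditions: no effect, trivially non-significant
            return PairedTestResult(
                component=component, n=n, t=0.0, df=n - 1, p=1.0, dz=0.0,
                mean_diff=0.0, ks_D=float("nan"), ks_p=float("nan"),
            )
        raise ValueError("paired differences have zero variance; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    if ks_method == "fitted":
        ks = stats.kstest(d, "norm", args=(d.mean(), sd), method="exact")
        ks_D, ks_p = float(ks.statistic), float(ks.pvalue)
    elif ks_method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        ks_D, ks_p = lilliefors(d, dist="norm", pvalmethod="table")
        ks_D, ks_p = float(ks_D), float(ks_p)
    else:
        raise ValueError("ks_method must be 'fitted' or 'lilliefors'")
    return PairedTestResult(
        component=component,
        n=n,
        t=float(t),
        df=df,
        p=float(p),
        dz=cohens_dz(t, n),
        mean_diff=float(d.mean()),
        ks_D=ks_D,
        ks_p=ks_p,
    )


def component_table(
    diffs: pd.DataFrame,
    windows: list[ComponentWindow],
    ks_method: str = "fitted",
) -> pd.DataFrame:
    """Per-component summary: window, per-condition grand means, paired test."""
    amps = mean_amplitudes(diffs, windows)
    rows = []
    for win in windows:
        res = paired_component_test(amps, win.label, ks_method=ks_method)
        sub = amps[amps["component"] == win.label]
        means = sub.groupby("condition", observed=True)["amplitude_uv"].mean()
        rows.append(
            {
                "component": win.label,
                "start_ms": win.start_ms,
                "end_ms": win.end_ms,
                "peak_ms": win.peak_latency_ms,
                "mean_approaching_uv": float(means["approaching"]),
                "mean_receding_uv": float(means["receding"]),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "dz": res.dz,
                "ks_D": res.ks_D,
                "ks_p": res.ks_p,
            }
        )
    return pd.DataFrame(rows)
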