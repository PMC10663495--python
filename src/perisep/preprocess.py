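"""From trial-level epochs to the contrast series the statistics act on.

The chain is: (optional channel-cluster averaging) -> baseline correction
-> artifact rejection by peak-to-peak amplitude -> per-cell subject
averages -> Touch minus No-Touch difference waves -> the per-subject
approaching-minus-receding contrast restricted to the analysis window.
Every step is linear in the amplitudes, so averaging and differencing
commute and scaling the input scales every derived waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from perisep.synthetic_data import CONDITIONS, TRIAL_TYPES

_TRIAL_KEYS = ["subject", "condition", "trial_type", "trial"]
_CELL_KEYS = ["subject", "condition", "trial_type"]

DEFAULT_BASELINE = (-100.0, 0.0)
DEFAULT_WINDOW = (-100.0, 900.0)


@dataclass(frozen=True)
class ContrastSeries:
    """Per-subject (Touch-NoTouch)_approaching - (Touch-NoTouch)_receding waveforms.

    ``data`` has one row per subject on the time grid ``times_ms`` of the
    analysis window.
    """

    subjects: tuple[str, ...]
    ages: np.ndarray
    times_ms: np.ndarray
    data: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.subjects), self.times_ms.size):
            raise ValueError("data shape must be (n_subjects, n_times)")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def dt_ms(self) -> float:
        return float(np.median(np.diff(self.times_ms)))

    @property
    def fs(self) -> float:
        return 1000.0 / self.dt_ms


def _combined_codes(epochs: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, pd.DataFrame]:
    """Encode a column tuple as one integer per row plus the sorted unique tuples.

    Lets per-trial and per-cell reductions run through ``np.bincount``
    instead of multi-key groupbys, which dominates runtime on large
    epoch tables.
    """
    codes = np.zeros(len(epochs), dtype=np.int64)
    uniques = {}
    for col in cols:
        c, u = pd.factorize(epochs[col], sort=True)
        if (c < 0).any():
            raise ValueError(f"missing values in column '{col}'")
        codes = codes * len(u) + c
        uniques[col] = u
    sizes = [len(uniques[c]) for c in cols]
    grid = np.indices(sizes).reshape(len(cols), -1)
    combos = pd.DataFrame(
        {col: uniques[col][grid[k]] for k, col in enumerate(cols)}
    )
    return codes, combos


def _grid(epochs: pd.DataFrame) -> np.ndarray:
    return np.sort(epochs["time_ms"].unique())


def _on_grid(value: float, times: np.ndarray, tol: float = 1e-6) -> bool:
    return bool(np.any(np.isclose(times, value, atol=tol)))


def average_channels(epochs: pd.DataFrame, channels: list | None = None) -> pd.DataFrame:
    """Average a channel cluster if a ``channel`` column is present.

    The paper-style analyses run on amplitudes already averaged over a
    small cluster of somatosensory electrodes; this pre-step performs that
    averaging when single-channel data are supplied.
    """
    if "channel" not in epochs.columns:
        return epochs
    df = epochs
    if channels is not None:
        df = df[df["channel"].isin(channels)]
        if df.empty:
            raise ValueError("no rows left after selecting channels")
    keys = [c for c in df.columns if c not in ("channel", "amplitude_uv")]
    out = df.groupby(keys, sort=False, observed=True, as_index=False)["amplitude_uv"].mean()
    return out


def baseline_correct(
    epochs: pd.DataFrame, baseline: tuple[float, float] = DEFAULT_BASELINE
) -> pd.DataFrame:
    """Subtract each trial's mean amplitude over the baseline interval.

    The interval is closed on grid points; the default is the 100 ms
    preceding tactile onset.
    """
    a, b = baseline
    if a > b:
        raise ValueError("baseline interval must be increasing")
    times = _grid(epochs)
    mask = (epochs["time_ms"] >= a - 1e-9) & (epochs["time_ms"] <= b + 1e-9)
    if a < times.min() - 1e-9 or b > times.max() + 1e-9 or not mask.any():
        raise ValueError("baseline interval outside the epoch or empty on the grid")
    codes, _ = _combined_codes(epochs, _TRIAL_KEYS)
    n_codes = int(codes.max()) + 1
    m = mask.to_numpy()
    amp = epochs["amplitude_uv"].to_numpy()
    counts = np.bincount(codes[m], minlength=n_codes)
    present = np.bincount(codes, minlength=n_codes) > 0
    if (present & (counts == 0)).any():
        raise ValueError("some trials have no samples in the baseline interval")
    sums = np.bincount(codes[m], weights=amp[m], minlength=n_codes)
    bl = np.zeros(n_codes)
    bl[counts > 0] = sums[counts > 0] / counts[counts > 0]
    out = epochs.copy()
    out["amplitude_uv"] = amp - bl[codes]
    return out


def reject_epochs(
    epochs: pd.DataFrame, peak_to_peak_uv: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials whose peak-to-peak amplitude exceeds a threshold.

    Returns the retained epochs and a per-cell rejection log
    (subject, condition, trial_type, n_rejected, n_kept).  An automated
    surrogate for visual artifact screening.
    """
    if not peak_to_peak_uv > 0:
        raise ValueError("peak_to_peak_uv must be positive")
    stats = epochs.groupby(_TRIAL_KEYS, sort=False, observed=True)["amplitude_uv"].agg(
        ["max", "min"]
    )
    ptp = stats["max"] - stats["min"]
    bad = ptp[ptp > peak_to_peak_uv].index
    bad_flags = pd.Series(True, index=bad, name="_bad")
    out = epochs.merge(
        bad_flags, left_on=_TRIAL_KEYS, right_index=True, how="left"
    )
    kept = out[out["_bad"].isna()].drop(columns="_bad").reset_index(drop=True)

    per_trial = ptp.rename("ptp").reset_index()
    per_trial["rejected"] = per_trial["ptp"] > peak_to_peak_uv
    log = (
        per_trial.groupby(_CELL_KEYS, sort=True, observed=True)["rejected"]
        .agg(n_rejected="sum", n_total="count")
        .reset_index()
    )
    log["n_kept"] = log["n_total"] - log["n_rejected"]
    empty = log[log["n_kept"] == 0]
    if not empty.empty:
        cell = empty.iloc[0]
        raise ValueError(
            "rejection emptied cell "
            f"(subject={cell['subject']}, condition={cell['condition']}, "
            f"trial_type={cell['trial_type']})"
        )
    return kept, log.drop(columns="n_total")


def _check_crossing(cells: pd.DataFrame) -> None:
    for subject, grp in cells.groupby("subject", sort=False, observed=True):
        have = set(zip(grp["condition"], grp["trial_type"]))
        need = {(c, t) for c in CONDITIONS for t in TRIAL_TYPES}
        if have != need:
            missing = sorted(need - have)
            raise ValueError(f"subject {subject} missing cells: {missing}")


def subject_averages(epochs: pd.DataFrame) -> pd.DataFrame:
    """Average trials within each (subject, condition, trial_type) cell.

    Returns a long table with one waveform per cell plus the number of
    trials averaged.
    """
    keys = _CELL_KEYS + ["time_ms"]
    has_age = "age_days" in epochs.columns
    codes, combos = _combined_codes(epochs, keys)
    n_codes = len(combos)
    amp = epochs["amplitude_uv"].to_numpy()
    counts = np.bincount(codes, minlength=n_codes)
    sums = np.bincount(codes, weights=amp, minlength=n_codes)
    present = counts > 0
    out = combos.loc[present].reset_index(drop=True)
    out["amplitude_uv"] = sums[present] / counts[present]

    # the grid is common iff every present cell covers every present time
    per_cell = present.reshape(-1, combos["time_ms"].nunique())
    cell_present = per_cell.any(axis=1)
    if not np.all(per_cell[cell_present]):
        raise ValueError("cells do not share a common time grid")

    n_trials = (
        epochs.groupby(_CELL_KEYS, sort=True, observed=True)["trial"]
        .nunique()
        .rename("n_trials")
    )
    out = out.merge(n_trials, left_on=_CELL_KEYS, right_index=True)
    if has_age:
        ages = epochs.groupby("subject", sort=True, observed=True)["age_days"].first()
        out = out.merge(ages.rename("age_days"), left_on="subject", right_index=True)
    _check_crossing(out[_CELL_KEYS].drop_duplicates())
    return out


def difference_waves(avgs: pd.DataFrame) -> pd.DataFrame:
    """Touch minus No-Touch waveform per subject and condition.

    Removes activity driven purely by the visual stimulation, which is
    common to both trial types.
    """
    for tt in TRIAL_TYPES:
        if tt not in set(avgs["trial_type"]):
            raise ValueError(f"trial_type '{tt}' missing from averages")
    keys = ["subject", "condition", "time_ms"]
    touch = avgs[avgs["trial_type"] == "touch"].set_index(keys)["amplitude_uv"]
    no_touch = avgs[avgs["trial_type"] == "no_touch"].set_index(keys)["amplitude_uv"]
    diff = (touch - no_touch).rename("amplitude_uv")
    if diff.isna().any():
        raise ValueError("touch and no_touch grids do not align")
    out = diff.reset_index()
    if "age_days" in avgs.columns:
        ages = avgs.groupby("subject", sort=True, observed=True)["age_days"].first()
        out = out.merge(ages.rename("age_days"), left_on="subject", right_index=True)
    return out


def condition_contrast(
    diffs: pd.DataFrame, window: tuple[float, float] = DEFAULT_WINDOW
) -> ContrastSeries:
    """Approaching minus receding difference wave per subject, in a window.

    The window is closed on grid points; its endpoints must lie on the
    sampling grid.
    """
    a, b = window
    if a > b:
        raise ValueError("window must be increasing")
    times = _grid(diffs)
    if not (_on_grid(a, times) and _on_grid(b, times)):
        raise ValueError("window endpoints must lie on the time grid")
    for cond in CONDITIONS:
        if cond not in set(diffs["condition"]):
            raise ValueError(f"condition '{cond}' missing from difference waves")
    sel = diffs[(diffs["time_ms"] >= a - 1e-9) & (diffs["time_ms"] <= b + 1e-9)]
    wide = sel.pivot_table(
        index="subject",
        columns=["condition", "time_ms"],
        values="amplitude_uv",
        observed=True,
    )
    t_grid = times[(times >= a - 1e-9) & (times <= b + 1e-9)]
    appr = wide["approaching"].loc[:, t_grid].to_numpy()
    rec = wide["receding"].loc[:, t_grid].to_numpy()
    if np.isnan(appr).any() or np.isnan(rec).any():
        raise ValueError("incomplete condition coverage inside the window")
    subjects = tuple(wide.index)
    if "age_days" in diffs.columns:
        ages = (
            diffs.groupby("subject", sort=True, observed=True)["age_days"]
            .first()
            .loc[list(subjects)]
            .to_numpy(dtype=float)
        )
    else:
        ages = np.full(len(subjects), np.nan)
    return ContrastSeries(
        subjects=subjects,
        ages=ages,
        times_ms=t_grid.astype(float),
        data=appr - rec,
        window=(float(a), float(b)),
    )
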