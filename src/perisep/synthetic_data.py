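"""Synthetic multi-subject SEP epoch generator.

Emulates the structure of an infant tactile-ERP study: two visual-motion
conditions (``approaching`` / ``receding``) crossed with two trial types
(``touch`` / ``no_touch``), ~10 artifact-free trials per cell, 500 Hz
sampling, epochs from -300 to 1300 ms around tactile onset.  Each trial is
a sum of condition-independent visual components, a somatosensory response
present only on touch trials and multiplicatively modulated by condition
(and, optionally, linearly by age in days), a constant per-subject offset,
and stationary AR(1) noise.  Because the ground truth is known, every
downstream stage of the pipeline can be tested against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("approaching", "receding")
TRIAL_TYPES = ("touch", "no_touch")

EPOCH_COLUMNS = [
    "subject",
    "age_days",
    "condition",
    "trial_type",
    "trial",
    "time_ms",
    "amplitude_uv",
]


@dataclass(frozen=True)
class ComponentTemplate:
    """A Gaussian deflection: signed peak amplitude at a latency, with SD width."""

    peak_latency_ms: float
    width_ms: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    def evaluate(self, times_ms: np.ndarray) -> np.ndarray:
        z = (np.asarray(times_ms, dtype=float) - self.peak_latency_ms) / self.width_ms
        return self.amplitude_uv * np.exp(-0.5 * z * z)


def template_sum(times_ms: np.ndarray, components: Sequence[ComponentTemplate]) -> np.ndarray:
    """Evaluate the summed component waveform on a time grid (µV)."""
    out = np.zeros_like(np.asarray(times_ms, dtype=float))
    for c in components:
        out += c.evaluate(times_ms)
    return out


@dataclass(frozen=True)
class SimConfig:
    """Free parameters of the epoch generator.

    ``effect_gain`` multiplies the SEP templates on touch trials in the
    approaching condition (receding is the reference, gain 1).  For cohorts
    with a developmental trend, ``age_effect_slope`` (1/day) tilts the gain
    linearly around the midpoint of ``age_days_range``.
    """

    n_subjects: int = 20
    trials_per_cell: int = 10
    fs: float = 500.0
    epoch_start_ms: float = -300.0
    epoch_end_ms: float = 1300.0
    phi: float = 0.8
    noise_sd: float = 4.0
    subject_sd: float = 2.0
    visual_components: tuple[ComponentTemplate, ...] = ()
    sep_components: tuple[ComponentTemplate, ...] = ()
    effect_gain: float = 1.0
    age_days_range: tuple[float, float] = (109.0, 137.0)
    age_effect_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (self.epoch_start_ms < 0.0 < self.epoch_end_ms):
            raise ValueError("epoch must straddle tactile onset (start < 0 < end)")
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1 for a stationary AR(1)")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.age_days_range[0] > self.age_days_range[1]:
            raise ValueError("age_days_range must be increasing")
        dt = 1000.0 / self.fs
        span = self.epoch_end_ms - self.epoch_start_ms
        n = span / dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch bounds must lie on the sampling grid (1000/fs ms)")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        n = int(round((self.epoch_end_ms - self.epoch_start_ms) / self.dt_ms)) + 1
        return self.epoch_start_ms + self.dt_ms * np.arange(n)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "SimConfig":
        d = json.loads(text)
        for key in ("visual_components", "sep_components"):
            d[key] = tuple(ComponentTemplate(**c) for c in d[key])
        d["age_days_range"] = tuple(d["age_days_range"])
        return SimConfig(**d)


def ar1_series(
    n_points: int,
    phi: float,
    sd: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw stationary AR(1) series x_t = phi*x_{t-1} + eps_t, eps ~ N(0, sd^2).

    The initial value is drawn from the stationary distribution
    N(0, sd^2/(1-phi^2)).  Draw order is fixed (first the initial values,
    then the innovations row-wise) so a run is reproducible from the
    generator state alone.

    Parameters
    ----------
    n_points : length of each series.
    phi : lag-1 coefficient, |phi| < 1.
    sd : innovation standard deviation (µV).
    rng : numpy Generator supplying the randomness.
    size : if given, return ``size`` independent series as a
        ``(size, n_points)`` array; otherwise a 1-D array.
    """
    if not abs(phi) < 1:
        raise ValueError("|phi| must be < 1 for a stationary AR(1)")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    m = 1 if size is None else int(size)
    stat_sd = sd / np.sqrt(1.0 - phi * phi)
    x0 = rng.standard_normal(m) * stat_sd
    out = np.empty((m, n_points))
    out[:, 0] = x0
    if n_points > 1:
        eps = rng.standard_normal((m, n_points - 1)) * sd
        # recursion via scipy.signal.lfilter would also work; the explicit
        # cumulative form keeps the draw order contract obvious
        from scipy.signal import lfilter

        out[:, 1:], _ = lfilter([1.0], [1.0, -phi], eps, axis=1, zi=(phi * x0)[:, None])
    return out[0] if size is None else out


def _condition_effect(cfg: SimConfig, condition: str, age_days: float) -> float:
    if condition == "receding":
        return 1.0
    mid_age = 0.5 * (cfg.age_days_range[0] + cfg.age_days_range[1])
    return cfg.effect_gain + cfg.age_effect_slope * (age_days - mid_age)


def generate_epochs(config: SimConfig) -> pd.DataFrame:
    """Generate a long-format epoch table for one simulated cohort.

    Fixing ``config.seed`` fixes the output byte for byte.  One master
    seed sequence spawns an independent stream per subject, so enlarging
    ``n_subjects`` leaves existing subjects' data unchanged.
    """
    times = config.times_ms
    n_t = times.size
    visual = template_sum(times, config.visual_components)
    sep = template_sum(times, config.sep_components)

    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_subjects)

    n_trials = config.trials_per_cell
    n_subj = config.n_subjects
    cell_rows = n_trials * n_t
    subj_rows = len(CONDITIONS) * len(TRIAL_TYPES) * cell_rows

    amps = []
    ages = np.empty(n_subj)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        lo, hi = config.age_days_range
        age = float(rng.integers(int(lo), int(hi) + 1)) if hi > lo else float(lo)
        ages[i] = age
        offset = rng.normal(0.0, config.subject_sd) if config.subject_sd > 0 else 0.0
        for condition in CONDITIONS:
            eff = _condition_effect(config, condition, age)
            for trial_type in TRIAL_TYPES:
                mean_wave = visual + offset
                if trial_type == "touch":
                    mean_wave = mean_wave + eff * sep
                noise = ar1_series(n_t, config.phi, config.noise_sd, rng, size=n_trials)
                amps.append((mean_wave[None, :] + noise).ravel())

    subjects = [f"s{i + 1:02d}" for i in range(n_subj)]
    subj_codes = np.repeat(np.arange(n_subj), subj_rows)
    cond_codes = np.tile(np.repeat([0, 1], 2 * cell_rows), n_subj)
    tt_codes = np.tile(np.repeat([0, 1], cell_rows), 2 * n_subj)
    return pd.DataFrame(
        {
            "subject": pd.Categorical.from_codes(subj_codes, subjects),
            "age_days": np.repeat(ages, subj_rows),
            "condition": pd.Categorical.from_codes(cond_codes, list(CONDITIONS)),
            "trial_type": pd.Categorical.from_codes(tt_codes, list(TRIAL_TYPES)),
            "trial": np.tile(np.repeat(np.arange(1, n_trials + 1), n_t), 4 * n_subj),
            "time_ms": np.tile(times, 4 * n_trials * n_subj),
            "amplitude_uv": np.concatenate(amps),
        }
    )


def preset_4mo(seed: int = 0) -> SimConfig:
    """Default configuration for the 4-month cohort.

    20 subjects, 10 trials per cell, 500 Hz, epochs -300..1300 ms, ages
    109-137 days.  SEP components alternate in polarity between ~280 and
    ~660 ms; the approaching condition scales them by a constant gain with
    no age trend.
    """
    return SimConfig(
        n_subjects=20,
        trials_per_cell=10,
        fs=500.0,
        epoch_start_ms=-300.0,
        epoch_end_ms=1300.0,
        phi=0.8,
        noise_sd=4.0,
        subject_sd=2.0,
        visual_components=(
            ComponentTemplate(100.0, 30.0, 3.0),
            ComponentTemplate(180.0, 40.0, -2.0),
        ),
        sep_components=(
            ComponentTemplate(286.0, 45.0, 6.0),
            ComponentTemplate(398.0, 35.0, -5.0),
            ComponentTemplate(506.0, 45.0, 5.0),
            ComponentTemplate(560.0, 30.0, -4.0),
            ComponentTemplate(662.0, 40.0, 3.5),
        ),
        effect_gain=1.8,
        age_days_range=(109.0, 137.0),
        age_effect_slope=0.0,
        seed=seed,
    )


def preset_8mo(seed: int = 0) -> SimConfig:
    """Default configuration for the 8-month cohort.

    Ages 230-257 days.  The condition gain is 1 at the middle of the age
    range and tilts by 0.05 per day, so the condition effect reverses sign
    from the youngest to the oldest subjects.
    """
    return SimConfig(
        n_subjects=20,
        trials_per_cell=10,
        fs=500.0,
        epoch_start_ms=-300.0,
        epoch_end_ms=1300.0,
        phi=0.8,
        noise_sd=4.0,
        subject_sd=2.0,
        visual_components=(
            ComponentTemplate(100.0, 30.0, 3.0),
            ComponentTemplate(180.0, 40.0, -2.0),
        ),
        sep_components=(
            ComponentTemplate(240.0, 40.0, 5.0),
            ComponentTemplate(362.0, 40.0, -5.0),
            ComponentTemplate(470.0, 45.0, 4.5),
            ComponentTemplate(572.0, 40.0, -4.0),
        ),
        effect_gain=1.0,
        age_days_range=(230.0, 257.0),
        age_effect_slope=0.05,
        seed=seed,
    )


def write_epochs(epochs: pd.DataFrame, path) -> None:
    """Write an epoch table as delimited text with the canonical header."""
    epochs.loc[:, EPOCH_COLUMNS].to_csv(path, index=False)


def read_epochs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epoch table missing columns: {missing}")
    for col in ("subject", "condition", "trial_type"):
        df[col] = df[col].astype("category")
    return df
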