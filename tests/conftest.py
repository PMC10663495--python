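import dataclasses

import numpy as np
import pandas as pd
import pytest

from perisep import (
    ComponentTemplate,
    SimConfig,
    ContrastSeries,
    baseline_correct,
    condition_contrast,
    difference_waves,
    generate_epochs,
    subject_averages,
)


@pytest.fixture
def small_config() -> SimConfig:
    """A fast, short-epoch configuration for structural tests."""
    return SimConfig(
        n_subjects=4,
        trials_per_cell=3,
        fs=500.0,
        epoch_start_ms=-100.0,
        epoch_end_ms=300.0,
        phi=0.5,
        noise_sd=1.0,
        subject_sd=0.5,
        visual_components=(ComponentTemplate(50.0, 20.0, 2.0),),
        sep_components=(ComponentTemplate(150.0, 30.0, 4.0),),
        effect_gain=1.5,
        age_days_range=(109.0, 137.0),
        seed=7,
    )


@pytest.fixture
def noise_free_config(small_config) -> SimConfig:
    return dataclasses.replace(small_config, noise_sd=0.0, subject_sd=0.0)


def contrast_from_array(data: np.ndarray, dt_ms: float = 2.0, t0: float = 0.0,
                        ages=None) -> ContrastSeries:
    """Wrap a (n_subjects, n_points) array as a ContrastSeries."""
    n_subj, n_pts = data.shape
    times = t0 + dt_ms * np.arange(n_pts)
    return ContrastSeries(
        subjects=tuple(f"s{i + 1:02d}" for i in range(n_subj)),
        ages=np.full(n_subj, np.nan) if ages is None else np.asarray(ages, float),
        times_ms=times,
        data=np.asarray(data, dtype=float),
        window=(float(times[0]), float(times[-1])),
    )


def pipeline_diffs(config: SimConfig, baseline: bool = True) -> pd.DataFrame:
    """Epochs -> (baseline) -> averages -> difference waves."""
    epochs = generate_epochs(config)
    if baseline:
        epochs = baseline_correct(epochs)
    return difference_waves(subject_averages(epochs))


def pipeline_contrast(config: SimConfig, window=(-100.0, 300.0 - 100.0),
                      baseline: bool = True) -> ContrastSeries:
    return condition_contrast(pipeline_diffs(config, baseline), window)
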