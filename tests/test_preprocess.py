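import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perisep import (
    baseline_correct,
    condition_contrast,
    difference_waves,
    generate_epochs,
    reject_epochs,
    subject_averages,
)
from perisep.synthetic_data import template_sum
from conftest import pipeline_contrast, pipeline_diffs


def make_epochs(waves: dict, times: np.ndarray, trials: int = 1) -> pd.DataFrame:
    """Build a tiny epoch table; ``waves`` maps (subject, cond, tt) -> waveform
    or (subject, cond, tt, trial) -> waveform."""
    rows = []
    for key, wave in waves.items():
        if len(key) == 3:
            keys = [key + (k,) for k in range(1, trials + 1)]
        else:
            keys = [key]
        for subject, cond, tt, trial in keys:
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "age_days": 120.0,
                        "condition": cond,
                        "trial_type": tt,
                        "trial": trial,
                        "time_ms": times,
                        "amplitude_uv": np.asarray(wave, dtype=float),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


TIMES = np.arange(-100.0, 101.0, 2.0)


def full_crossing(wavefun, trials=1) -> pd.DataFrame:
    waves = {}
    for s in ("s01", "s02"):
        for c in ("approaching", "receding"):
            for t in ("touch", "no_touch"):
                for k in range(1, trials + 1):
                    waves[(s, c, t, k)] = wavefun(s, c, t, k)
    return make_epochs(waves, TIMES)


class TestBaselineCorrect:
    def test_constant_trial_becomes_zero(self):
        ep = full_crossing(lambda *a: np.full(TIMES.size, 5.0))
        out = baseline_correct(ep, (-100.0, 0.0))
        assert np.allclose(out["amplitude_uv"], 0.0)

    def test_idempotent(self):
        ep = full_crossing(lambda s, c, t, k: np.sin(TIMES / 30.0) + 2.0)
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        np.testing.assert_allclose(
            once["amplitude_uv"].to_numpy(), twice["amplitude_uv"].to_numpy()
        )

    def test_linear_ramp_shifted_by_closed_form_mean(self):
        a, b = 1.5, 0.02
        ep = full_crossing(lambda *args: a + b * TIMES)
        out = baseline_correct(ep, (-100.0, 0.0))
        bl_times = TIMES[(TIMES >= -100.0) & (TIMES <= 0.0)]
        m = a + b * bl_times.mean()  # closed-form mean of the ramp
        np.testing.assert_allclose(
            out["amplitude_uv"].to_numpy(),
            ep["amplitude_uv"].to_numpy() - m,
        )

    def test_baseline_outside_epoch_rejected(self):
        ep = full_crossing(lambda *a: np.zeros(TIMES.size) + 1)
        with pytest.raises(ValueError):
            baseline_correct(ep, (-500.0, -200.0))


class TestRejectEpochs:
    def test_infinite_threshold_is_identity(self, small_config):
        ep = generate_epochs(small_config)
        kept, log = reject_epochs(ep, np.inf)
        assert len(kept) == len(ep)
        assert log["n_rejected"].sum() == 0

    def test_spike_trial_dropped_exactly(self):
        def wave(s, c, t, k):
            w = np.zeros(TIMES.size)
            if (s, c, t, k) == ("s01", "approaching", "touch", 2):
                w[10] = 10_000.0
            return w + np.linspace(0, 1, TIMES.size)

        ep = full_crossing(wave, trials=3)
        kept, log = reject_epochs(ep, 200.0)
        assert log["n_rejected"].sum() == 1
        gone = kept[
            (kept["subject"] == "s01")
            & (kept["condition"] == "approaching")
            & (kept["trial_type"] == "touch")
        ]["trial"].unique()
        assert sorted(gone) == [1, 3]

    def test_empirical_percentile_threshold_drops_that_fraction(self, small_config):
        cfg = dataclasses.replace(small_config, trials_per_cell=25, n_subjects=5)
        ep = generate_epochs(cfg)
        ptp = (
            ep.groupby(["subject", "condition", "trial_type", "trial"], observed=True)[
                "amplitude_uv"
            ].agg(lambda x: x.max() - x.min())
        )
        thr = float(np.percentile(ptp, 90))
        kept, log = reject_epochs(ep, thr)
        assert log["n_rejected"].sum() == int((ptp > thr).sum())
        assert log["n_rejected"].sum() / len(ptp) == pytest.approx(0.1, abs=0.02)

    def test_emptied_cell_raises_with_cell_name(self):
        ep = full_crossing(lambda s, *a: np.linspace(0, 300 if s == "s01" else 1, TIMES.size))
        with pytest.raises(ValueError, match="s01"):
            reject_epochs(ep, 100.0)


class TestSubjectAverages:
    def test_single_trial_average_is_the_trial(self):
        ep = full_crossing(lambda s, c, t, k: np.sin(TIMES / 25.0))
        avgs = subject_averages(ep)
        cell = avgs[
            (avgs["subject"] == "s01")
            & (avgs["condition"] == "approaching")
            & (avgs["trial_type"] == "touch")
        ].sort_values("time_ms")
        np.testing.assert_allclose(cell["amplitude_uv"].to_numpy(), np.sin(TIMES / 25.0))
        assert (avgs["n_trials"] == 1).all()

    def test_mean_of_constant_trials(self):
        ep = full_crossing(lambda s, c, t, k: np.full(TIMES.size, float(2 * (k - 1))), trials=2)
        avgs = subject_averages(ep)
        assert np.allclose(avgs["amplitude_uv"], 1.0)
        assert (avgs["n_trials"] == 2).all()

    def test_missing_cell_raises(self):
        ep = full_crossing(lambda *a: np.zeros(TIMES.size))
        ep = ep[~((ep["subject"] == "s02") & (ep["trial_type"] == "no_touch"))]
        with pytest.raises(ValueError, match="s02"):
            subject_averages(ep)

    def test_average_tracks_template_within_standard_error(self):
        import perisep

        cfg = perisep.SimConfig(
            n_subjects=1,
            trials_per_cell=10_000,
            epoch_start_ms=-20.0,
            epoch_end_ms=80.0,
            phi=0.6,
            noise_sd=1.0,
            subject_sd=0.0,
            visual_components=(perisep.ComponentTemplate(30.0, 20.0, 2.0),),
            sep_components=(perisep.ComponentTemplate(50.0, 15.0, 3.0),),
            effect_gain=1.0,
            seed=17,
        )
        ep = generate_epochs(cfg)
        avgs = subject_averages(ep)
        cell = avgs[
            (avgs["condition"] == "approaching") & (avgs["trial_type"] == "touch")
        ].sort_values("time_ms")
        t = cell["time_ms"].to_numpy()
        expected = template_sum(t, cfg.visual_components) + template_sum(
            t, cfg.sep_components
        )
        se = (cfg.noise_sd / np.sqrt(1 - cfg.phi**2)) / np.sqrt(cfg.trials_per_cell)
        assert np.max(np.abs(cell["amplitude_uv"].to_numpy() - expected)) < 3 * se


class TestDifferenceWaves:
    def test_touch_equals_no_touch_gives_zero(self):
        ep = full_crossing(lambda s, c, t, k: np.cos(TIMES / 40.0))
        diffs = difference_waves(subject_averages(ep))
        assert np.allclose(diffs["amplitude_uv"], 0.0)

    def test_recovers_added_signal_exactly(self):
        s_t = np.exp(-((TIMES - 50.0) ** 2) / 800.0)

        def wave(s, c, t, k):
            base = np.sin(TIMES / 20.0)
            return base + s_t if t == "touch" else base

        diffs = difference_waves(subject_averages(full_crossing(wave)))
        for _, g in diffs.groupby(["subject", "condition"], observed=True):
            np.testing.assert_allclose(
                g.sort_values("time_ms")["amplitude_uv"].to_numpy(), s_t, atol=1e-12
            )

    def test_missing_trial_type_raises(self):
        ep = full_crossing(lambda *a: np.zeros(TIMES.size))
        avgs = subject_averages(ep)
        with pytest.raises(ValueError):
            difference_waves(avgs[avgs["trial_type"] == "touch"])


class TestConditionContrast:
    def test_identical_conditions_give_zero_series(self):
        ep = full_crossing(lambda s, c, t, k: (t == "touch") * np.sin(TIMES / 10.0))
        con = condition_contrast(
            difference_waves(subject_averages(ep)), (-100.0, 100.0)
        )
        assert np.allclose(con.data, 0.0)

    def test_default_window_has_501_points_at_500_hz(self, small_config):
        cfg = dataclasses.replace(
            small_config, epoch_start_ms=-300.0, epoch_end_ms=1300.0
        )
        con = pipeline_contrast(cfg, window=(-100.0, 900.0))
        assert con.times_ms.size == 501
        assert con.fs == pytest.approx(500.0)

    def test_antisymmetric_effects_double_in_contrast(self):
        s_t = np.exp(-((TIMES - 20.0) ** 2) / 500.0)

        def wave(s, c, t, k):
            sign = 1.0 if c == "approaching" else -1.0
            return sign * s_t if t == "touch" else np.zeros(TIMES.size)

        con = condition_contrast(
            difference_waves(subject_averages(full_crossing(wave))), (-100.0, 100.0)
        )
        np.testing.assert_allclose(con.data, np.tile(2 * s_t, (2, 1)), atol=1e-12)

    def test_off_grid_window_rejected(self):
        ep = full_crossing(lambda *a: np.ones(TIMES.size))
        diffs = difference_waves(subject_averages(ep))
        with pytest.raises(ValueError, match="grid"):
            condition_contrast(diffs, (-99.0, 100.0))


class TestLinearity:
    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(c=st.floats(min_value=-5.0, max_value=5.0, allow_nan=False).filter(lambda v: abs(v) > 1e-3))
    def test_scaling_amplitudes_scales_contrast(self, c):
        ep = full_crossing(
            lambda s, cond, t, k: np.sin(TIMES / 15.0) + (t == "touch") * (cond == "approaching") * 1.0
        )
        base = condition_contrast(difference_waves(subject_averages(ep)), (-100.0, 100.0))
        scaled = ep.copy()
        scaled["amplitude_uv"] = scaled["amplitude_uv"] * c
        out = condition_contrast(
            difference_waves(subject_averages(scaled)), (-100.0, 100.0)
        )
        np.testing.assert_allclose(out.data, c * base.data, atol=1e-10)

    def test_averaging_and_differencing_commute(self, small_config):
        ep = generate_epochs(small_config)
        diffs = difference_waves(subject_averages(ep))
        # independent route: per-trial touch-minus-no_touch, then average
        wide = ep.pivot_table(
            index=["subject", "condition", "trial", "time_ms"],
            columns="trial_type",
            values="amplitude_uv",
            observed=True,
        )
        per_trial = (wide["touch"] - wide["no_touch"]).rename("d").reset_index()
        manual = (
            per_trial.groupby(["subject", "condition", "time_ms"], observed=True)["d"]
            .mean()
            .reset_index()
        )
        merged = diffs.merge(manual, on=["subject", "condition", "time_ms"])
        np.testing.assert_allclose(
            merged["amplitude_uv"].to_numpy(), merged["d"].to_numpy(), atol=1e-10
        )
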