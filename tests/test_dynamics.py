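"""Trial windows, per-trial activation/FC, task contrasts, r-to-p."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from faupa import (
    compare_tasks,
    group_mean,
    make_default_paradigm,
    paired_coactivation,
    r_to_p,
    trial_activation,
    trial_fc,
    trial_mean_by_task,
    trial_windows,
)
from faupa.paradigm import TaskParadigm, Trial


class TestTrialWindows:
    def test_default_partition(self, paradigm):
        w = trial_windows(paradigm)
        assert w.n_trials == 24
        assert set(w.n_samples) == {12}
        assert (w.starts[0], w.ends[0]) == (0, 12)
        # contiguous, non-overlapping cover of the run
        assert list(w.starts[1:]) == list(w.ends[:-1])
        assert w.ends[-1] == 288

    def test_misaligned_onset_rejected(self):
        p = TaskParadigm(trials=(Trial(1.3, 6, "WR"),), tr_s=2.5, n_timepoints=288)
        with pytest.raises(ValueError, match="multiple of TR"):
            trial_windows(p)

    def test_lag_shifts_windows(self, paradigm):
        w = trial_windows(paradigm, lag_trs=2)
        assert (w.starts[1], w.ends[1]) == (14, 26)


class TestTrialActivation:
    def test_constant_one_percent_gives_one(self, paradigm):
        w = trial_windows(paradigm)
        np.testing.assert_allclose(trial_activation(np.ones(288), w), 1.0)

    def test_quadratic_scaling(self, paradigm):
        rng = np.random.default_rng(0)
        ts = rng.standard_normal(288)
        w = trial_windows(paradigm)
        np.testing.assert_allclose(
            trial_activation(3.0 * ts, w), 9.0 * trial_activation(ts, w),
            rtol=1e-12,
        )

    def test_windows_partition_the_total_mean_square(self, paradigm):
        rng = np.random.default_rng(1)
        ts = rng.standard_normal(288)
        w = trial_windows(paradigm)
        act = trial_activation(ts, w)
        weights = np.array(w.n_samples) / 288
        assert np.sum(act * weights) == pytest.approx(
            np.mean(ts**2), rel=1e-10
        )

    def test_short_series_rejected(self, paradigm):
        with pytest.raises(ValueError):
            trial_activation(np.ones(100), trial_windows(paradigm))


class TestTrialFC:
    def test_self_and_negated_series(self, paradigm):
        rng = np.random.default_rng(2)
        ts = rng.standard_normal(288)
        w = trial_windows(paradigm)
        np.testing.assert_allclose(trial_fc(ts, ts, w), 1.0, atol=1e-12)
        np.testing.assert_allclose(trial_fc(ts, -ts, w), -1.0, atol=1e-12)

    def test_values_bounded(self, paradigm):
        rng = np.random.default_rng(3)
        w = trial_windows(paradigm)
        fc = trial_fc(rng.standard_normal(288), rng.standard_normal(288), w)
        assert np.all(fc >= -1.0) and np.all(fc <= 1.0)

    def test_zero_variance_window_flagged_nan(self, paradigm):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(288)
        b = rng.standard_normal(288)
        b[:12] = 5.0  # first trial window flat
        w = trial_windows(paradigm)
        with pytest.warns(UserWarning, match="zero variance"):
            fc = trial_fc(a, b, w)
        assert np.isnan(fc[0])
        assert not np.isnan(fc[1:]).any()


class TestTaskMeans:
    def test_constant_values(self, paradigm):
        st_ = trial_mean_by_task(np.ones(24), paradigm, "FT")
        assert (st_.mean, st_.sd, st_.n) == (1.0, 0.0, 8)

    def test_task_selective_values(self, paradigm):
        vals = np.zeros(24)
        vals[list(paradigm.task_trial_indices("FT"))] = 2.0
        assert trial_mean_by_task(vals, paradigm, "FT").mean == 2.0
        assert trial_mean_by_task(vals, paradigm, "WR").mean == 0.0

    def test_undefined_entries_excluded_and_counted(self, paradigm):
        vals = np.ones(24)
        vals[paradigm.task_trial_indices("FT")[0]] = np.nan
        st_ = trial_mean_by_task(vals, paradigm, "FT")
        assert (st_.n, st_.n_undefined) == (7, 1)
        assert st_.mean == 1.0

    def test_unknown_task_rejected(self, paradigm):
        with pytest.raises(ValueError):
            trial_mean_by_task(np.ones(24), paradigm, "XX")


class TestCompareTasks:
    def test_identical_samples_two_tail_p_one(self, paradigm):
        vals = np.ones(24)
        t, p = compare_tasks(vals + 0.0, paradigm, "FT", "WR", tail="two")
        assert np.isnan(t) or p == pytest.approx(1.0)

    def test_clear_difference_one_tail(self, paradigm):
        vals = np.zeros(24)
        vals[list(paradigm.task_trial_indices("FT"))] = 10.0
        rng = np.random.default_rng(5)
        vals += 0.01 * rng.standard_normal(24)
        t, p = compare_tasks(vals, paradigm, "FT", "WR", tail="one")
        assert t > 0 and p < 0.01

    def test_single_value_per_side_rejected(self, paradigm):
        vals = np.full(24, np.nan)
        vals[0] = 1.0  # one WR value
        vals[2] = 2.0  # one FT value
        with pytest.raises(ValueError):
            compare_tasks(vals, paradigm, "FT", "WR")


class TestPairedCoactivation:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(6)
        series = [rng.standard_normal(288) for _ in range(4)]
        r = paired_coactivation(series)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)

    def test_independent_noise_stays_low(self):
        """Null |R| at N = 288 stays well below 0.2."""
        rng = np.random.default_rng(7)
        series = [rng.standard_normal(288) for _ in range(10)]
        r = paired_coactivation(series)
        off = r[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_zero_variance_series_rejected(self):
        with pytest.raises(ValueError):
            paired_coactivation([np.ones(288), np.arange(288.0)])


class TestRtoP:
    def test_zero_r_gives_p_one(self):
        assert r_to_p(0.0, 100, "t") == pytest.approx(1.0)
        assert r_to_p(0.0, 100, "normal") == pytest.approx(1.0)

    def test_t_convention_agrees_with_numeric_integration(self):
        """Cross-check the closed-form t tail against brute-force numeric
        integration of the t density at (r=0.5864, n=12)."""
        r, n = 0.5864, 12
        p = r_to_p(r, n, "t")
        tval = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        grid = np.linspace(tval, 200.0, 2_000_001)
        tail = np.trapezoid(stats.t.pdf(grid, df=n - 2), grid)
        assert p == pytest.approx(2 * tail, abs=1e-4)

    @given(
        r=st.floats(0.05, 0.95),
        dr=st.floats(0.01, 0.04),
        n=st.integers(10, 500),
        convention=st.sampled_from(["t", "normal"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_r_and_n(self, r, dr, n, convention):
        assert r_to_p(r + dr, n, convention) < r_to_p(r, n, convention)
        assert r_to_p(r, 2 * n, convention) < r_to_p(r, n, convention)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_to_p(1.0, 100)
        with pytest.raises(ValueError):
            r_to_p(0.5, 2, "t")
        with pytest.raises(ValueError):
            r_to_p(0.5, 100, "bogus")


class TestGroupMean:
    def test_single_subject_passthrough_with_nan_sem(self):
        vals = np.arange(24.0)
        with pytest.warns(UserWarning, match="single subject"):
            mean, sem = group_mean([vals])
        np.testing.assert_array_equal(mean, vals)
        assert np.isnan(sem).all()

    def test_identical_subjects_have_zero_sem(self):
        vals = np.arange(24.0)
        mean, sem = group_mean([vals] * 9)
        np.testing.assert_array_equal(mean, vals)
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)

    def test_within_subject_units_averaged_first(self):
        # subject A: two units averaging to 2; subject B: one unit at 4
        a = np.vstack([np.full(24, 1.0), np.full(24, 3.0)])
        b = np.full(24, 4.0)
        mean, _ = group_mean([a, b])
        np.testing.assert_allclose(mean, 3.0)

    def test_mismatched_trial_counts_rejected(self):
        with pytest.raises(ValueError):
            group_mean([np.ones(24), np.ones(20)])
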