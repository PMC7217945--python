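"""Trial-by-trial network dynamics: activation, connectivity, contrasts.

Per-trial activation of a FAUPA is the mean of its squared percent signal
changes over the trial window (the full 30-s trial: task period plus the
following rest), motivated by the BOLD magnitude scaling as roughly the
square root of the underlying neural response — squaring puts the measure
on a neural-activity-like scale (%^2).  Per-trial functional connectivity
is the Pearson correlation of two FAUPA time courses within the window.
Trial means, one/two-tailed task contrasts, full-run paired co-activation
and analytic correlation p-values complete the toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .paradigm import TaskParadigm


@dataclass(frozen=True)
class TrialWindows:
    """Half-open per-trial index ranges [start, end) into the time axis."""

    starts: tuple[int, ...]
    ends: tuple[int, ...]

    @property
    def n_trials(self) -> int:
        return len(self.starts)

    @property
    def n_samples(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in zip(self.starts, self.ends))

    def slices(self) -> list[slice]:
        return [slice(s, e) for s, e in zip(self.starts, self.ends)]


def trial_windows(paradigm: TaskParadigm, lag_trs: int = 0) -> TrialWindows:
    """Partition the run into per-trial windows.

    Window k runs from trial k's onset to trial k+1's onset (the last to
    the end of the run), covering the full task + rest period contiguously
    and without overlap.  ``lag_trs`` shifts every window by a fixed number
    of TRs to account for hemodynamic delay if desired (default 0: the
    window already contains the evoked response).  Onsets must fall on the
    TR grid.
    """
    bounds = []
    for t in paradigm.trials:
        b = t.onset_s / paradigm.tr_s
        if abs(b - round(b)) > 1e-6:
            raise ValueError(f"trial onset {t.onset_s}s is not a multiple of TR")
        bounds.append(int(round(b)) + lag_trs)
    bounds.append(paradigm.n_timepoints + lag_trs)
    starts = tuple(max(0, b) for b in bounds[:-1])
    ends = tuple(min(paradigm.n_timepoints, b) for b in bounds[1:])
    if any(e <= s for s, e in zip(starts, ends)):
        raise ValueError("lag pushes a trial window outside the run")
    return TrialWindows(starts=starts, ends=ends)


def trial_activation(pct_ts: np.ndarray, windows: TrialWindows) -> np.ndarray:
    """Per-trial activation: mean squared percent change per window (%^2)."""
    pct_ts = np.asarray(pct_ts, dtype=float)
    if pct_ts.shape[-1] < max(windows.ends):
        raise ValueError("series shorter than the last trial window")
    return np.array([np.mean(pct_ts[..., sl] ** 2) for sl in windows.slices()])


def trial_fc(ts_a: np.ndarray, ts_b: np.ndarray, windows: TrialWindows) -> np.ndarray:
    """Per-trial functional connectivity: Pearson R within each window.

    A window where either series has zero variance yields NaN (flagged via
    a warning), never a silent 0.
    """
    ts_a = np.asarray(ts_a, dtype=float)
    ts_b = np.asarray(ts_b, dtype=float)
    if ts_a.shape != ts_b.shape:
        raise ValueError("series lengths differ")
    if ts_a.shape[-1] < max(windows.ends):
        raise ValueError("series shorter than the last trial window")
    if min(windows.n_samples) < 3:
        raise ValueError("trial windows need at least 3 samples for correlation")
    out = np.empty(windows.n_trials)
    for k, sl in enumerate(windows.slices()):
        a, b = ts_a[sl], ts_b[sl]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            warnings.warn(f"zero variance in trial window {k}; FC undefined", stacklevel=2)
            out[k] = np.nan
        else:
            out[k] = np.corrcoef(a, b)[0, 1]
    return out


@dataclass(frozen=True)
class TaskTrialStats:
    """Mean +/- sd of a per-trial quantity over one task's trials."""

    task: str
    mean: float
    sd: float
    n: int
    n_undefined: int


def trial_mean_by_task(
    values_per_trial: np.ndarray,
    paradigm: TaskParadigm,
    task: str,
    fisher_z: bool = False,
) -> TaskTrialStats:
    """Mean and sd of a per-trial quantity over the trials of one task.

    Raw values are averaged by default (set ``fisher_z`` to average
    correlations on the z scale and transform back).  NaN (undefined)
    entries are excluded and counted.
    """
    values = np.asarray(values_per_trial, dtype=float)
    if len(values) != paradigm.n_trials:
        raise ValueError("need exactly one value per trial")
    idx = list(paradigm.task_trial_indices(task))
    vals = values[idx]
    defined = vals[~np.isnan(vals)]
    n_undef = int(np.isnan(vals).sum())
    if len(defined) == 0:
        return TaskTrialStats(task, float("nan"), float("nan"), 0, n_undef)
    if fisher_z:
        z = np.arctanh(np.clip(defined, -1 + 1e-15, 1 - 1e-15))
        mean = float(np.tanh(z.mean()))
        sd = float(np.tanh(z.std(ddof=1))) if len(defined) > 1 else 0.0
    else:
        mean = float(defined.mean())
        sd = float(defined.std(ddof=1)) if len(defined) > 1 else 0.0
    return TaskTrialStats(task, mean, sd, len(defined), n_undef)


def compare_tasks(
    values_per_trial: np.ndarray,
    paradigm: TaskParadigm,
    task_a: str,
    task_b: str,
    tail: str = "two",
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test between two tasks' per-trial values.

    ``tail="one"`` tests task_a > task_b; ``"two"`` is two-sided.  Classic
    equal-variance test by default; Welch via ``equal_var=False``.
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    values = np.asarray(values_per_trial, dtype=float)
    if len(values) != paradigm.n_trials:
        raise ValueError("need exactly one value per trial")
    a = values[list(paradigm.task_trial_indices(task_a))]
    b = values[list(paradigm.task_trial_indices(task_b))]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 defined values per task")
    alternative = "greater" if tail == "one" else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def paired_coactivation(series: list[np.ndarray]) -> np.ndarray:
    """Full-run Pearson correlation matrix among FAUPA(-pair) mean series."""
    if len(series) < 2:
        raise ValueError("need at least 2 series")
    arr = np.vstack(series)
    if np.any(arr.std(axis=-1) == 0):
        raise ValueError("zero-variance series in co-activation table")
    return np.corrcoef(arr)


def r_to_p(r: float, n: int, convention: str = "t") -> float:
    """Two-sided p-value for a Pearson correlation.

    convention "t": exact null test, t = r sqrt(n-2) / sqrt(1-r^2) on n-2
    degrees of freedom (requires n >= 3) — the default for inference.
    convention "normal": two-sided tail of z = r sqrt(n) under the standard
    normal; an asymptotic form that matches the large-N p-values printed in
    the field's reports (requires n >= 1).
    """
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    if convention == "t":
        if n < 3:
            raise ValueError("t convention needs n >= 3")
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        return float(2 * stats.t.sf(abs(t), df=n - 2))
    if convention == "normal":
        if n < 1:
            raise ValueError("normal convention needs n >= 1")
        z = abs(r) * np.sqrt(n)
        return float(2 * stats.norm.sf(z))
    raise ValueError("convention must be 't' or 'normal'")


def group_mean(
    per_subject_values: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Group mean and SEM of a per-trial quantity across subjects.

    Each subject's input is either a 1D per-trial vector or a 2D
    (unit x trial) matrix, in which case the within-subject mean over units
    (FAUPAs or FAUPA pairs) is taken first; NaN entries are excluded
    within-subject.  With a single subject the SEM is NaN (flagged).
    """
    if not per_subject_values:
        raise ValueError("no subjects")
    rows = []
    for v in per_subject_values:
        v = np.asarray(v, dtype=float)
        if v.ndim == 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                v = np.nanmean(v, axis=0)
        elif v.ndim != 1:
            raise ValueError("per-subject values must be 1D or 2D")
        rows.append(v)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("subjects disagree on the number of trials")
    mat = np.vstack(rows)
    mean = np.nanmean(mat, axis=0)
    if len(rows) == 1:
        warnings.warn("single subject: SEM undefined", stacklevel=2)
        sem = np.full(mat.shape[1], np.nan)
    else:
        sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(mat), axis=0))
    return mean, sem
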