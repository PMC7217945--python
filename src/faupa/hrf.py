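"""Hemodynamic response modelling and ideal-response regressors.

The model BOLD response for a task-set ("category") is the task on/off
boxcar convolved with a canonical double-gamma hemodynamic response
function (HRF), sampled on the TR grid, truncated to the run length and
mean-centered.  Pearson correlations with such a regressor are invariant to
affine rescaling, so the mean-centered series is also the relative-signal-
change form up to a positive factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

from .paradigm import CATEGORIES, TASKS, TaskParadigm, category_name


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF shape (SPM-style defaults).

    Response peak at 6 s, undershoot peaking at 16 s with 1/6 the peak
    amplitude, unit dispersions, 32-s support.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0


@dataclass(frozen=True)
class HRFKernel:
    """Double-gamma impulse response sampled at TR resolution."""

    values: np.ndarray
    tr_s: float
    params: HRFParams

    def __len__(self) -> int:
        return len(self.values)


def _double_gamma(t: np.ndarray, p: HRFParams) -> np.ndarray:
    peak = _gamma_dist.pdf(t, a=p.peak_delay_s / p.peak_dispersion_s, scale=p.peak_dispersion_s)
    under = _gamma_dist.pdf(
        t, a=p.undershoot_delay_s / p.undershoot_dispersion_s, scale=p.undershoot_dispersion_s
    )
    return peak - p.undershoot_ratio * under


def hrf_kernel(tr_s: float, params: HRFParams | None = None) -> HRFKernel:
    """Sample the double-gamma HRF on the TR grid.

    The kernel is normalised to unit peak; its value at t = 0 is exactly 0
    and, with default parameters, its peak lies near 5 s.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    p = params or HRFParams()
    if p.length_s <= p.peak_delay_s:
        raise ValueError("kernel length must exceed the peak delay")
    t = np.arange(0.0, p.length_s, tr_s)
    h = _double_gamma(t, p)
    h = h / np.max(np.abs(h))
    return HRFKernel(values=h, tr_s=tr_s, params=p)


@dataclass(frozen=True)
class IdealResponse:
    """Mean-centered model response for one task-association category."""

    category: tuple[str, ...]
    values: np.ndarray
    paradigm: TaskParadigm

    @property
    def name(self) -> str:
        return category_name(self.category)

    def percent_form(self) -> np.ndarray:
        """Relative-signal-change form: 100 * (x - mean) / mean of the raw
        (baseline 1) response.  Provided for plotting; correlations do not
        depend on this rescaling."""
        raw = self.values - self.values.min() + 1.0
        return 100.0 * (raw - raw.mean()) / raw.mean()


def task_boxcar(
    paradigm: TaskParadigm,
    task_set: Sequence[str],
    trial_multipliers: Mapping[int, float] | Sequence[float] | None = None,
) -> np.ndarray:
    """On/off indicator on the TR grid: 1 during each included task's task
    period, 0 elsewhere, optionally scaled per trial.

    A TR sample at time ``i*tr`` is "on" when it falls inside
    ``[onset, onset + duration)``.
    """
    task_set = tuple(task_set)
    if not task_set:
        raise ValueError("task_set must be non-empty")
    for task in task_set:
        if task not in TASKS:
            raise ValueError(f"unknown task label {task!r}")
    box = np.zeros(paradigm.n_timepoints)
    t = np.arange(paradigm.n_timepoints) * paradigm.tr_s
    for k, trial in enumerate(paradigm.trials):
        if trial.task not in task_set:
            continue
        scale = 1.0
        if trial_multipliers is not None:
            scale = float(trial_multipliers[k])
        on = (t >= trial.onset_s - 1e-9) & (t < trial.onset_s + trial.duration_s - 1e-9)
        box[on] = scale
    return box


def convolve_boxcar(
    box: np.ndarray, kernel: HRFKernel, n_timepoints: int, circular: bool = False
) -> np.ndarray:
    """Convolve a boxcar with the HRF kernel on the TR grid.

    Linear convolution truncated to the run length by default; the circular
    variant wraps the response around the run and is exactly symmetric under
    cyclic shifts of the paradigm (useful for symmetry checks).
    """
    if circular:
        k = np.zeros(len(box))
        nk = min(len(kernel.values), len(box))
        k[:nk] = kernel.values[:nk]
        return np.real(np.fft.ifft(np.fft.fft(box) * np.fft.fft(k)))
    return np.convolve(box, kernel.values)[:n_timepoints]


def build_ideal_response(
    paradigm: TaskParadigm,
    task_set: Sequence[str],
    kernel: HRFKernel | None = None,
    circular: bool = False,
) -> IdealResponse:
    """Construct the mean-centered ideal response for a task-set.

    Composite categories use the same unit magnitude for every included
    task, so before centering the composite response equals the sum of its
    single-task responses.
    """
    kernel = kernel if kernel is not None else hrf_kernel(paradigm.tr_s)
    if abs(kernel.tr_s - paradigm.tr_s) > 1e-9:
        raise ValueError(
            f"kernel TR ({kernel.tr_s}) does not match paradigm TR ({paradigm.tr_s})"
        )
    box = task_boxcar(paradigm, task_set)
    resp = convolve_boxcar(box, kernel, paradigm.n_timepoints, circular=circular)
    resp = resp - resp.mean()
    cat = tuple(t for t in TASKS if t in tuple(task_set))
    return IdealResponse(category=cat, values=resp, paradigm=paradigm)


def build_all_ideal_responses(
    paradigm: TaskParadigm, kernel: HRFKernel | None = None, circular: bool = False
) -> dict[tuple[str, ...], IdealResponse]:
    """Ideal responses for all seven categories, keyed by category tuple."""
    kernel = kernel if kernel is not None else hrf_kernel(paradigm.tr_s)
    return {
        cat: build_ideal_response(paradigm, cat, kernel, circular=circular)
        for cat in CATEGORIES
    }


def ideal_response_correlation_table(
    paradigm: TaskParadigm | None = None,
    kernel: HRFKernel | None = None,
    circular: bool = False,
) -> pd.DataFrame:
    """7x7 Pearson correlation table among the category ideal responses.

    Rows/columns ordered WR, PV, FT, WR_PV, WR_FT, PV_FT, WR_PV_FT.  With
    the default interleaved paradigm the maximum off-diagonal entry (pair
    vs. overlapping triple) is ~0.774, which motivates the 0.8 assignment
    threshold: no category regressor can be confused with another at that
    threshold.
    """
    from .paradigm import make_default_paradigm

    paradigm = paradigm or make_default_paradigm()
    responses = build_all_ideal_responses(paradigm, kernel, circular=circular)
    names = [category_name(c) for c in CATEGORIES]
    mat = np.corrcoef(np.vstack([responses[c].values for c in CATEGORIES]))
    return pd.DataFrame(mat, index=names, columns=names)


def composite_correlation_identities(r: float) -> dict[str, float]:
    """Closed-form composite correlations implied by the paradigm symmetry.

    If the three single-task regressors have equal variance and a common
    pairwise correlation ``r``, the correlations involving equal-magnitude
    sums follow from bilinearity of covariance:

    - single vs. a pair containing it:        sqrt((1 + r) / 2)
    - single vs. the disjoint-other pair:     2 r / sqrt(2 + 2 r)
    - pair vs. overlapping pair:              (1 + 3 r) / (2 + 2 r)
    - pair vs. the triple:                    (2 + 4 r) / sqrt((2 + 2 r) (3 + 6 r))
    - single vs. the triple:                  (1 + 2 r) / sqrt(3 + 6 r)
    """
    if not -0.5 < r < 1:
        raise ValueError("r must lie in (-0.5, 1) for the identities to be defined")
    return {
        "single_vs_own_pair": np.sqrt((1 + r) / 2),
        "single_vs_other_pair": 2 * r / np.sqrt(2 + 2 * r),
        "pair_vs_pair": (1 + 3 * r) / (2 + 2 * r),
        "pair_vs_triple": (2 + 4 * r) / np.sqrt((2 + 2 * r) * (3 + 6 * r)),
        "single_vs_triple": (1 + 2 * r) / np.sqrt(3 + 6 * r),
    }
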