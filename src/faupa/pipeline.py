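"""End-to-end analysis: preprocess -> detect -> associate -> dynamics.

`analyze_subject` is the in-memory pipeline used by the command line, by
cohort analyses and by the reproducibility script; it returns a
`SubjectResult` bundling every stage's output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associate import (
    CategoryAssignment,
    RepresentativeSet,
    TaskNetwork,
    build_networks,
    classify_faupas,
    select_representatives,
)
from .config import RunConfig
from .detect import FAUPA, detect_faupas
from .dynamics import (
    TrialWindows,
    trial_activation,
    trial_fc,
    trial_mean_by_task,
    trial_windows,
)
from .hrf import build_all_ideal_responses, hrf_kernel
from .paradigm import TASKS, TaskParadigm, category_name
from .preprocess import PercentChangeImage, preprocess


@dataclass
class SubjectResult:
    """Everything one subject's run produces."""

    pct: PercentChangeImage
    faupas: list[FAUPA]
    representatives: RepresentativeSet | None
    assignments: list[CategoryAssignment]
    networks: dict[str, TaskNetwork]
    windows: TrialWindows
    activation: pd.DataFrame  # FAUPA id x trial, %^2
    fc: pd.DataFrame  # pair label x trial, Pearson R
    warnings: list[str] = field(default_factory=list)

    def assignment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "faupa_id": [a.faupa_id for a in self.assignments],
                "category": [
                    category_name(a.category) if a.category else "none"
                    for a in self.assignments
                ],
                "r_to_representative": [a.r_to_representative for a in self.assignments],
                "r_to_ideal": [a.r_to_ideal for a in self.assignments],
            }
        )

    def category_members(self) -> dict[tuple[str, ...], list[int]]:
        out: dict[tuple[str, ...], list[int]] = {}
        for a in self.assignments:
            if a.category is not None:
                out.setdefault(a.category, []).append(a.faupa_id)
        return out


def analyze_subject(
    image4d: np.ndarray,
    paradigm: TaskParadigm,
    config: RunConfig | None = None,
    mask: np.ndarray | None = None,
) -> SubjectResult:
    """Run the full pipeline on one 4D acquisition."""
    config = config or RunConfig()
    if image4d.shape[-1] != paradigm.n_timepoints:
        raise ValueError(
            f"image has {image4d.shape[-1]} volumes but the paradigm expects "
            f"{paradigm.n_timepoints}"
        )
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        pc = config.preprocess
        pct = preprocess(
            image4d,
            tr_s=paradigm.tr_s,
            mask=mask,
            fwhm_mm=pc.fwhm_mm,
            voxel_size_mm=pc.voxel_size_mm,
            f_lo=pc.f_lo_hz,
            f_hi=pc.f_hi_hz,
            mask_fraction=pc.mask_fraction,
        )
        faupas = detect_faupas(pct, config.detection)

        kernel = hrf_kernel(paradigm.tr_s)
        ideals = build_all_ideal_responses(paradigm, kernel)
        representatives = None
        assignments: list[CategoryAssignment] = []
        if faupas:
            representatives = select_representatives(
                faupas, ideals, validation_r=config.association.validation_r
            )
            assignments = classify_faupas(
                faupas,
                representatives,
                r_threshold=config.association.r_threshold,
                multi_assign=config.association.multi_assign,
                ideal_responses=ideals,
            )
        networks = build_networks(assignments)

        windows = trial_windows(paradigm, lag_trs=config.dynamics.lag_trs)
        act_rows = {fa.id: trial_activation(fa.mean_ts, windows) for fa in faupas}
        activation = pd.DataFrame.from_dict(act_rows, orient="index")
        activation.index.name = "faupa_id"

        fc_rows: dict[str, np.ndarray] = {}
        by_cat = {}
        for a in assignments:
            if a.category is not None:
                by_cat.setdefault(a.category, []).append(a.faupa_id)
        ts_of = {fa.id: fa.mean_ts for fa in faupas}
        for cat, ids in by_cat.items():
            for i, ia in enumerate(ids):
                for ib in ids[i + 1 :]:
                    fc_rows[f"{ia}-{ib}"] = trial_fc(ts_of[ia], ts_of[ib], windows)
        fc = pd.DataFrame.from_dict(fc_rows, orient="index")
        fc.index.name = "pair"

        captured = [str(w.message) for w in wlist]

    return SubjectResult(
        pct=pct,
        faupas=faupas,
        representatives=representatives,
        assignments=assignments,
        networks=networks,
        windows=windows,
        activation=activation,
        fc=fc,
        warnings=captured,
    )


def task_contrast_table(
    result: SubjectResult, paradigm: TaskParadigm
) -> pd.DataFrame:
    """Trial-mean activation per task for every FAUPA (mean, sd per task)."""
    rows = []
    for fa in result.faupas:
        vals = result.activation.loc[fa.id].to_numpy()
        row: dict[str, float | int | str] = {"faupa_id": fa.id}
        for task in TASKS:
            st = trial_mean_by_task(vals, paradigm, task)
            row[f"{task}_mean"] = st.mean
            row[f"{task}_sd"] = st.sd
        rows.append(row)
    return pd.DataFrame(rows)
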