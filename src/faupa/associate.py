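"""Task association: categorise FAUPAs and assemble task-specific networks.

Each FAUPA is compared against seven model ("ideal") responses — one per
non-empty subset of the three tasks.  Per category, the best-matching FAUPA
becomes the *representative*, and its empirical time course (rather than
the model response) is the classification reference: this absorbs the
subject's idiosyncratic response shape.  A FAUPA joins a category when its
correlation with the representative exceeds the assignment threshold
(default 0.8, chosen above the maximum inter-category model correlation of
~0.774 so categories cannot be confused).  A task's network is the union of
the four categories containing that task.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .detect import FAUPA
from .hrf import IdealResponse
from .paradigm import CATEGORIES, TASKS, category_name
from .preprocess import PercentChangeImage

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.8
DEFAULT_MAP_THRESHOLD = 0.45


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance series in correlation")
    return float(a @ b / (na * nb))


@dataclass
class Representative:
    """Best-matching FAUPA for one category."""

    faupa_id: int
    timecourse: np.ndarray
    r_to_ideal: float
    below_validation: bool = False


@dataclass
class RepresentativeSet:
    by_category: dict[tuple[str, ...], Representative]

    def __getitem__(self, category: tuple[str, ...]) -> Representative:
        return self.by_category[category]


@dataclass
class CategoryAssignment:
    """One FAUPA's category call and the correlations behind it."""

    faupa_id: int
    category: tuple[str, ...] | None
    r_to_representative: float
    r_to_ideal: float = float("nan")


@dataclass
class TaskNetwork:
    """All FAUPAs associated with one task, grouped by contributing category."""

    task: str
    members: dict[tuple[str, ...], list[int]] = field(default_factory=dict)

    @property
    def faupa_ids(self) -> list[int]:
        return sorted(i for ids in self.members.values() for i in ids)

    @property
    def size(self) -> int:
        return len(self.faupa_ids)


def select_representatives(
    faupas: list[FAUPA],
    ideal_responses: dict[tuple[str, ...], IdealResponse],
    validation_r: float = DEFAULT_R_THRESHOLD,
) -> RepresentativeSet:
    """Per category, pick the FAUPA whose time course best matches the
    category's model response (argmax Pearson R).

    A representative whose match falls below ``validation_r`` is still
    selected but flagged and logged: downstream assignments to that
    category should be audited.
    """
    if not faupas:
        raise ValueError("no FAUPAs to select representatives from")
    reps: dict[tuple[str, ...], Representative] = {}
    for cat in CATEGORIES:
        ideal = ideal_responses[cat]
        rs = np.array([_corr(fa.mean_ts, ideal.values) for fa in faupas])
        best = int(np.argmax(rs))
        flagged = bool(rs[best] < validation_r)
        if flagged:
            warnings.warn(
                f"representative for {category_name(cat)} matches its ideal "
                f"response at R={rs[best]:.3f} < {validation_r}",
                stacklevel=2,
            )
        reps[cat] = Representative(
            faupa_id=faupas[best].id,
            timecourse=faupas[best].mean_ts.copy(),
            r_to_ideal=float(rs[best]),
            below_validation=flagged,
        )
    return RepresentativeSet(by_category=reps)


def classify_faupas(
    faupas: list[FAUPA],
    representatives: RepresentativeSet,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    multi_assign: bool = False,
    ideal_responses: dict[tuple[str, ...], IdealResponse] | None = None,
) -> list[CategoryAssignment]:
    """Assign each FAUPA the category of its best-matching representative.

    Default is single-label: argmax R over the seven representatives,
    assigned only when that R exceeds ``r_threshold`` (else ``None``).
    With ``multi_assign=True`` every category whose representative exceeds
    the threshold yields an assignment row (per-category thresholding,
    which can multiply-assign a FAUPA); provided for audit.
    """
    out: list[CategoryAssignment] = []
    for fa in faupas:
        rs = {
            cat: _corr(fa.mean_ts, representatives[cat].timecourse) for cat in CATEGORIES
        }
        if multi_assign:
            hit = False
            for cat in CATEGORIES:
                if rs[cat] > r_threshold:
                    hit = True
                    out.append(_assignment(fa, cat, rs[cat], ideal_responses))
            if not hit:
                out.append(_assignment(fa, None, max(rs.values()), ideal_responses))
        else:
            best = max(CATEGORIES, key=lambda c: rs[c])
            if rs[best] > r_threshold:
                out.append(_assignment(fa, best, rs[best], ideal_responses))
            else:
                out.append(_assignment(fa, None, rs[best], ideal_responses))
    return out


def _assignment(
    fa: FAUPA,
    cat: tuple[str, ...] | None,
    r: float,
    ideals: dict[tuple[str, ...], IdealResponse] | None,
) -> CategoryAssignment:
    r_ideal = float("nan")
    if ideals is not None and cat is not None:
        r_ideal = _corr(fa.mean_ts, ideals[cat].values)
    return CategoryAssignment(
        faupa_id=fa.id, category=cat, r_to_representative=float(r), r_to_ideal=r_ideal
    )


def build_networks(assignments: list[CategoryAssignment]) -> dict[str, TaskNetwork]:
    """Assemble the three task networks from category assignments.

    The network for task T collects the four categories containing T;
    unassigned FAUPAs are excluded.
    """
    nets = {task: TaskNetwork(task=task) for task in TASKS}
    for a in assignments:
        if a.category is None:
            continue
        for task in a.category:
            nets[task].members.setdefault(a.category, []).append(a.faupa_id)
    return nets


def correlation_map(
    pct: PercentChangeImage,
    reference_ts: np.ndarray,
    r_threshold: float = DEFAULT_MAP_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-by-voxel Pearson R against a reference time course.

    The reference may be a model (ideal) response — the GLM-style map — or
    a selected FAUPA's empirical time course.  Returns the 3D R map (NaN
    outside the mask) and the binary activation mask R > threshold.
    """
    reference_ts = np.asarray(reference_ts, dtype=float)
    if reference_ts.shape[-1] != pct.n_timepoints:
        raise ValueError("reference length does not match the image time axis")
    ref = reference_ts - reference_ts.mean()
    norm = np.linalg.norm(ref)
    if norm == 0:
        raise ValueError("reference has zero variance")
    ref = ref / norm
    series = pct.data[pct.mask]
    centered = series - series.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(centered, axis=-1)
    norms[norms == 0] = np.inf
    rvals = (centered @ ref) / norms
    rmap = np.full(pct.data.shape[:3], np.nan)
    rmap[pct.mask] = rvals
    act = np.zeros(pct.data.shape[:3], dtype=bool)
    act[pct.mask] = rvals > r_threshold
    return rmap, act
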