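"""Engagement indices for parents and cohorts.

Two indices summarize a parent's engagement:

* **PPP** (Parent Participation Profile) — the number of distinct activity
  *types* the parent attempted (nonzero frequency points), i.e. breadth;
* **PEI** (Parent Engagement Intensity) — the sum over attempted activities of
  frequency points × intensity factor, i.e. burden-weighted depth.

Because arms offered unequal activity sets, both indices are standardized by
the arm-specific maxima (``std_ppp = ppp / max_ppp`` and likewise for PEI),
yielding fractions in [0, 1] that are comparable across arms.  Program and
evaluation sub-scores split each index over the two activity categories; a
standardized sub-score is *missing* (not zero) when the arm offers nothing in
that category.

A parent whose standardized index meets or exceeds the positive-deviance
threshold (default 75%, inclusive) is classified a **positive deviant** (PD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import ArmCatalog, Catalog, frequency_points
from .errors import ValidationError
from .records import TIMEPOINTS, OutcomeRecord, ParentRecord

__all__ = [
    "EngagementScore",
    "CohortScores",
    "PD_THRESHOLD",
    "compute_score",
    "classify_positive_deviant",
    "score_cohort",
]

#: Standardized-index fraction at or above which a parent is a positive deviant.
PD_THRESHOLD = 0.75

PDBasis = Literal["ppp", "pei"]


@dataclass(frozen=True)
class EngagementScore:
    """PPP/PEI indices, standardized forms, category splits and PD flags."""

    parent_id: str
    ppp: int
    pei: int
    std_ppp: float
    std_pei: float
    program_ppp: int
    program_pei: int
    evaluation_ppp: int
    evaluation_pei: int
    std_program_ppp: Optional[float]
    std_program_pei: Optional[float]
    std_evaluation_ppp: Optional[float]
    std_evaluation_pei: Optional[float]
    pd_by_ppp: bool
    pd_by_pei: bool
    activity_points: dict[str, int]


def compute_score(
    record: ParentRecord,
    catalogs: Catalog,
    arm: ArmCatalog | None = None,
    pd_threshold: float = PD_THRESHOLD,
) -> EngagementScore:
    """Score one validated participation record against its arm catalog.

    ``arm`` may be passed explicitly (it must be the arm the record resolves
    to); by default it is looked up from the record's cohort and school.
    """
    resolved = catalogs.arm(record.cohort_id, record.school_id)
    if arm is not None and arm.key != resolved.key:
        raise ValidationError(
            f"record arm {resolved.key} does not match the supplied arm {arm.key}"
        )
    arm = resolved
    record.validate(catalogs)
    maxima = catalogs.arm_maxima(arm)

    points: dict[str, int] = {}
    ppp = pei = 0
    cat_ppp = {"program": 0, "evaluation": 0}
    cat_pei = {"program": 0, "evaluation": 0}
    for name in sorted(arm.offered):
        act = catalogs.activity(name)
        pts = frequency_points(act.frequency_rule, record.counts.get(name, 0))
        points[name] = pts
        if pts == 0:
            continue
        contrib = pts * act.intensity_factor
        ppp += 1
        pei += contrib
        cat_ppp[act.category] += 1
        cat_pei[act.category] += contrib

    std_ppp = ppp / maxima.max_ppp
    std_pei = pei / maxima.max_pei if maxima.max_pei else math.nan
    score = EngagementScore(
        parent_id=record.parent_id,
        ppp=ppp,
        pei=pei,
        std_ppp=std_ppp,
        std_pei=std_pei,
        program_ppp=cat_ppp["program"],
        program_pei=cat_pei["program"],
        evaluation_ppp=cat_ppp["evaluation"],
        evaluation_pei=cat_pei["evaluation"],
        std_program_ppp=_safe_div(cat_ppp["program"], maxima.program_ppp),
        std_program_pei=_safe_div(cat_pei["program"], maxima.program_pei),
        std_evaluation_ppp=_safe_div(cat_ppp["evaluation"], maxima.evaluation_ppp),
        std_evaluation_pei=_safe_div(cat_pei["evaluation"], maxima.evaluation_pei),
        pd_by_ppp=False,
        pd_by_pei=False,
        activity_points=points,
    )
    object.__setattr__(score, "pd_by_ppp", classify_positive_deviant(score, pd_threshold, "ppp"))
    object.__setattr__(score, "pd_by_pei", classify_positive_deviant(score, pd_threshold, "pei"))
    return score


def _safe_div(num: int, den: int) -> Optional[float]:
    # a category with nothing offered has no defined standardized sub-score
    return num / den if den else None


def classify_positive_deviant(
    score: EngagementScore, threshold: float = PD_THRESHOLD, basis: PDBasis = "ppp"
) -> bool:
    """True iff the chosen standardized index meets the threshold (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValidationError(f"PD threshold must lie in (0, 1], got {threshold}")
    if basis not in ("ppp", "pei"):
        raise ValidationError(f"PD basis must be 'ppp' or 'pei', got {basis!r}")
    value = score.std_ppp if basis == "ppp" else score.std_pei
    return bool(not math.isnan(value) and value >= threshold)


@dataclass
class CohortScores:
    """Per-parent score table plus a cohort-level summary block."""

    table: pd.DataFrame
    summary: dict


def score_cohort(
    records: Sequence[ParentRecord],
    outcomes: Sequence[OutcomeRecord] | None,
    catalogs: Catalog,
    pd_threshold: float = PD_THRESHOLD,
    pd_basis: PDBasis = "ppp",
) -> CohortScores:
    """Score every parent and join arm metadata and outcomes into one table.

    Parents appearing only in the outcomes table are retained with zero
    engagement (their arm is resolved through the outcome row's cohort when
    available); parents with no outcome row are retained for scoring only.
    """
    ids = [r.parent_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate parent_id in participation records: {dupes}")
    outcomes = outcomes or []
    out_ids = [o.parent_id for o in outcomes]
    if len(out_ids) != len(set(out_ids)):
        dupes = sorted({i for i in out_ids if out_ids.count(i) > 1})
        raise ValidationError(f"duplicate parent_id in outcomes: {dupes}")
    out_by_id = {o.parent_id: o for o in outcomes}

    all_records = list(records)
    scored_ids = set(ids)
    for o in outcomes:
        if o.parent_id in scored_ids:
            continue
        if o.cohort_id is not None:
            all_records.append(ParentRecord(o.parent_id, o.cohort_id, o.school_id, {}))
            scored_ids.add(o.parent_id)

    activity_names = sorted(catalogs.activities)
    rows = []
    for rec in all_records:
        arm = catalogs.arm(rec.cohort_id, rec.school_id)
        score = compute_score(rec, catalogs, pd_threshold=pd_threshold)
        out = out_by_id.get(rec.parent_id)
        row = {
            "parent_id": rec.parent_id,
            "cohort": rec.cohort_id,
            "school": rec.school_id,
            "treatment": arm.treatment,
            "classroom": out.classroom_id if out else None,
            "ppp": score.ppp,
            "pei": score.pei,
            "std_ppp": score.std_ppp,
            "std_pei": score.std_pei,
            "program_ppp": score.program_ppp,
            "program_pei": score.program_pei,
            "evaluation_ppp": score.evaluation_ppp,
            "evaluation_pei": score.evaluation_pei,
            "std_program_ppp": score.std_program_ppp,
            "std_program_pei": score.std_program_pei,
            "std_evaluation_ppp": score.std_evaluation_ppp,
            "std_evaluation_pei": score.std_evaluation_pei,
            "pd_by_ppp": score.pd_by_ppp,
            "pd_by_pei": score.pd_by_pei,
            "pd": score.pd_by_ppp if pd_basis == "ppp" else score.pd_by_pei,
        }
        for name in activity_names:
            pts = score.activity_points.get(name)
            row[f"pts_{name}"] = pts if name in arm.offered else None
        if out:
            for t, p in zip(TIMEPOINTS, out.bmi_percentile):
                row[f"bmi_percentile_{t}"] = p
            row["parent_bmi"] = out.parent_bmi
        else:
            for t in TIMEPOINTS:
                row[f"bmi_percentile_{t}"] = None
            row["parent_bmi"] = None
        rows.append(row)

    table = pd.DataFrame(rows)
    summary = _summarize(table, activity_names, pd_threshold, pd_basis)
    return CohortScores(table=table, summary=summary)


def _summarize(
    table: pd.DataFrame, activity_names: Iterable[str], pd_threshold: float, pd_basis: str
) -> dict:
    if table.empty:
        return {"n_parents": 0}
    engaged = table[table["ppp"] > 0]
    def _ms(col: pd.Series) -> dict:
        col = col.dropna()
        if col.empty:
            return {"mean": math.nan, "sd": math.nan, "n": 0}
        return {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            "n": int(len(col)),
        }

    return {
        "n_parents": int(len(table)),
        "n_engaged": int(len(engaged)),
        "pd_threshold": pd_threshold,
        "pd_basis": pd_basis,
        "n_pd": int(table["pd"].sum()),
        "n_pd_by_ppp": int(table["pd_by_ppp"].sum()),
        "n_pd_by_pei": int(table["pd_by_pei"].sum()),
        "std_ppp": _ms(table["std_ppp"]),
        "std_pei": _ms(table["std_pei"]),
        "std_ppp_engaged": _ms(engaged["std_ppp"]),
        "std_pei_engaged": _ms(engaged["std_pei"]),
        "activity_participation": {
            name: int((pd.to_numeric(table[f"pts_{name}"]) > 0).sum())
            for name in activity_names
        },
    }
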