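"""Reading, validating and normalizing participation logs and outcome tables.

Participation logs are tidy CSV — one row per parent × activity (× timepoint
for per-timepoint activities such as dietary recalls) with a raw count.  Rows
are validated against the parent's arm catalog: the activity must be offered
in that arm and the count must lie within the activity's declared maximum.
Invalid rows are not silently dropped; they are returned in a rejects table
with a reason, and accepted plus rejected rows always partition the input.

Outcome tables carry youth BMI percentile at up to three timepoints
(t0 = baseline, t1 = post-program, t2 = 12 months after baseline) together
with school/classroom identifiers and the treatment assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .catalog import Catalog, frequency_points
from .errors import CatalogLookupError, ValidationError

__all__ = [
    "ParentRecord",
    "OutcomeRecord",
    "TIMEPOINTS",
    "read_participation_csv",
    "write_participation_csv",
    "read_outcomes_csv",
    "write_outcomes_csv",
]

#: Ordered timepoint labels: baseline, post-program, 12 months after baseline.
TIMEPOINTS = ("t0", "t1", "t2")

CountValue = Union[int, tuple[int, ...]]


@dataclass(frozen=True)
class ParentRecord:
    """One parent's raw participation counts within an arm.

    ``counts`` maps activity name → raw count; for per-timepoint activities the
    value is a tuple with one entry per timepoint.  Activities absent from the
    map count as zero.
    """

    parent_id: str
    cohort_id: str
    school_id: str
    counts: Mapping[str, CountValue] = field(default_factory=dict)

    def validate(self, catalogs: Catalog) -> None:
        """Raise unless every keyed activity is offered in the arm with an
        admissible count."""
        arm = catalogs.arm(self.cohort_id, self.school_id)
        for name, count in self.counts.items():
            if name not in arm.offered:
                raise ValidationError(
                    f"parent {self.parent_id}: activity {name!r} is not offered "
                    f"in arm (cohort {self.cohort_id}, school {self.school_id})"
                )
            try:
                frequency_points(catalogs.activity(name).frequency_rule, count)
            except ValidationError as exc:
                raise ValidationError(
                    f"parent {self.parent_id}, activity {name!r}: {exc}"
                ) from None


@dataclass(frozen=True)
class OutcomeRecord:
    """Youth outcome and design metadata for one parent.

    BMI percentiles are percentile-for-age in the open interval (0, 100);
    missing timepoints are ``None``.  ``cohort_id`` is optional — when present
    it lets a parent with no participation rows be resolved to an arm.
    """

    parent_id: str
    school_id: str
    classroom_id: str
    treatment: str
    bmi_percentile: tuple[Optional[float], Optional[float], Optional[float]]
    parent_bmi: Optional[float] = None
    cohort_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "intervention"):
            raise ValidationError(
                f"parent {self.parent_id}: treatment must be 'control' or "
                f"'intervention', got {self.treatment!r}"
            )
        for label, p in zip(TIMEPOINTS, self.bmi_percentile):
            if p is not None and not 0 < p < 100:
                raise ValidationError(
                    f"parent {self.parent_id}: BMI percentile at {label} must lie "
                    f"in (0, 100), got {p}"
                )

    @property
    def missing_timepoints(self) -> tuple[str, ...]:
        return tuple(
            t for t, p in zip(TIMEPOINTS, self.bmi_percentile) if p is None
        )


# ---------------------------------------------------------------------------
# participation logs
# ---------------------------------------------------------------------------

PARTICIPATION_COLUMNS = ["parent_id", "cohort", "school", "activity", "timepoint", "count"]


def read_participation_csv(
    path: str | Path, catalogs: Catalog
) -> tuple[list[ParentRecord], pd.DataFrame]:
    """Read a tidy participation log and validate it against ``catalogs``.

    Returns ``(records, rejects)``: one :class:`ParentRecord` per parent built
    from the accepted rows, and a DataFrame of rejected rows with a ``reason``
    column.  An unknown cohort/school pair is an error (the log does not match
    the study design); a known arm with an un-offered activity or an
    out-of-range count is a per-row reject.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"parent_id", "cohort", "school", "activity", "count"} - set(df.columns)
    if missing:
        raise ValidationError(f"participation CSV missing columns {sorted(missing)}")
    if "timepoint" not in df.columns:
        df["timepoint"] = ""
    return _rows_to_records(df, catalogs)


def _rows_to_records(
    df: pd.DataFrame, catalogs: Catalog
) -> tuple[list[ParentRecord], pd.DataFrame]:
    reject_idx: list[int] = []
    reasons: list[str] = []
    # accumulate per (parent, cohort, school): activity -> scalar or per-tp dict
    acc: dict[tuple[str, str, str], dict[str, object]] = {}

    for idx, row in enumerate(df.itertuples(index=False)):
        cohort, school = str(row.cohort), str(row.school)
        try:
            arm = catalogs.arm(cohort, school)
        except CatalogLookupError as exc:
            raise ValidationError(f"row {idx}: {exc}") from None
        name = str(row.activity)
        if name not in arm.offered:
            reject_idx.append(idx)
            reasons.append(
                f"activity {name!r} not offered in arm (cohort {cohort}, school {school})"
            )
            continue
        rule = catalogs.activity(name).frequency_rule
        try:
            count = int(str(row.count))
            if count < 0:
                raise ValueError
        except ValueError:
            reject_idx.append(idx)
            reasons.append(f"count {row.count!r} is not a non-negative integer")
            continue
        tp = str(row.timepoint).strip()
        per_tp = rule.kind == "per_timepoint_binned"
        if per_tp and tp not in TIMEPOINTS:
            reject_idx.append(idx)
            reasons.append(
                f"activity {name!r} requires a timepoint in {TIMEPOINTS}, got {tp!r}"
            )
            continue
        if count > rule.max_raw:
            reject_idx.append(idx)
            reasons.append(
                f"count {count} for {name!r} exceeds the declared maximum {rule.max_raw}"
            )
            continue
        slot = acc.setdefault((str(row.parent_id), cohort, school), {})
        if per_tp:
            tp_map = slot.setdefault(name, {})
            tp_map[tp] = tp_map.get(tp, 0) + count  # type: ignore[union-attr]
            if tp_map[tp] > rule.max_raw:  # type: ignore[index]
                tp_map[tp] -= count  # type: ignore[index]
                reject_idx.append(idx)
                reasons.append(
                    f"accumulated count for {name!r} at {tp} exceeds {rule.max_raw}"
                )
        else:
            new = slot.get(name, 0) + count
            if new > rule.max_raw:
                reject_idx.append(idx)
                reasons.append(
                    f"accumulated count for {name!r} exceeds the declared "
                    f"maximum {rule.max_raw}"
                )
            else:
                slot[name] = new

    records = []
    for (pid, cohort, school), counts in acc.items():
        clean: dict[str, CountValue] = {}
        for name, val in counts.items():
            if isinstance(val, dict):
                vec = tuple(val.get(t, 0) for t in TIMEPOINTS)
                if any(vec):
                    clean[name] = vec
            elif val:
                clean[name] = val
        records.append(ParentRecord(pid, cohort, school, clean))

    rejects = df.iloc[reject_idx].copy()
    rejects["reason"] = reasons
    return records, rejects.reset_index(drop=True)


def write_participation_csv(records: Iterable[ParentRecord], path: str | Path) -> None:
    """Write records in the tidy layout accepted by :func:`read_participation_csv`."""
    rows = []
    for rec in records:
        for name, count in sorted(rec.counts.items()):
            if isinstance(count, tuple):
                for tp, c in zip(TIMEPOINTS, count):
                    if c:
                        rows.append(
                            (rec.parent_id, rec.cohort_id, rec.school_id, name, tp, c)
                        )
            elif count:
                rows.append((rec.parent_id, rec.cohort_id, rec.school_id, name, "", count))
    pd.DataFrame(rows, columns=PARTICIPATION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# outcome tables
# ---------------------------------------------------------------------------

OUTCOME_COLUMNS = [
    "parent_id", "cohort", "school", "classroom", "treatment",
    "bmi_percentile_t0", "bmi_percentile_t1", "bmi_percentile_t2", "parent_bmi",
]


def read_outcomes_csv(path: str | Path) -> list[OutcomeRecord]:
    """Read an outcomes table; empty optional cells become missing values."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"parent_id", "school", "classroom", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"outcomes CSV missing columns {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        perc = tuple(
            _opt_float(row.get(f"bmi_percentile_{t}", "")) for t in TIMEPOINTS
        )
        records.append(
            OutcomeRecord(
                parent_id=str(row["parent_id"]),
                school_id=str(row["school"]),
                classroom_id=str(row["classroom"]),
                treatment=str(row["treatment"]),
                bmi_percentile=perc,  # type: ignore[arg-type]
                parent_bmi=_opt_float(row.get("parent_bmi", "")),
                cohort_id=str(row["cohort"]) if str(row.get("cohort", "")).strip() else None,
            )
        )
    return records


def write_outcomes_csv(records: Iterable[OutcomeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "parent_id": rec.parent_id,
                "cohort": rec.cohort_id or "",
                "school": rec.school_id,
                "classroom": rec.classroom_id,
                "treatment": rec.treatment,
                **{
                    f"bmi_percentile_{t}": ("" if p is None else p)
                    for t, p in zip(TIMEPOINTS, rec.bmi_percentile)
                },
                "parent_bmi": "" if rec.parent_bmi is None else rec.parent_bmi,
            }
        )
    pd.DataFrame(rows, columns=OUTCOME_COLUMNS).to_csv(path, index=False)


def _opt_float(value: str) -> Optional[float]:
    value = str(value).strip()
    if not value:
        return None
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"expected a number or empty cell, got {value!r}") from None
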