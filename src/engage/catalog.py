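"""Activity catalogs: burden-derived intensity factors, frequency-point rules, and
per-arm offerings.

The scoring schema quantifies how much effort a parent put into an engagement
activity.  Each activity type carries

* a :class:`BurdenProfile` — five effort attributes (was participation
  incentivized, did it require leaving home, did it involve the child, how long
  did one episode take, was personal information requested) from which an
  integer *intensity factor* in 0..5 is derived; and
* a :class:`FrequencyRule` — how raw participation counts convert to
  *frequency points* (one point per occasion, or a binned scale for
  high-frequency items such as take-home action packs).

An activity's *weighting* is its maximum frequency points times its intensity
factor; in the canonical Fuel-for-Fun catalog every one of the eight activities
has weighting 6, so a parent offered all eight can score at most 48 intensity
points.

Arms (cohort × school cells of the study) offered unequal subsets of the
activities, so every index is standardized by arm-specific maxima computed
here by :func:`arm_maxima`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence, Union

from .errors import CatalogLookupError, ConfigError, ValidationError

__all__ = [
    "BurdenProfile",
    "FrequencyRule",
    "ActivityType",
    "ArmCatalog",
    "ArmMaxima",
    "Catalog",
    "intensity_factor",
    "frequency_points",
    "max_weighting",
    "build_default_catalogs",
    "CANONICAL_ACTIVITIES",
]

#: Names of the eight canonical activities, program first, then evaluation.
CANONICAL_ACTIVITIES = (
    "family_fun_nights",
    "action_packs",
    "recipes",
    "about_eating",
    "surveys",
    "parent_diet",
    "youth_diet",
    "accelerometry",
)

#: Episode duration (hours) at or above which an activity earns a burden credit.
DURATION_CREDIT_HOURS = 0.5

CATEGORIES = ("program", "evaluation")


@dataclass(frozen=True)
class BurdenProfile:
    """Five effort attributes of an activity.

    ``incentivized`` *removes* a credit (compensated effort is cheaper for the
    parent); the other four attributes each *add* one when present.  Internet
    activities done at home count as not away from home.
    """

    incentivized: bool
    away_from_home: bool
    involves_child: bool
    duration_hours: float
    personal_info: bool

    def __post_init__(self) -> None:
        if self.duration_hours < 0:
            raise ValidationError(
                f"duration_hours must be non-negative, got {self.duration_hours}"
            )


def intensity_factor(burden: BurdenProfile) -> int:
    """Burden score in 0..5 for one activity.

    One credit for being unpaid, one each for leaving home, involving the
    child, taking at least 30 minutes (``duration_hours >= 0.5``), and
    requesting personal information.
    """
    return (
        (0 if burden.incentivized else 1)
        + (1 if burden.away_from_home else 0)
        + (1 if burden.involves_child else 0)
        + (1 if burden.duration_hours >= DURATION_CREDIT_HOURS else 0)
        + (1 if burden.personal_info else 0)
    )


Bin = tuple[int, int, int]  # (lo, hi, points), inclusive raw-count range


@dataclass(frozen=True)
class FrequencyRule:
    """Conversion from raw participation counts to frequency points.

    kinds
        ``per_occasion``
            one point per occasion, up to ``max_occasions`` (e.g. 3 surveys,
            6 online lessons);
        ``binned``
            a total raw count maps through ordered ``bins`` of
            ``(lo, hi, points)`` (e.g. 1–3 action packs → 1 point,
            4–6 → 2, 7–10 → 3);
        ``per_timepoint_binned``
            the binned scale applies independently at each of ``timepoints``
            measurement waves and the per-wave points are summed (dietary
            recalls: 1 recall → 1 point, 2 or 3 recalls → 2 points, at each
            of 3 timepoints).
    """

    kind: str
    max_occasions: int | None = None
    bins: tuple[Bin, ...] | None = None
    timepoints: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("per_occasion", "binned", "per_timepoint_binned"):
            raise ConfigError(f"unknown frequency rule kind {self.kind!r}")
        if self.kind == "per_occasion":
            if not isinstance(self.max_occasions, int) or self.max_occasions < 1:
                raise ConfigError("per_occasion rule needs a positive max_occasions")
            if self.bins is not None or self.timepoints is not None:
                raise ConfigError("per_occasion rule takes no bins/timepoints")
            return
        if not self.bins:
            raise ConfigError(f"{self.kind} rule needs non-empty bins")
        object.__setattr__(self, "bins", tuple(tuple(b) for b in self.bins))
        self._validate_bins()
        if self.kind == "per_timepoint_binned":
            if not isinstance(self.timepoints, int) or self.timepoints < 1:
                raise ConfigError("per_timepoint_binned rule needs positive timepoints")
        elif self.timepoints is not None:
            raise ConfigError("binned rule takes no timepoints")

    def _validate_bins(self) -> None:
        # contiguity, coverage from 1, non-overlap, monotone points
        prev_hi, prev_pts = 0, 0
        for lo, hi, pts in self.bins:  # type: ignore[union-attr]
            if lo != prev_hi + 1:
                raise ConfigError(
                    f"bins must be contiguous from 1: bin starts at {lo}, "
                    f"expected {prev_hi + 1}"
                )
            if hi < lo:
                raise ConfigError(f"empty bin ({lo}, {hi})")
            if pts < prev_pts:
                raise ConfigError("bin points must be non-decreasing")
            prev_hi, prev_pts = hi, pts

    @property
    def max_raw(self) -> int:
        """Largest admissible raw count (per timepoint for per-timepoint rules)."""
        if self.kind == "per_occasion":
            return self.max_occasions  # type: ignore[return-value]
        return self.bins[-1][1]  # type: ignore[index]

    @property
    def max_points(self) -> int:
        """Maximum attainable frequency points under this rule."""
        if self.kind == "per_occasion":
            return self.max_occasions  # type: ignore[return-value]
        top = self.bins[-1][2]  # type: ignore[index]
        if self.kind == "per_timepoint_binned":
            return top * self.timepoints  # type: ignore[operator]
        return top

    def _bin_points(self, count: int) -> int:
        if count == 0:
            return 0
        for lo, hi, pts in self.bins:  # type: ignore[union-attr]
            if lo <= count <= hi:
                return pts
        raise ValidationError(
            f"count {count} exceeds the rule maximum {self.max_raw}"
        )


Counts = Union[int, Sequence[int]]


def frequency_points(rule: FrequencyRule, raw_counts: Counts) -> int:
    """Frequency points earned for ``raw_counts`` under ``rule``.

    ``raw_counts`` is a scalar for ``per_occasion``/``binned`` rules and a
    per-timepoint sequence (length at most ``rule.timepoints``; missing
    trailing waves count as zero) for ``per_timepoint_binned``.
    """
    if rule.kind == "per_timepoint_binned":
        if isinstance(raw_counts, int):
            raw_counts = (raw_counts,)
        counts = list(raw_counts)
        if len(counts) > rule.timepoints:  # type: ignore[operator]
            raise ValidationError(
                f"{len(counts)} timepoint counts given, rule has {rule.timepoints}"
            )
        _check_nonneg(counts)
        return sum(rule._bin_points(c) for c in counts)
    if not isinstance(raw_counts, int):
        seq = list(raw_counts)
        if len(seq) != 1:
            raise ValidationError(f"{rule.kind} rule takes a single count, got {seq}")
        raw_counts = seq[0]
    _check_nonneg([raw_counts])
    if rule.kind == "per_occasion":
        if raw_counts > rule.max_occasions:  # type: ignore[operator]
            raise ValidationError(
                f"count {raw_counts} exceeds the rule maximum {rule.max_occasions}"
            )
        return raw_counts
    return rule._bin_points(raw_counts)


def _check_nonneg(counts: Iterable[int]) -> None:
    for c in counts:
        if not isinstance(c, (int,)) or isinstance(c, bool) or c < 0:
            raise ValidationError(f"raw counts must be non-negative integers, got {c!r}")


@dataclass(frozen=True)
class ActivityType:
    """A named engagement activity with category, frequency rule and burden."""

    name: str
    category: str
    frequency_rule: FrequencyRule
    burden: BurdenProfile

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(
                f"activity {self.name!r}: category must be one of {CATEGORIES}"
            )

    @property
    def intensity_factor(self) -> int:
        return intensity_factor(self.burden)


def max_weighting(activity: ActivityType) -> int:
    """Maximum frequency points × intensity factor for one activity."""
    return activity.frequency_rule.max_points * activity.intensity_factor


@dataclass(frozen=True)
class ArmCatalog:
    """The offering of one cohort × school arm."""

    cohort_id: str
    school_id: str
    treatment: str
    offered: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "intervention"):
            raise ConfigError(
                f"arm ({self.cohort_id}, {self.school_id}): treatment must be "
                "'control' or 'intervention'"
            )
        if not self.offered:
            raise ConfigError(
                f"arm ({self.cohort_id}, {self.school_id}) offers no activities"
            )
        object.__setattr__(self, "offered", frozenset(self.offered))

    @property
    def key(self) -> tuple[str, str]:
        return (self.cohort_id, self.school_id)


class ArmMaxima(NamedTuple):
    """Standardization divisors of one arm, totals then program/evaluation splits."""

    max_ppp: int
    max_pei: int
    program_ppp: int
    program_pei: int
    evaluation_ppp: int
    evaluation_pei: int


class Catalog:
    """A set of activity types plus the arms that offer subsets of them."""

    def __init__(self, activities: Iterable[ActivityType], arms: Iterable[ArmCatalog]):
        self.activities: dict[str, ActivityType] = {}
        for act in activities:
            if act.name in self.activities:
                raise ConfigError(f"duplicate activity name {act.name!r}")
            self.activities[act.name] = act
            if act.intensity_factor == 0:
                warnings.warn(
                    f"activity {act.name!r} has intensity factor 0; it will never "
                    "contribute to engagement intensity",
                    stacklevel=2,
                )
        self.arms: dict[tuple[str, str], ArmCatalog] = {}
        for arm in arms:
            unknown = arm.offered - self.activities.keys()
            if unknown:
                raise ConfigError(
                    f"arm ({arm.cohort_id}, {arm.school_id}) offers unknown "
                    f"activities {sorted(unknown)}"
                )
            if arm.key in self.arms:
                raise ConfigError(f"duplicate arm {arm.key}")
            self.arms[arm.key] = arm

    def __repr__(self) -> str:
        return f"Catalog({len(self.activities)} activities, {len(self.arms)} arms)"

    def arm(self, cohort_id, school_id) -> ArmCatalog:
        key = (str(cohort_id), str(school_id))
        try:
            return self.arms[key]
        except KeyError:
            raise CatalogLookupError(
                f"no arm for cohort {cohort_id}, school {school_id}"
            ) from None

    def activity(self, name: str) -> ActivityType:
        try:
            return self.activities[name]
        except KeyError:
            raise CatalogLookupError(f"unknown activity {name!r}") from None

    def arm_maxima(self, arm: ArmCatalog) -> ArmMaxima:
        return arm_maxima(arm, self.activities)

    # ---- serialization ------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "Catalog":
        try:
            raw_acts = cfg["activities"]
            raw_arms = cfg["arms"]
        except KeyError as exc:
            raise ConfigError(f"catalog config missing section {exc}") from None
        activities = [_parse_activity(a) for a in raw_acts]
        arms = [
            ArmCatalog(
                cohort_id=str(a["cohort"]),
                school_id=str(a["school"]),
                treatment=a["treatment"],
                offered=frozenset(a["offered"]),
            )
            for a in raw_arms
        ]
        return cls(activities, arms)

    @classmethod
    def from_json(cls, path: str | Path) -> "Catalog":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _parse_activity(a: Mapping) -> ActivityType:
    freq = dict(a["frequency"])
    if "bins" in freq:
        freq["bins"] = tuple(tuple(b) for b in freq["bins"])
    b = a["burden"]
    return ActivityType(
        name=a["name"],
        category=a["category"],
        frequency_rule=FrequencyRule(**freq),
        burden=BurdenProfile(
            incentivized=bool(b["incentivized"]),
            away_from_home=bool(b["away_from_home"]),
            involves_child=bool(b["involves_child"]),
            duration_hours=float(b["duration_hours"]),
            personal_info=bool(b["personal_info"]),
        ),
    )


def arm_maxima(arm: ArmCatalog, activities: Mapping[str, ActivityType]) -> ArmMaxima:
    """Standardization divisors for one arm.

    ``max_ppp`` is the number of offered activity types; ``max_pei`` the sum of
    their weightings; the program/evaluation pairs partition both totals.
    """
    tot_ppp = tot_pei = 0
    sub = {"program": [0, 0], "evaluation": [0, 0]}
    for name in sorted(arm.offered):
        try:
            act = activities[name]
        except KeyError:
            raise CatalogLookupError(f"unknown activity {name!r} in arm {arm.key}") from None
        w = max_weighting(act)
        tot_ppp += 1
        tot_pei += w
        sub[act.category][0] += 1
        sub[act.category][1] += w
    return ArmMaxima(
        tot_ppp,
        tot_pei,
        sub["program"][0],
        sub["program"][1],
        sub["evaluation"][0],
        sub["evaluation"][1],
    )


def build_default_catalogs() -> Catalog:
    """The canonical Fuel-for-Fun catalog: 8 activities and the 31 cohort × school arms.

    Cohorts 1 and 4 are controls, cohorts 2 and 3 intervention; cohort 4 has no
    school-5 arm, exactly as fielded, and looking that arm up raises
    :class:`~engage.errors.CatalogLookupError`.
    """
    ref = resources.files("engage").joinpath("data/fff_catalog.json")
    return Catalog.from_dict(json.loads(ref.read_text(encoding="utf-8")))
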