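"""Study-table parsing, quality scoring, and demographic aggregation.

This is stage 0 of the dual-disorder ALE pipeline: it turns two CSV files
(``studies.csv`` with one row per included VBM study, ``foci.csv`` with one
row per reported peak coordinate) into validated :class:`StudyRecord`
objects, applies the 12-item quality checklist, and pools study-level
demographics per condition the way meta-analysis summary tables do
(unweighted mean of per-study means; the pooled "±" is the unweighted mean
of per-study standard deviations, not the sd of study means).

A study that reported no significant group difference is a valid record
with an empty foci list ("null-result study"); downstream it is represented
by an all-zero likelihood map so that it still dilutes its condition's mean
map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Space",
    "Direction",
    "FocusCoordinate",
    "QualityChecklist",
    "StudyRecord",
    "ConditionSummary",
    "DemographicsSummary",
    "parse_study_table",
    "write_study_table",
    "score_quality",
    "aggregate_demographics",
    "compare_conditions",
    "QUALITY_INCLUSION_THRESHOLD",
    "N_QUALITY_ITEMS",
    "STUDY_COLUMNS",
    "FOCI_COLUMNS",
]

#: Minimum quality-checklist total for a study to enter the analysis.
QUALITY_INCLUSION_THRESHOLD = 8.0
N_QUALITY_ITEMS = 12
_VALID_ITEM_SCORES = (0.0, 0.5, 1.0)

#: Sanity bound on stereotactic coordinates (mm); nothing in a human head
#: template is further than this from the origin.
MAX_ABS_COORD_MM = 200.0

_QUALITY_COLS = tuple(f"q{i}" for i in range(1, N_QUALITY_ITEMS + 1))
STUDY_COLUMNS = (
    "study_id",
    "condition",
    "n_patients",
    "n_controls",
    "age_mean",
    "age_sd",
    "ctrl_age_mean",
    "ctrl_age_sd",
    "duration_mean",
    "duration_sd",
    "duration_is_median",
    "hba1c_mean",
    "hba1c_sd",
) + _QUALITY_COLS
FOCI_COLUMNS = ("study_id", "x", "y", "z", "space", "direction")


class Space(str, Enum):
    """Stereotactic coordinate space a focus was reported in."""

    MNI = "MNI"
    TALAIRACH = "TAL"

    @classmethod
    def parse(cls, text: str) -> "Space":
        t = str(text).strip().upper()
        if t in ("MNI", "ICBM", "MNI152"):
            return cls.MNI
        if t in ("TAL", "TALAIRACH"):
            return cls.TALAIRACH
        raise ValueError(f"unknown coordinate space: {text!r}")


class Direction(str, Enum):
    """Sign of the reported gray-matter difference (patients vs controls)."""

    REDUCTION = "reduction"
    INCREASE = "increase"

    @classmethod
    def parse(cls, text: str) -> "Direction":
        t = str(text).strip().lower()
        if t in ("reduction", "decrease", "lower", "-"):
            return cls.REDUCTION
        if t in ("increase", "elevation", "higher", "+"):
            return cls.INCREASE
        raise ValueError(f"unknown effect direction: {text!r}")


@dataclass(frozen=True)
class FocusCoordinate:
    """A single reported peak coordinate (mm) with its space and direction."""

    x: float
    y: float
    z: float
    space: Space
    direction: Direction

    def __post_init__(self) -> None:
        for name, v in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not math.isfinite(v):
                raise ValueError(f"focus coordinate {name} is not finite: {v}")
            if abs(v) > MAX_ABS_COORD_MM:
                raise ValueError(
                    f"focus coordinate {name}={v} mm exceeds sanity bound "
                    f"±{MAX_ABS_COORD_MM} mm"
                )

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class QualityChecklist:
    """Scores on the 12-item study-quality checklist.

    Each item is scored 0 (not met), 0.5 (partially met) or 1 (met); a study
    is retained only when the total reaches
    :data:`QUALITY_INCLUSION_THRESHOLD`.
    """

    items: tuple[float, ...]

    @property
    def total(self) -> float:
        return float(sum(self.items))

    @property
    def included(self) -> bool:
        return self.total >= QUALITY_INCLUSION_THRESHOLD


def score_quality(items: Sequence[float]) -> QualityChecklist:
    """Validate 12 checklist item scores and build a :class:`QualityChecklist`.

    Raises
    ------
    ValueError
        If there are not exactly 12 items or an item is outside {0, 0.5, 1}.
    """
    items = tuple(float(v) for v in items)
    if len(items) != N_QUALITY_ITEMS:
        raise ValueError(
            f"quality checklist needs exactly {N_QUALITY_ITEMS} items, "
            f"got {len(items)}"
        )
    for i, v in enumerate(items, start=1):
        if v not in _VALID_ITEM_SCORES:
            raise ValueError(
                f"checklist item {i} score {v} not in {{0, 0.5, 1}}"
            )
    return QualityChecklist(items)


@dataclass(frozen=True)
class StudyRecord:
    """One included VBM study: condition, samples, covariates, quality, foci.

    ``duration_mean`` may carry a study-reported median (``duration_is_median``
    flags that provenance); it is pooled as if it were a mean. Missing
    covariates are ``None`` and are excluded from pooled means, never imputed.
    """

    study_id: str
    condition: str
    n_patients: int
    n_controls: int
    age_mean: float | None = None
    age_sd: float | None = None
    ctrl_age_mean: float | None = None
    ctrl_age_sd: float | None = None
    duration_mean: float | None = None
    duration_sd: float | None = None
    duration_is_median: bool = False
    hba1c_mean: float | None = None
    hba1c_sd: float | None = None
    quality: QualityChecklist | None = None
    foci: tuple[FocusCoordinate, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError(
                f"study {self.study_id!r}: group sizes must be >= 1 "
                f"(got {self.n_patients} patients, {self.n_controls} controls)"
            )
        if not self.study_id:
            raise ValueError("study_id must be non-empty")

    def foci_with_direction(self, direction: Direction) -> tuple[FocusCoordinate, ...]:
        return tuple(f for f in self.foci if f.direction == direction)


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def _opt_float(value, what: str, row: int) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        s = value.strip()
        if s == "":
            return None
        value = s
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: non-numeric {what}: {value!r}") from None


def _req_int(value, what: str, row: int) -> int:
    v = _opt_float(value, what, row)
    if v is None:
        raise ValueError(f"row {row}: missing {what}")
    if v != int(v):
        raise ValueError(f"row {row}: {what} must be an integer, got {value!r}")
    return int(v)


def parse_study_table(
    studies_path: str | Path,
    foci_path: str | Path | None = None,
    conditions: Sequence[str] | None = None,
) -> list[StudyRecord]:
    """Read ``studies.csv`` (+ optional ``foci.csv``) into StudyRecords.

    Parameters
    ----------
    studies_path:
        CSV with columns :data:`STUDY_COLUMNS`. Empty cells are missing
        values; decimals use ".".
    foci_path:
        Optional CSV with columns :data:`FOCI_COLUMNS`; every focus row must
        reference a declared study_id. Omitted or absent file means a
        metadata-only table (no coordinates).
    conditions:
        If given, the set of admissible condition labels; any other label is
        a hard error naming the offending row.

    The parse is order-preserving: records come back in file order, foci in
    file order within each study.
    """
    studies_path = Path(studies_path)
    if not studies_path.exists():
        raise FileNotFoundError(studies_path)
    df = pd.read_csv(studies_path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"{studies_path.name}: missing required columns {missing_cols}"
        )

    foci_by_study: dict[str, list[FocusCoordinate]] = {}
    declared: set[str] = set(df["study_id"])
    if foci_path is not None and Path(foci_path).exists():
        fdf = pd.read_csv(foci_path, dtype=str, keep_default_na=False)
        missing_cols = [c for c in FOCI_COLUMNS if c not in fdf.columns]
        if missing_cols:
            raise ValueError(
                f"{Path(foci_path).name}: missing required columns {missing_cols}"
            )
        for i, frow in enumerate(fdf.itertuples(index=False), start=2):
            sid = frow.study_id
            if sid not in declared:
                raise ValueError(
                    f"foci row {i}: focus references undeclared study {sid!r}"
                )
            try:
                focus = FocusCoordinate(
                    x=float(frow.x),
                    y=float(frow.y),
                    z=float(frow.z),
                    space=Space.parse(frow.space),
                    direction=Direction.parse(frow.direction),
                )
            except ValueError as exc:
                raise ValueError(f"foci row {i}: {exc}") from None
            foci_by_study.setdefault(sid, []).append(focus)

    records: list[StudyRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.study_id
        if sid in seen:
            raise ValueError(f"row {i}: duplicate study_id {sid!r}")
        seen.add(sid)
        cond = str(row.condition).strip()
        if conditions is not None and cond not in conditions:
            raise ValueError(
                f"row {i}: unknown condition label {cond!r} "
                f"(expected one of {sorted(conditions)})"
            )
        items = [_opt_float(getattr(row, c), c, i) for c in _QUALITY_COLS]
        if any(v is None for v in items):
            raise ValueError(f"row {i}: incomplete quality checklist")
        is_median = str(row.duration_is_median).strip() in ("1", "1.0", "true", "True")
        records.append(
            StudyRecord(
                study_id=sid,
                condition=cond,
                n_patients=_req_int(row.n_patients, "n_patients", i),
                n_controls=_req_int(row.n_controls, "n_controls", i),
                age_mean=_opt_float(row.age_mean, "age_mean", i),
                age_sd=_opt_float(row.age_sd, "age_sd", i),
                ctrl_age_mean=_opt_float(row.ctrl_age_mean, "ctrl_age_mean", i),
                ctrl_age_sd=_opt_float(row.ctrl_age_sd, "ctrl_age_sd", i),
                duration_mean=_opt_float(row.duration_mean, "duration_mean", i),
                duration_sd=_opt_float(row.duration_sd, "duration_sd", i),
                duration_is_median=is_median,
                hba1c_mean=_opt_float(row.hba1c_mean, "hba1c_mean", i),
                hba1c_sd=_opt_float(row.hba1c_sd, "hba1c_sd", i),
                quality=score_quality(items),
                foci=tuple(foci_by_study.get(sid, ())),
            )
        )
    return records


def write_study_table(
    records: Iterable[StudyRecord],
    studies_path: str | Path,
    foci_path: str | Path | None = None,
) -> None:
    """Write StudyRecords back to the ``studies.csv`` / ``foci.csv`` dialect.

    Round-trips with :func:`parse_study_table`.
    """
    records = list(records)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "study_id": r.study_id,
            "condition": r.condition,
            "n_patients": r.n_patients,
            "n_controls": r.n_controls,
            "age_mean": r.age_mean,
            "age_sd": r.age_sd,
            "ctrl_age_mean": r.ctrl_age_mean,
            "ctrl_age_sd": r.ctrl_age_sd,
            "duration_mean": r.duration_mean,
            "duration_sd": r.duration_sd,
            "duration_is_median": int(r.duration_is_median),
            "hba1c_mean": r.hba1c_mean,
            "hba1c_sd": r.hba1c_sd,
        }
        q = r.quality if r.quality is not None else score_quality([1.0] * 12)
        for j, v in enumerate(q.items, start=1):
            row[f"q{j}"] = v
        rows.append(row)
    pd.DataFrame(rows, columns=list(STUDY_COLUMNS)).to_csv(studies_path, index=False)

    if foci_path is not None:
        frows = [
            {
                "study_id": r.study_id,
                "x": f.x,
                "y": f.y,
                "z": f.z,
                "space": f.space.value,
                "direction": f.direction.value,
            }
            for r in records
            for f in r.foci
        ]
        pd.DataFrame(frows, columns=list(FOCI_COLUMNS)).to_csv(foci_path, index=False)


# ---------------------------------------------------------------------------
# Demographic aggregation
# ---------------------------------------------------------------------------

_COVARIATES = {
    "age": "age_mean",
    "ctrl_age": "ctrl_age_mean",
    "duration": "duration_mean",
    "hba1c": "hba1c_mean",
}
_COVARIATE_SDS = {
    "age": "age_sd",
    "ctrl_age": "ctrl_age_sd",
    "duration": "duration_sd",
    "hba1c": "hba1c_sd",
}


@dataclass(frozen=True)
class ConditionSummary:
    """Pooled summary of one condition's studies (one Table-2-style row)."""

    condition: str
    n_studies: int
    total_patients: int
    total_controls: int
    mean_of_means: Mapping[str, float | None]
    mean_of_sds: Mapping[str, float | None]
    n_missing: Mapping[str, int]


@dataclass(frozen=True)
class DemographicsSummary:
    """Per-condition pooled demographics plus cross-condition Welch tests."""

    per_condition: Mapping[str, ConditionSummary]
    quality_mean: float
    quality_sd: float
    tests: Mapping[str, Mapping[str, float]]

    @property
    def total_patients(self) -> int:
        return sum(s.total_patients for s in self.per_condition.values())

    @property
    def total_controls(self) -> int:
        return sum(s.total_controls for s in self.per_condition.values())

    def to_frame(self, ndigits: int = 1) -> pd.DataFrame:
        """Presentation table (rounded only here, never in the aggregates)."""
        rows = []
        for cond, s in self.per_condition.items():
            row: dict[str, object] = {
                "condition": cond,
                "n_studies": s.n_studies,
                "total_patients": s.total_patients,
                "total_controls": s.total_controls,
            }
            for cov in _COVARIATES:
                m, sd = s.mean_of_means[cov], s.mean_of_sds[cov]
                row[f"{cov}_mean"] = None if m is None else round(m, ndigits)
                row[f"{cov}_sd"] = None if sd is None else round(sd, ndigits)
            rows.append(row)
        return pd.DataFrame(rows)


def _pool(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def aggregate_demographics(records: Sequence[StudyRecord]) -> DemographicsSummary:
    """Pool study-level demographics per condition, Table-2 style.

    Totals are column sums; pooled covariate means are unweighted means of
    per-study means over the studies reporting them, and the pooled "±" is
    the unweighted mean of per-study sds. Study-reported medians are pooled
    as means. Raises if any condition has zero records.
    """
    if not records:
        raise ValueError("no study records to aggregate")
    by_cond: dict[str, list[StudyRecord]] = {}
    for r in records:
        by_cond.setdefault(r.condition, []).append(r)
    for cond, group in by_cond.items():
        if not group:
            raise ValueError(f"condition {cond!r} has no records")

    per_condition: dict[str, ConditionSummary] = {}
    for cond, group in by_cond.items():
        means: dict[str, float | None] = {}
        sds: dict[str, float | None] = {}
        n_missing: dict[str, int] = {}
        for cov, attr in _COVARIATES.items():
            vals = [getattr(r, attr) for r in group]
            present = [v for v in vals if v is not None]
            means[cov] = _pool(present)
            n_missing[cov] = len(vals) - len(present)
            sd_vals = [
                v for v in (getattr(r, _COVARIATE_SDS[cov]) for r in group)
                if v is not None
            ]
            sds[cov] = _pool(sd_vals)
        per_condition[cond] = ConditionSummary(
            condition=cond,
            n_studies=len(group),
            total_patients=sum(r.n_patients for r in group),
            total_controls=sum(r.n_controls for r in group),
            mean_of_means=means,
            mean_of_sds=sds,
            n_missing=n_missing,
        )

    qualities = [r.quality.total for r in records if r.quality is not None]
    if not qualities:
        raise ValueError("no quality scores present")
    quality_mean = float(np.mean(qualities))
    quality_sd = float(np.std(qualities, ddof=1)) if len(qualities) > 1 else 0.0

    tests = compare_conditions(records) if len(by_cond) == 2 else {}
    return DemographicsSummary(
        per_condition=per_condition,
        quality_mean=quality_mean,
        quality_sd=quality_sd,
        tests=tests,
    )


def compare_conditions(
    records: Sequence[StudyRecord],
    covariates: Sequence[str] = ("age", "duration", "hba1c"),
) -> dict[str, dict[str, float]]:
    """Welch two-sample t-tests on study-level covariate means across the
    two conditions.

    Returns ``{covariate: {"statistic", "df", "p"}}``. Requires at least two
    usable studies per condition per covariate.
    """
    by_cond: dict[str, list[StudyRecord]] = {}
    for r in records:
        by_cond.setdefault(r.condition, []).append(r)
    if len(by_cond) != 2:
        raise ValueError(
            f"need exactly two conditions, got {sorted(by_cond)}"
        )
    (cond_a, group_a), (cond_b, group_b) = by_cond.items()

    out: dict[str, dict[str, float]] = {}
    for cov in covariates:
        attr = _COVARIATES[cov]
        a = np.array([getattr(r, attr) for r in group_a if getattr(r, attr) is not None])
        b = np.array([getattr(r, attr) for r in group_b if getattr(r, attr) is not None])
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"covariate {cov!r}: need >=2 usable studies per condition "
                f"({cond_a}: {len(a)}, {cond_b}: {len(b)})"
            )
        if np.array_equal(np.sort(a), np.sort(b)):
            # identical samples: Welch is 0/0-safe only away from zero spread
            out[cov] = {"statistic": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0}
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        out[cov] = {
            "statistic": float(res.statistic),
            "df": float(res.df),
            "p": float(res.pvalue),
        }
    return out


def filter_by_quality(
    records: Sequence[StudyRecord],
    threshold: float = QUALITY_INCLUSION_THRESHOLD,
) -> list[StudyRecord]:
    """Keep only studies whose checklist total reaches ``threshold``."""
    kept = []
    for r in records:
        total = r.quality.total if r.quality is not None else 0.0
        if total >= threshold:
            kept.append(r)
    return kept
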