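"""The 14-item phenotype severity index.

Each clinical item is mapped to an ordinal grade through published bins;
grades are summed into a severity index (SI), the SI is mapped to one of five
severity classes, and the cohort is dichotomized at SI > 20 into a
lower-severity (``VM_M``) and a higher-severity (``M_S``) group.

Bin edges are stored as exact decimals and the measurement is rounded to the
precision of the printed edges (half-up) before lookup, so boundary behaviour
is deterministic and matches the published grade matrix where that matrix
pins it down (e.g. age-at-onset 50 grades 1, an FVC drop of 20 grades 2).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from ._missing import NOT_PERFORMED, Missing, is_missing
from .clinical_records import ITEM_ORDER, PatientRecord

__all__ = [
    "GradingScheme",
    "ItemRule",
    "Bin",
    "ItemGrades",
    "SeverityResult",
    "GradingError",
    "UnavailableMeasurementError",
    "grade_item",
    "grade_bmd",
    "score_patient",
    "compute_severity_index",
    "classify_severity",
    "dichotomize",
    "load_scheme",
    "load_overrides",
]

VM_M = "VM_M"  # very mild / mild
M_S = "M_S"  # moderate, severe or very severe

PROV_COMPUTED = "computed"
PROV_OVERRIDE = "override"
PROV_NOT_PERFORMED_WORST = "not_performed_worst"
PROV_UNAVAILABLE_ZERO = "unavailable_zero"


class GradingError(ValueError):
    """A measurement could not be graded under the scheme."""


class UnavailableMeasurementError(GradingError):
    """An unavailable (not just not-performed) measurement was graded."""


@dataclass(frozen=True)
class Bin:
    grade: int
    lo: Decimal | None  # closed lower bound; None = open
    hi: Decimal | None  # closed upper bound; None = open

    def contains(self, value: Decimal) -> bool:
        if self.lo is not None and value < self.lo:
            return False
        if self.hi is not None and value > self.hi:
            return False
        return True


@dataclass(frozen=True)
class ItemRule:
    """Grading rule for a single clinical item."""

    item_id: str
    kind: str  # numeric | boolean | positive_titre | bmd
    source_field: str
    max_grade: int
    missing_policy: str  # worst_if_not_performed | unavailable_zero
    precision: int = 0
    direction: str = "higher_worse"
    bins: tuple[Bin, ...] = ()
    bins_by_sex: Mapping[str, tuple[Bin, ...]] | None = None
    # bmd composite parameters
    osteoporosis_tscore: Decimal = Decimal("-2.5")
    osteopenia_tscore: Decimal = Decimal("-1.0")
    osteoporosis_min_districts: int = 2

    @property
    def sex_stratified(self) -> bool:
        return self.bins_by_sex is not None

    def bins_for(self, sex: str | None) -> tuple[Bin, ...]:
        if self.bins_by_sex is None:
            return self.bins
        if sex not in self.bins_by_sex:
            raise GradingError(
                f"{self.item_id}: sex is required for this item (got {sex!r})"
            )
        return self.bins_by_sex[sex]

    def round(self, value: float) -> Decimal:
        quantum = Decimal(1).scaleb(-self.precision)
        return Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP)

    def grade_range(self) -> tuple[int, int]:
        if self.kind in ("boolean", "positive_titre"):
            return 0, 1
        if self.kind == "bmd":
            return 0, self.max_grade
        grades = sorted({b.grade for b in (self.bins or next(iter(self.bins_by_sex.values())))})
        return grades[0], grades[-1]


@dataclass(frozen=True)
class GradingScheme:
    """Ordered item rules plus SI classification bins."""

    items: tuple[ItemRule, ...]
    si_max: int
    class_bins: tuple[tuple[str, int, int], ...]

    def __getitem__(self, item_id: str) -> ItemRule:
        for rule in self.items:
            if rule.item_id == item_id:
                return rule
        raise KeyError(item_id)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(r.item_id for r in self.items)

    def max_total(self) -> int:
        """Sum of the items' maximum grades under the published bins.

        The declared ``si_max`` is carried as published; the bins as printed
        yield a smaller attainable maximum, and both numbers are exposed
        rather than reconciled.
        """
        return sum(r.grade_range()[1] for r in self.items)

    @staticmethod
    def default() -> "GradingScheme":
        return _default_scheme()


@dataclass
class ItemGrades:
    patient_id: str
    grades: dict[str, int]
    provenance: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class SeverityResult:
    patient_id: str
    si: int
    severity_class: str
    group: str
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# scheme loading

def _parse_bins(raw: Sequence[Mapping]) -> tuple[Bin, ...]:
    out = []
    for b in raw:
        lo = None if b["lo"] is None else Decimal(str(b["lo"]))
        hi = None if b["hi"] is None else Decimal(str(b["hi"]))
        out.append(Bin(grade=int(b["grade"]), lo=lo, hi=hi))
    return tuple(out)


def load_scheme(path: str | Path) -> GradingScheme:
    """Load a grading scheme from its YAML serialization."""
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    items = []
    for it in raw["items"]:
        kind = it["kind"]
        common = dict(
            item_id=it["id"],
            kind=kind,
            source_field=it["field"],
            max_grade=int(it["max_grade"]),
            missing_policy=it.get("missing_policy", "unavailable_zero"),
        )
        if kind == "numeric":
            common["precision"] = int(it.get("precision", 0))
            common["direction"] = it.get("direction", "higher_worse")
            if it.get("sex_stratified"):
                common["bins_by_sex"] = {
                    "female": _parse_bins(it["bins_female"]),
                    "male": _parse_bins(it["bins_male"]),
                }
            else:
                common["bins"] = _parse_bins(it["bins"])
        elif kind == "bmd":
            common["osteoporosis_tscore"] = Decimal(str(it["osteoporosis_tscore"]))
            common["osteopenia_tscore"] = Decimal(str(it["osteopenia_tscore"]))
            common["osteoporosis_min_districts"] = int(
                it["osteoporosis_min_districts"]
            )
        items.append(ItemRule(**common))
    classes = tuple(
        (c["label"], int(c["lo"]), int(c["hi"])) for c in raw["classes"]
    )
    return GradingScheme(items=tuple(items), si_max=int(raw["si_max"]),
                         class_bins=classes)


@lru_cache(maxsize=1)
def _default_scheme() -> GradingScheme:
    ref = resources.files("lopdkit.data").joinpath("si_scheme_v1.yaml")
    with resources.as_file(ref) as p:
        scheme = load_scheme(p)
    if scheme.item_ids != ITEM_ORDER:
        raise GradingError("default scheme items out of order")
    return scheme


def load_overrides(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a per-patient grade override TSV (patient_id, item_id, grade)."""
    out: dict[str, dict[str, int]] = {}
    with open(path, "r", encoding="utf-8", newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            out.setdefault(row["patient_id"], {})[row["item_id"]] = int(row["grade"])
    return out


# ---------------------------------------------------------------------------
# grading

def _grade_missing(rule: ItemRule, measurement: Missing,
                   allow_unavailable_zero: bool) -> tuple[int, str]:
    if (measurement.reason == NOT_PERFORMED
            and rule.missing_policy == "worst_if_not_performed"):
        return rule.max_grade, PROV_NOT_PERFORMED_WORST
    if allow_unavailable_zero:
        warnings.warn(
            f"{rule.item_id}: missing ({measurement.reason}) graded 0",
            stacklevel=3,
        )
        return 0, PROV_UNAVAILABLE_ZERO
    raise UnavailableMeasurementError(
        f"{rule.item_id}: measurement missing ({measurement.reason}) and no "
        f"worst-grade policy applies"
    )


def grade_item(
    scheme: GradingScheme,
    item_id: str,
    measurement,
    sex: str | None = None,
    *,
    allow_unavailable_zero: bool = False,
) -> int:
    """Grade one measurement under *scheme*; deterministic bin lookup."""
    rule = scheme[item_id]
    if is_missing(measurement):
        grade, _ = _grade_missing(rule, measurement, allow_unavailable_zero)
        return grade
    if rule.kind == "boolean":
        return int(bool(measurement))
    if rule.kind == "positive_titre":
        return int(float(measurement) > 0)
    if rule.kind == "bmd":
        return grade_bmd(measurement, rule=rule)
    value = rule.round(float(measurement))
    for b in rule.bins_for(sex):
        if b.contains(value):
            return b.grade
    raise GradingError(
        f"{item_id}: value {measurement!r} (rounded {value}) matches no bin"
    )


def grade_bmd(tscores: Sequence, rule: ItemRule | None = None) -> int:
    """Composite bone-density grade over the three district T-scores.

    Grade 2 if at least two districts are at or below the osteoporosis
    threshold, else grade 1 if any district is at or below the osteopenia
    threshold, else 0.  Missing districts are ignored; all-missing errors.
    """
    if rule is None:
        rule = GradingScheme.default()["BMD"]
    present = [Decimal(str(t)) for t in tscores if not is_missing(t)]
    if not present:
        raise GradingError("BMD: all three district T-scores are missing")
    n_porosis = sum(t <= rule.osteoporosis_tscore for t in present)
    if n_porosis >= rule.osteoporosis_min_districts:
        return 2
    if any(t <= rule.osteopenia_tscore for t in present):
        return 1
    return 0


def score_patient(
    scheme: GradingScheme,
    record: PatientRecord,
    overrides: Mapping[str, int] | None = None,
    *,
    allow_unavailable_zero: bool = False,
) -> ItemGrades:
    """Grade every scheme item for one patient record."""
    overrides = overrides or {}
    grades: dict[str, int] = {}
    provenance: dict[str, str] = {}
    sex = None if is_missing(record.sex) else record.sex
    for rule in scheme.items:
        item_id = rule.item_id
        if item_id in overrides:
            grade = int(overrides[item_id])
            if not (0 <= grade <= rule.max_grade):
                raise GradingError(
                    f"{record.patient_id}/{item_id}: override grade {grade} "
                    f"outside [0, {rule.max_grade}]"
                )
            grades[item_id] = grade
            provenance[item_id] = PROV_OVERRIDE
            continue
        measurement = getattr(record, rule.source_field)
        try:
            if is_missing(measurement):
                grade, prov = _grade_missing(
                    rule, measurement, allow_unavailable_zero
                )
            else:
                grade = grade_item(scheme, item_id, measurement, sex=sex)
                prov = PROV_COMPUTED
        except GradingError as exc:
            raise GradingError(f"{record.patient_id}: {exc}") from exc
        grades[item_id] = grade
        provenance[item_id] = prov
    return ItemGrades(patient_id=record.patient_id, grades=grades,
                      provenance=provenance)


def compute_severity_index(
    g: ItemGrades, scheme: GradingScheme | None = None
) -> SeverityResult:
    """Sum the grade map into an SI and classify it."""
    scheme = scheme or GradingScheme.default()
    missing = [i for i in scheme.item_ids if i not in g.grades]
    if missing:
        raise GradingError(f"{g.patient_id}: missing item grade(s): {missing}")
    si = int(sum(g.grades[i] for i in scheme.item_ids))
    flags = ()
    if si < scheme.class_bins[0][1]:
        flags = ("si_below_published_minimum",)
    return SeverityResult(
        patient_id=g.patient_id,
        si=si,
        severity_class=classify_severity(si, scheme),
        group=M_S if si > 20 else VM_M,
        flags=flags,
    )


def classify_severity(si: int, scheme: GradingScheme | None = None) -> str:
    """Map an SI value to its severity class label."""
    scheme = scheme or GradingScheme.default()
    if si < 0:
        raise GradingError(f"negative SI: {si}")
    for label, lo, hi in scheme.class_bins:
        if lo <= si <= hi:
            return label
    if si >= scheme.class_bins[-1][1]:
        return scheme.class_bins[-1][0]
    return scheme.class_bins[0][0]  # si below the published minimum


def dichotomize(
    results: Sequence[SeverityResult], threshold: int = 20
) -> dict[str, str]:
    """Split patients into lower/higher-severity groups at SI > *threshold*."""
    if not results:
        raise GradingError("dichotomize: no severity results")
    return {
        r.patient_id: (M_S if r.si > threshold else VM_M) for r in results
    }


def group_sizes(groups: Mapping[str, str]) -> dict[str, int]:
    sizes = {VM_M: 0, M_S: 0}
    for g in groups.values():
        sizes[g] += 1
    return sizes


# ---------------------------------------------------------------------------
# grade matrix output

def grades_to_rows(
    all_grades: Sequence[ItemGrades],
    results: Sequence[SeverityResult],
    scheme: GradingScheme | None = None,
) -> list[dict]:
    """Flatten grades + severity results to writable rows (one per patient)."""
    scheme = scheme or GradingScheme.default()
    by_id = {r.patient_id: r for r in results}
    rows = []
    for g in all_grades:
        row: dict = {"patient_id": g.patient_id}
        row.update({i: g.grades[i] for i in scheme.item_ids})
        res = by_id[g.patient_id]
        row.update(SI=res.si, severity_class=res.severity_class,
                   group=res.group)
        rows.append(row)
    return rows
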