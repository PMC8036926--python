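"""Cohort domain types, TSV ingestion/validation and packaged table fixtures.

The on-disk format is a UTF-8 TSV with one header row using the clinical
table's column labels (a small alias map accommodates spelling variants such
as ``Δ-FVC`` vs ``Delta-FVC``).  Missing measurements are written with the
markers ``n.p.`` (not performed) and ``na`` (unavailable) and surface as typed
:class:`~lopdkit._missing.Missing` values, never as silent ``NaN``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from ._missing import (
    MISSING_NOT_PERFORMED,
    Missing,
    is_missing,
    parse_missing,
)

__all__ = [
    "PatientRecord",
    "ClinicalDataset",
    "GenotypeRow",
    "Issue",
    "ClinicalTableError",
    "Table2Grades",
    "load_clinical_table",
    "write_clinical_table",
    "validate_record",
    "bundled_fixture",
]

FEMALE = "female"
MALE = "male"

ITEM_ORDER = (
    "AAO", "MMT", "SIXMWT", "GSCG", "FVC", "DFVC", "BMI",
    "VDD", "BMD", "BF", "BAD", "MVP", "IGG", "ERTAE",
)


class ClinicalTableError(ValueError):
    """Raised for malformed clinical tables (unknown columns, bad values)."""


@dataclass(frozen=True)
class PatientRecord:
    """One sibling's clinical measurements (one row of the clinical table)."""

    patient_id: str
    family_id: str
    sex: str | Missing
    age_dx: float | Missing
    aao: float | Missing
    mmt_mrc: float | Missing
    six_mwt: float | Missing
    gscg: float | Missing
    fvc_upright: float | Missing
    delta_fvc: float | Missing
    bmi: float | Missing
    vdd: float | Missing
    bmd_tscores: tuple  # (total-body, femoral-neck, lumbar-sacral)
    bf: bool | Missing
    bad: bool | Missing
    mvp: bool | Missing
    igg_rhgaa: float | Missing
    ert_ae: bool | Missing
    dbs_gaa: float | Missing
    ppl: float | Missing
    vmf: float | Missing
    gaa_genotype: tuple = ("", "")


@dataclass
class ClinicalDataset:
    records: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ClinicalTableError(f"duplicate patient_id(s): {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.records:
            out.setdefault(r.family_id, []).append(r.patient_id)
        return out


@dataclass(frozen=True)
class GenotypeRow:
    """Per-patient diploid genotype strings keyed by rsID (e.g. ``CC``)."""

    patient_id: str
    genotypes: Mapping[str, str]

    def __post_init__(self) -> None:
        for rsid, gt in self.genotypes.items():
            if len(gt) != 2 or any(b not in "ACGT" for b in gt):
                raise ClinicalTableError(
                    f"{self.patient_id}: bad genotype {gt!r} at {rsid}"
                )


@dataclass(frozen=True)
class Issue:
    """A single validation finding: which field, what value, which rule."""

    field: str
    value: object
    rule: str

    def __str__(self) -> str:
        return f"{self.field}={self.value!r} violates: {self.rule}"


# ---------------------------------------------------------------------------
# column dialect

#: header label -> record field; BMD districts are three separate columns
DEFAULT_ALIASES: dict[str, str] = {
    "ID": "patient_id",
    "Family": "family_id",
    "GAA Mut": "gaa_genotype",
    "GAA": "gaa_genotype",
    "Sex": "sex",
    "Age": "age_dx",
    "AAO": "aao",
    "MMT-MRC": "mmt_mrc",
    "MMTMRC": "mmt_mrc",
    "6MWT": "six_mwt",
    "GSCG": "gscg",
    "GSGC": "gscg",
    "FVC": "fvc_upright",
    "Delta-FVC": "delta_fvc",
    "Δ-FVC": "delta_fvc",
    "DFVC": "delta_fvc",
    "BMI": "bmi",
    "VDD": "vdd",
    "BF": "bf",
    "BMD-TB": "bmd_tb",
    "BMD-FN": "bmd_fn",
    "BMD-LSV": "bmd_lsv",
    "BAD": "bad",
    "MVP": "mvp",
    "IgG-rhGAA": "igg_rhgaa",
    "IGG": "igg_rhgaa",
    "ERT-AE": "ert_ae",
    "DBS GAA": "dbs_gaa",
    "DBS": "dbs_gaa",
    "PPL": "ppl",
    "VMF": "vmf",
}

_NUMERIC_FIELDS = {
    "age_dx", "aao", "mmt_mrc", "six_mwt", "gscg", "fvc_upright",
    "delta_fvc", "bmi", "vdd", "igg_rhgaa", "dbs_gaa", "ppl", "vmf",
    "bmd_tb", "bmd_fn", "bmd_lsv",
}
_BOOL_FIELDS = {"bf", "bad", "mvp", "ert_ae"}
_BOOL_TOKENS = {"yes": True, "y": True, "true": True, "1": True,
                "no": False, "n": False, "false": False, "0": False}

#: write-order for round-trip output
_OUTPUT_COLUMNS = [
    "ID", "Family", "GAA Mut", "Sex", "Age", "AAO", "MMT-MRC", "6MWT",
    "GSCG", "FVC", "Delta-FVC", "BMI", "VDD", "BF", "BMD-TB", "BMD-FN",
    "BMD-LSV", "BAD", "MVP", "IgG-rhGAA", "ERT-AE", "DBS GAA", "PPL", "VMF",
]


def _parse_cell(token: str, fieldname: str, row: int, column: str):
    token = token.strip()
    if token == "":
        return MISSING_NOT_PERFORMED if fieldname != "patient_id" else token
    missing = parse_missing(token)
    if missing is not None:
        return missing
    if fieldname in _NUMERIC_FIELDS:
        try:
            return float(token)
        except ValueError:
            raise ClinicalTableError(
                f"row {row}, column {column!r}: non-numeric value {token!r}"
            ) from None
    if fieldname in _BOOL_FIELDS:
        try:
            return _BOOL_TOKENS[token.lower()]
        except KeyError:
            raise ClinicalTableError(
                f"row {row}, column {column!r}: not a yes/no value {token!r}"
            ) from None
    if fieldname == "sex":
        low = token.lower()
        if low in ("f", "female"):
            return FEMALE
        if low in ("m", "male"):
            return MALE
        raise ClinicalTableError(f"row {row}: unknown sex {token!r}")
    if fieldname == "gaa_genotype":
        parts = token.split("/")
        return tuple(parts) if len(parts) == 2 else (token, "")
    return token


def load_clinical_table(
    path: str | Path | io.TextIOBase,
    dialect: Mapping[str, str] | None = None,
) -> ClinicalDataset:
    """Read a clinical TSV into a validated :class:`ClinicalDataset`.

    *dialect* extends (and may override) the default header-alias map.
    Unknown columns, non-numeric cells in numeric columns and duplicate
    patient ids raise :class:`ClinicalTableError`.
    """
    aliases = dict(DEFAULT_ALIASES)
    if dialect:
        aliases.update(dialect)

    if isinstance(path, (str, Path)):
        handle = open(path, "r", encoding="utf-8", newline="")
        provenance = str(path)
        close = True
    else:
        handle, provenance, close = path, "<stream>", False
    try:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ClinicalTableError("empty file: missing header row") from None
        unknown = [c for c in header if c not in aliases]
        if unknown:
            raise ClinicalTableError(f"unknown column(s): {unknown}")
        fieldmap = [aliases[c] for c in header]

        records: list[PatientRecord] = []
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            values: dict[str, object] = {}
            for col, fieldname, token in zip(header, fieldmap, row):
                values[fieldname] = _parse_cell(token, fieldname, i, col)
            pid = values.get("patient_id")
            if not pid:
                raise ClinicalTableError(f"row {i}: missing patient id")
            if "family_id" not in values:
                values["family_id"] = str(pid).split("II")[0].rstrip("-_ ")
            bmd = tuple(
                values.pop(k, MISSING_NOT_PERFORMED)
                for k in ("bmd_tb", "bmd_fn", "bmd_lsv")
            )
            defaults = {
                f.name: MISSING_NOT_PERFORMED
                for f in fields(PatientRecord)
                if f.name not in ("patient_id", "family_id", "bmd_tscores",
                                  "gaa_genotype")
            }
            defaults["gaa_genotype"] = ("", "")
            defaults.update(values)
            records.append(PatientRecord(bmd_tscores=bmd, **defaults))
    finally:
        if close:
            handle.close()
    return ClinicalDataset(records=records, provenance=provenance)


def _format_value(value: object) -> str:
    if is_missing(value):
        return value.marker()  # type: ignore[union-attr]
    if isinstance(value, bool):
        return "YES" if value else "NO"
    if isinstance(value, float):
        return repr(int(value)) if value == int(value) else repr(value)
    if isinstance(value, tuple):
        return "/".join(str(v) for v in value)
    if value == FEMALE:
        return "F"
    if value == MALE:
        return "M"
    return str(value)


def write_clinical_table(ds: ClinicalDataset, path: str | Path) -> None:
    """Write *ds* back to TSV; ``load_clinical_table`` round-trips it."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_OUTPUT_COLUMNS)
        for r in ds.records:
            tb, fn, lsv = r.bmd_tscores
            row = [
                r.patient_id, r.family_id, _format_value(r.gaa_genotype),
                _format_value(r.sex), _format_value(r.age_dx),
                _format_value(r.aao), _format_value(r.mmt_mrc),
                _format_value(r.six_mwt), _format_value(r.gscg),
                _format_value(r.fvc_upright), _format_value(r.delta_fvc),
                _format_value(r.bmi), _format_value(r.vdd),
                _format_value(r.bf), _format_value(tb), _format_value(fn),
                _format_value(lsv), _format_value(r.bad),
                _format_value(r.mvp), _format_value(r.igg_rhgaa),
                _format_value(r.ert_ae), _format_value(r.dbs_gaa),
                _format_value(r.ppl), _format_value(r.vmf),
            ]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# validation

_PERCENT_BOUNDED = ("mmt_mrc", "delta_fvc", "ppl", "vmf")
_NONNEGATIVE = ("six_mwt", "fvc_upright", "igg_rhgaa", "dbs_gaa", "age_dx",
                "aao", "bmi", "vdd")


def validate_record(r: PatientRecord) -> list[Issue]:
    """Check record invariants; returns an empty list iff all hold."""
    issues: list[Issue] = []
    for name in _PERCENT_BOUNDED:
        v = getattr(r, name)
        if not is_missing(v) and not (0 <= v <= 100):
            issues.append(Issue(name, v, "percent must be within [0, 100]"))
    for name in _NONNEGATIVE:
        v = getattr(r, name)
        if not is_missing(v) and v < 0:
            issues.append(Issue(name, v, "must be non-negative"))
    if not is_missing(r.gscg) and not (4 <= r.gscg <= 27):
        issues.append(Issue("gscg", r.gscg, "GSCG score range is 4-27"))
    if not is_missing(r.six_mwt) and is_missing(r.sex):
        issues.append(Issue(
            "sex", r.sex,
            "sex is required when six_mwt is present (sex-stratified bins)",
        ))
    if not is_missing(r.sex) and r.sex not in (FEMALE, MALE):
        issues.append(Issue("sex", r.sex, "sex must be female or male"))
    if len(r.bmd_tscores) != 3:
        issues.append(Issue("bmd_tscores", r.bmd_tscores,
                            "exactly three BMD districts expected"))
    return issues


# ---------------------------------------------------------------------------
# packaged fixtures

@dataclass(frozen=True)
class Table2Grades:
    """The published 11-patient x 14-item grade matrix plus its SI row."""

    grades: pd.DataFrame  # index: item ids; columns: patient ids
    printed_si: Mapping[str, int]

    @property
    def patients(self) -> list[str]:
        return list(self.grades.columns)

    @property
    def items(self) -> list[str]:
        return list(self.grades.index)

    def column(self, patient_id: str) -> dict[str, int]:
        return self.grades[patient_id].to_dict()

    def column_sum(self, patient_id: str) -> int:
        return int(self.grades[patient_id].sum())


def _data_path(name: str):
    return resources.files("lopdkit.data").joinpath(name)


def _load_table2() -> Table2Grades:
    with resources.as_file(_data_path("table2_grades.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    si = df.loc["SI"]
    grades = df.drop(index="SI").astype(int)
    if list(grades.index) != list(ITEM_ORDER):
        raise ClinicalTableError("grade matrix fixture has unexpected items")
    return Table2Grades(grades=grades, printed_si=si.astype(int).to_dict())


def _load_table6() -> list[GenotypeRow]:
    with resources.as_file(_data_path("table6_genotypes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    rs_cols = [c for c in df.columns if c.startswith("rs")]
    return [
        GenotypeRow(
            patient_id=row["ID"],
            genotypes={c: row[c] for c in rs_cols},
        )
        for _, row in df.iterrows()
    ]


def _load_overrides() -> dict[str, dict[str, int]]:
    with resources.as_file(_data_path("table2_overrides.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"grade": int})
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["patient_id"], {})[row["item_id"]] = int(row["grade"])
    return out


def bundled_fixture(name: str):
    """Return a packaged fixture by name.

    ``table1`` -> ClinicalDataset (11 siblings, two families);
    ``table2_grades`` -> :class:`Table2Grades`;
    ``table2_overrides`` -> per-patient grade overrides reproducing the
    published matrix where the computed grading rules disagree with it;
    ``table6`` -> list of :class:`GenotypeRow`.
    """
    if name == "table1":
        with resources.as_file(_data_path("table1_clinical.tsv")) as p:
            ds = load_clinical_table(p)
        return replace_provenance(ds, "fixture:table1")
    if name == "table2_grades":
        return _load_table2()
    if name == "table2_overrides":
        return _load_overrides()
    if name == "table6":
        return _load_table6()
    raise KeyError(f"unknown fixture: {name!r}")


def replace_provenance(ds: ClinicalDataset, provenance: str) -> ClinicalDataset:
    return ClinicalDataset(records=list(ds.records), provenance=provenance)
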