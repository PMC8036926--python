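"""Descriptive statistics and severity-group comparisons.

The group comparison uses an exact Mann-Whitney U test by default: with
eleven patients every label assignment can be enumerated, so no asymptotic
approximation is needed.  Ties get mid-ranks and the two-sided p-value is the
probability mass of |U - E[U]| at least as large as observed, which reduces
to the classical doubled one-sided p when there are no ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from ._missing import is_missing
from .clinical_records import ClinicalDataset
from .severity_index import M_S, VM_M, SeverityResult

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "StatsError",
    "describe",
    "mann_whitney",
    "chi_square",
    "pearson",
    "severity_association_report",
    "bh_qvalues",
    "report_to_tsv",
]

MW_EXACT = "mw_exact"
MW_NORMAL = "mw_normal_tie_corrected"
CHISQ = "chisq"

#: assignments beyond which `mode="auto"` falls back to the normal approximation
DEFAULT_EXACT_CAP = 500_000


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    variable: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd_n: tuple[float, float]
    sd_n_minus_1: tuple[float, float]
    statistic: float
    p_two_sided: float
    method: str
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class CorrelationResult:
    variables: tuple[str, str]
    r: float
    n: int


def _clean(values: Sequence) -> list[float]:
    return [float(v) for v in values if not is_missing(v) and v is not None
            and not (isinstance(v, float) and math.isnan(v))]


def describe(values: Sequence[float], divisor: str = "n_minus_1") -> tuple[float, float]:
    """Arithmetic mean and SD with the chosen divisor (``n`` or ``n_minus_1``)."""
    vals = _clean(values)
    if not vals:
        raise StatsError("describe: no values after missing removal")
    if divisor not in ("n", "n_minus_1"):
        raise StatsError(f"unknown divisor {divisor!r}")
    arr = np.asarray(vals, dtype=float)
    ddof = 0 if divisor == "n" else 1
    if len(arr) == 1 and ddof == 1:
        return float(arr.mean()), float("nan")
    return float(arr.mean()), float(arr.std(ddof=ddof))


def _both_sds(vals: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(list(vals), dtype=float)
    sd_n = float(arr.std(ddof=0))
    sd_n1 = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    return sd_n, sd_n1


def _u_statistic(pooled_ranks: np.ndarray, idx: Sequence[int], n1: int) -> float:
    r1 = float(pooled_ranks[list(idx)].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "exact",
    exact_cap: int = DEFAULT_EXACT_CAP,
    labels: tuple[str, str] = ("x", "y"),
    variable: str = "",
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    ``mode="exact"`` enumerates all C(n1+n2, n1) group-label assignments with
    mid-rank tie handling; ``mode="auto"`` switches to the tie-corrected
    normal approximation above *exact_cap* assignments.
    """
    xs, ys = _clean(x), _clean(y)
    if not xs or not ys:
        raise StatsError("mann_whitney: both groups must be nonempty")
    if len(xs) + len(ys) < 2:
        raise StatsError("mann_whitney: need at least two observations")
    if mode not in ("exact", "auto"):
        raise StatsError(f"unknown mode {mode!r}")

    n1, n2 = len(xs), len(ys)
    pooled = np.asarray(xs + ys, dtype=float)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    mu = n1 * n2 / 2.0
    u_obs = _u_statistic(ranks, range(n1), n1)

    n_assignments = math.comb(n1 + n2, n1)
    if mode == "auto" and n_assignments > exact_cap:
        res = sps.mannwhitneyu(xs, ys, alternative="two-sided",
                               method="asymptotic")
        p, method = float(res.pvalue), MW_NORMAL
    else:
        dev_obs = abs(u_obs - mu) - 1e-9  # guard exact float comparison
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            if abs(_u_statistic(ranks, idx, n1) - mu) >= dev_obs:
                hits += 1
        p, method = hits / n_assignments, MW_EXACT

    return GroupComparison(
        variable=variable,
        group_labels=labels,
        n=(n1, n2),
        mean=(float(np.mean(xs)), float(np.mean(ys))),
        sd_n=(_both_sds(xs)[0], _both_sds(ys)[0]),
        sd_n_minus_1=(_both_sds(xs)[1], _both_sds(ys)[1]),
        statistic=u_obs,
        p_two_sided=p,
        method=method,
    )


def chi_square(
    contingency: Sequence[Sequence[int]],
    correction: bool = False,
    labels: tuple[str, str] = ("a", "b"),
    variable: str = "",
) -> GroupComparison:
    """Pearson chi-square on a 2x2 table; optional Yates correction.

    Warns (and records a warning tag) when any expected count is below 5,
    which is unavoidable at cohort sizes this small.
    """
    table = np.asarray(contingency, dtype=float)
    if table.shape != (2, 2) or (table < 0).any() or (table % 1 != 0).any():
        raise StatsError("chi_square: need a 2x2 table of nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("chi_square: zero row/column margin")
    stat, p, _, expected = sps.chi2_contingency(table, correction=correction)
    tags: tuple[str, ...] = ()
    if (expected < 5).any():
        warnings.warn("chi_square: expected count < 5; test is approximate",
                      stacklevel=2)
        tags = ("expected_count_lt_5",)
    row_n = table.sum(axis=1)
    props = table[:, 0] / row_n
    return GroupComparison(
        variable=variable,
        group_labels=labels,
        n=(int(row_n[0]), int(row_n[1])),
        mean=(float(props[0]), float(props[1])),
        sd_n=(float("nan"), float("nan")),
        sd_n_minus_1=(float("nan"), float("nan")),
        statistic=float(stat),
        p_two_sided=float(p),
        method=CHISQ,
        warnings=tags,
    )


def pearson(x: Sequence, y: Sequence,
            names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation over pairwise-complete observations."""
    pairs = [
        (float(a), float(b))
        for a, b in zip(x, y)
        if not is_missing(a) and not is_missing(b)
    ]
    if len(pairs) < 3:
        raise StatsError("pearson: need >= 3 pairwise-complete observations")
    xs, ys = zip(*pairs)
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise StatsError("pearson: zero variance in one of the inputs")
    r, _ = sps.pearsonr(xs, ys)
    return CorrelationResult(variables=names, r=float(r), n=len(pairs))


# ---------------------------------------------------------------------------
# severity-group report

def _bmd_accessor(district: int):
    return lambda r: r.bmd_tscores[district]


#: report variable name -> (record accessor, kind)
VARIABLES: dict[str, tuple] = {
    "AGE": (lambda r: r.age_dx, "numeric"),
    "AAO": (lambda r: r.aao, "numeric"),
    "MMT": (lambda r: r.mmt_mrc, "numeric"),
    "6MWT": (lambda r: r.six_mwt, "numeric"),
    "GSGC": (lambda r: r.gscg, "numeric"),
    "FVC": (lambda r: r.fvc_upright, "numeric"),
    "DFVC": (lambda r: r.delta_fvc, "numeric"),
    "BMI": (lambda r: r.bmi, "numeric"),
    "VDD": (lambda r: r.vdd, "numeric"),
    "BMD_TB": (_bmd_accessor(0), "numeric"),
    "BMD_FN": (_bmd_accessor(1), "numeric"),
    "BMD_LSV": (_bmd_accessor(2), "numeric"),
    "IGG_TITRE": (lambda r: r.igg_rhgaa, "numeric"),
    "DBS": (lambda r: r.dbs_gaa, "numeric"),
    "PPL": (lambda r: r.ppl, "numeric"),
    "VMF": (lambda r: r.vmf, "numeric"),
    "SEX": (lambda r: None if is_missing(r.sex) else r.sex == "female", "boolean"),
    "BF": (lambda r: r.bf, "boolean"),
    "BAD": (lambda r: r.bad, "boolean"),
    "MVP": (lambda r: r.mvp, "boolean"),
    "IGG": (lambda r: None if is_missing(r.igg_rhgaa) else r.igg_rhgaa > 0,
            "boolean"),
    "ERTAE": (lambda r: r.ert_ae, "boolean"),
}

_ALIASES = {"GSCG": "GSGC", "ΔFVC": "DFVC", "Δ-FVC": "DFVC",
            "MMT-MRC": "MMT", "DELTA-FVC": "DFVC"}


def resolve_variable(name: str) -> str:
    key = _ALIASES.get(name.upper(), name.upper())
    if key not in VARIABLES:
        raise StatsError(f"unknown variable {name!r}")
    return key


def severity_association_report(
    ds: ClinicalDataset,
    results: Sequence[SeverityResult],
    variables: Sequence[str],
    bh: bool = False,
) -> list[GroupComparison]:
    """Per-variable lower- vs higher-severity group comparison.

    Numeric variables get group means/SDs (missing excluded) and the exact
    Mann-Whitney test; boolean variables get a 2x2 chi-square.  With
    ``bh=True`` Benjamini-Hochberg q-values are appended to the warning tags
    (the default mirrors the published analysis: no multiplicity correction).
    """
    group_of = {r.patient_id: r.group for r in results}
    lower = [r for r in ds.records if group_of.get(r.patient_id) == VM_M]
    higher = [r for r in ds.records if group_of.get(r.patient_id) == M_S]
    report: list[GroupComparison] = []
    for name in variables:
        key = resolve_variable(name)
        accessor, kind = VARIABLES[key]
        if kind == "numeric":
            x = _clean([accessor(r) for r in lower])
            y = _clean([accessor(r) for r in higher])
            cmp_ = mann_whitney(x, y, mode="exact", labels=(VM_M, M_S),
                                variable=key)
        else:
            counts = np.zeros((2, 2), dtype=int)
            for i, grp in enumerate((lower, higher)):
                for r in grp:
                    v = accessor(r)
                    if v is None or is_missing(v):
                        continue
                    counts[i, 0 if v else 1] += 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp_ = chi_square(counts, labels=(VM_M, M_S), variable=key)
        report.append(cmp_)
    if bh:
        qs = bh_qvalues([c.p_two_sided for c in report])
        for c, q in zip(report, qs):
            c.warnings = c.warnings + (f"bh_q={q:.4g}",)
    return report


def bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q.tolist()


def report_to_tsv(report: Sequence[GroupComparison], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "variable\tgroup\tn\tmean\tsd_n\tsd_n_minus_1\tstatistic\t"
            "p_two_sided\tmethod\n"
        )
        for c in report:
            for i, label in enumerate(c.group_labels):
                # p displayed at 2 d.p. per report convention; full value kept
                # in the statistic columns of the first group row
                handle.write(
                    f"{c.variable}\t{label}\t{c.n[i]}\t{c.mean[i]:.4g}\t"
                    f"{c.sd_n[i]:.4g}\t{c.sd_n_minus_1[i]:.4g}\t"
                    f"{c.statistic:.6g}\t{c.p_two_sided:.6g}\t{c.method}\n"
                )
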