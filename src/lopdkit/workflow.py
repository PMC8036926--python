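"""End-to-end pipeline: score -> stats -> prioritize -> report.

A single :class:`RunConfig` drives the run; there are no hidden defaults
beyond the packaged grading scheme and the documented thresholds.  Outputs
are deterministic for a fixed config (the config hash is recorded in the
summary), and any stage failure raises :class:`PipelineError` naming the
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .clinical_records import load_clinical_table
from .cohort_stats import report_to_tsv, severity_association_report
from .severity_index import (
    GradingScheme,
    compute_severity_index,
    dichotomize,
    grades_to_rows,
    group_sizes,
    load_overrides,
    load_scheme,
    score_patient,
)
from .variant_prioritization import (
    load_pedigree,
    load_variant_table,
    prioritize,
    read_gmt,
)

log = logging.getLogger("lopdkit")

DEFAULT_STATS_VARIABLES = ("6MWT", "FVC", "DFVC", "VDD", "BMD_FN", "GSGC")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    clinical: str
    out_dir: str
    scheme: str | None = None
    overrides: str | None = None
    si_threshold: int = 20
    stats_variables: tuple[str, ...] = DEFAULT_STATS_VARIABLES
    annotations: str | None = None
    genotypes: str | None = None
    pedigree: str | None = None
    truth: str | None = None
    maf_cutoff: float = 0.2
    cadd_cutoff: float = 20.0
    min_call_rate: float = 0.95
    traits: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    gene_sets: str | None = None
    universe_size: int | None = None
    allow_unavailable_zero: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        cfg = RunConfig(**raw)
        if not (0 < cfg.maf_cutoff <= 1) or not (0 <= cfg.min_call_rate <= 1):
            raise PipelineError("config", "threshold outside its valid range")
        return cfg

    def hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _require(stage: str, path: str | None, what: str) -> Path:
    if path is None:
        raise PipelineError(stage, f"missing config entry: {what}")
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"file not found: {p}")
    return p


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the machine-readable summary."""
    logging.basicConfig(level=cfg.log_level)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
    }

    # -- score ------------------------------------------------------------
    stage = "score"
    clinical_path = _require(stage, cfg.clinical, "clinical")
    try:
        ds = load_clinical_table(clinical_path)
        scheme = (load_scheme(_require(stage, cfg.scheme, "scheme"))
                  if cfg.scheme else GradingScheme.default())
        overrides = load_overrides(cfg.overrides) if cfg.overrides else {}
        all_grades = [
            score_patient(scheme, r, overrides.get(r.patient_id),
                          allow_unavailable_zero=cfg.allow_unavailable_zero)
            for r in ds.records
        ]
        results = [compute_severity_index(g, scheme) for g in all_grades]
        groups = dichotomize(results, cfg.si_threshold)
        pd.DataFrame(grades_to_rows(all_grades, results, scheme)).to_csv(
            out_dir / "grades.tsv", sep="\t", index=False
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    summary["n_patients"] = len(ds)
    summary["group_sizes"] = group_sizes(groups)
    log.info("scored %d patients; groups %s", len(ds), summary["group_sizes"])

    # -- stats ------------------------------------------------------------
    stage = "stats"
    try:
        report = severity_association_report(
            ds, results, list(cfg.stats_variables)
        )
        report_to_tsv(report, out_dir / "associations.tsv")
        summary["n_associations"] = len(report)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- prioritize -------------------------------------------------------
    if cfg.annotations or cfg.genotypes:
        stage = "prioritize"
        try:
            annot = _require(stage, cfg.annotations, "annotations")
            geno = _require(stage, cfg.genotypes, "genotypes")
            ped = load_pedigree(_require(stage, cfg.pedigree, "pedigree"))
            variants, gm = load_variant_table(annot, geno)
            traits = {
                f"si_gt_{cfg.si_threshold}": {
                    p: int(g == "M_S") for p, g in groups.items()
                }
            }
            traits.update({k: dict(v) for k, v in cfg.traits.items()})
            gene_sets = read_gmt(cfg.gene_sets) if cfg.gene_sets else None
            candidates, cascade, enrichment = prioritize(
                variants, gm, ped, traits=traits,
                maf_cutoff=cfg.maf_cutoff, cadd_cutoff=cfg.cadd_cutoff,
                min_call_rate=cfg.min_call_rate, gene_sets=gene_sets,
                universe_size=cfg.universe_size,
            )
            _write_candidates(candidates, out_dir / "candidates.tsv")
            _write_cascade(cascade, out_dir / "cascade.tsv")
            summary["cascade"] = cascade.counts()
            summary["n_candidates"] = len(candidates)
            summary["candidate_genes"] = sorted(
                {c.variant.gene for c in candidates}
            )
            if enrichment:
                summary["top_enrichment"] = {
                    "set": enrichment[0].set_name,
                    "p_upper": enrichment[0].p_upper,
                }
            if cfg.truth:
                with open(_require(stage, cfg.truth, "truth"),
                          encoding="utf-8") as handle:
                    truth = json.load(handle)
                cand_ids = {c.variant.variant_id for c in candidates}
                planted = truth.get("planted", [])
                summary["planted_expected"] = [
                    p["variant_id"] for p in planted if p["expected_candidate"]
                ]
                summary["planted_recovered"] = sorted(
                    p["variant_id"] for p in planted
                    if p["expected_candidate"] and p["variant_id"] in cand_ids
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    with open(out_dir / "summary.json", "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return summary


def _write_candidates(candidates, path: Path) -> None:
    rows = []
    for c in candidates:
        rows.append({
            "variant_id": c.variant.variant_id,
            "gene": c.variant.gene,
            "func_class": c.variant.func_class,
            "maf_max": c.variant.maf_max,
            "cadd_phred": c.variant.cadd_phred,
            "sharing": c.sharing,
            "carriers": ",".join(sorted(c.carriers)),
            "concordance": c.concordance,
            "pathways": ",".join(c.pathways),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_cascade(cascade, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("stage\tn_after\tremoved_examples\n")
        for s in cascade.stages:
            handle.write(f"{s.name}\t{s.n_after}\t"
                         f"{','.join(s.removed_examples)}\n")
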