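"""Rare-variant modifier-gene prioritization cascade.

Stages, in order: genotype QC (minor-allele count, call rate), functional
class selection, rarity (maximum annotated population frequency), predicted
deleteriousness (CADD phred, with an exception for indel classes that lack a
score), carrier sharing between and within families, cosegregation with
dichotomized clinical traits, and hypergeometric gene-set enrichment of the
surviving candidate genes.

Carrier status uses a dominant model: alternate-allele dosage >= 1.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnnotatedVariant",
    "GenotypeMatrix",
    "Pedigree",
    "CascadeStage",
    "CascadeReport",
    "SharedVariant",
    "SegregationResult",
    "CandidateVariant",
    "GeneSetEnrichment",
    "VariantTableError",
    "load_variant_table",
    "load_pedigree",
    "read_gmt",
    "qc_filter",
    "functional_class_filter",
    "rarity_filter",
    "deleteriousness_filter",
    "shared_carrier_analysis",
    "phenotype_segregation",
    "pathway_enrichment",
    "prioritize",
    "count_genotypes",
    "compound_het_genes",
    "load_bundled_table5",
]

FUNC_CLASSES = {
    "nonsynonymous_SNV", "stopgain", "stoploss", "frameshift_indel",
    "nonframeshift_indel", "splicing", "synonymous_SNV", "other",
}
KEPT_FUNC_CLASSES = {
    "nonsynonymous_SNV", "stopgain", "stoploss", "frameshift_indel",
    "nonframeshift_indel", "splicing",
}
INDEL_CLASSES = {"frameshift_indel", "nonframeshift_indel"}

#: shorthand used in annotation tables
_FUNC_ALIASES = {
    "nsv": "nonsynonymous_SNV",
    "nonsynonymous snv": "nonsynonymous_SNV",
    "nonsynonymous_snv": "nonsynonymous_SNV",
    "stopgain": "stopgain",
    "stoploss": "stoploss",
    "frameshift insertion": "frameshift_indel",
    "frameshift deletion": "frameshift_indel",
    "frameshift_indel": "frameshift_indel",
    "nfins": "nonframeshift_indel",
    "nonframeshift insertion": "nonframeshift_indel",
    "nonframeshift deletion": "nonframeshift_indel",
    "nonframeshift_indel": "nonframeshift_indel",
    "splicing": "splicing",
    "synonymous snv": "synonymous_SNV",
    "synonymous_snv": "synonymous_SNV",
    "other": "other",
}

_ABSENT_MARKERS = {"", ".", "na", "n.a.", "nr", "n.r.", "none"}

BOTH_FAMILIES = "both_families"
FAMILY_SPECIFIC = "family_specific"

MISSING_CALL = -1


class VariantTableError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated variant (coordinates are 1-based, records pre-split)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    func_class: str
    transcript: str = ""
    nt_change: str = ""
    aa_change: str = ""
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    cadd_phred: float | None = None
    sift: str | None = None
    polyphen: str | None = None
    dbsnp: str | None = None

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise VariantTableError(f"{self.variant_id}: alt equals ref")
        if self.func_class not in FUNC_CLASSES:
            raise VariantTableError(
                f"{self.variant_id}: unknown functional class "
                f"{self.func_class!r}"
            )
        for pop, f in self.pop_freqs.items():
            if not (0.0 <= f <= 1.0):
                raise VariantTableError(
                    f"{self.variant_id}: {pop} frequency {f} outside [0, 1]"
                )

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def maf_max(self) -> float | None:
        """Maximum frequency over all populated population columns."""
        return max(self.pop_freqs.values()) if self.pop_freqs else None


class GenotypeMatrix:
    """Alt-allele dosages (0/1/2, -1 = missing) per variant per sample."""

    def __init__(
        self,
        variant_ids: Sequence[str],
        samples: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(variant_ids), len(samples)):
            raise VariantTableError(
                f"genotype matrix shape {calls.shape} does not match "
                f"{len(variant_ids)} variants x {len(samples)} samples"
            )
        bad = ~np.isin(calls, (MISSING_CALL, 0, 1, 2))
        if bad.any():
            raise VariantTableError("genotype dosages must be 0, 1, 2 or missing")
        self.variant_ids = list(variant_ids)
        self.samples = list(samples)
        self.calls = calls
        self._row = {v: i for i, v in enumerate(self.variant_ids)}

    def dosages(self, variant_id: str) -> np.ndarray:
        return self.calls[self._row[variant_id]]

    def call_rate(self, variant_id: str) -> float:
        d = self.dosages(variant_id)
        return float((d != MISSING_CALL).sum() / len(d))

    def mac(self, variant_id: str) -> int:
        d = self.dosages(variant_id)
        return int(d[d != MISSING_CALL].sum())

    def carriers(self, variant_id: str) -> set[str]:
        d = self.dosages(variant_id)
        return {s for s, x in zip(self.samples, d) if x >= 1}

    def subset(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self._row[v] for v in variant_ids]
        return GenotypeMatrix(list(variant_ids), self.samples,
                              self.calls[rows, :])


@dataclass(frozen=True)
class PedigreeEntry:
    sample: str
    family: str
    affected: bool


class Pedigree:
    """Sample -> family / affected-status map."""

    def __init__(self, entries: Sequence[PedigreeEntry]) -> None:
        self.entries = list(entries)
        self._by_sample = {e.sample: e for e in entries}
        if len(self._by_sample) != len(entries):
            raise VariantTableError("duplicate sample in pedigree")

    def family_of(self, sample: str) -> str:
        return self._by_sample[sample].family

    @property
    def families(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.family not in seen:
                seen.append(e.family)
        return seen

    def members(self, family: str, affected_only: bool = False) -> list[str]:
        return [
            e.sample
            for e in self.entries
            if e.family == family and (e.affected or not affected_only)
        ]

    def __contains__(self, sample: str) -> bool:
        return sample in self._by_sample


@dataclass(frozen=True)
class CascadeStage:
    name: str
    n_after: int
    removed_examples: tuple[str, ...] = ()


@dataclass
class CascadeReport:
    stages: list[CascadeStage] = field(default_factory=list)

    def add(self, name: str, n_after: int,
            removed: Iterable[str] = ()) -> None:
        removed = tuple(list(removed)[:5])
        if self.stages and n_after > self.stages[-1].n_after:
            raise VariantTableError(
                f"cascade stage {name!r} increased the variant count"
            )
        self.stages.append(CascadeStage(name, n_after, removed))

    def counts(self) -> dict[str, int]:
        return {s.name: s.n_after for s in self.stages}


@dataclass(frozen=True)
class SharedVariant:
    variant: AnnotatedVariant
    carriers: frozenset[str]
    label: str  # both_families | family_specific


@dataclass(frozen=True)
class SegregationResult:
    variant: AnnotatedVariant
    carriers: frozenset[str]
    concordance: float
    perfect: bool
    inverse: bool  # carriers exactly complement the trait-positive set


@dataclass(frozen=True)
class CandidateVariant:
    variant: AnnotatedVariant
    carriers: frozenset[str]
    sharing: str
    concordance: float
    concordance_by_trait: Mapping[str, float] = field(default_factory=dict)
    pathways: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.carriers:
            raise VariantTableError(
                f"{self.variant.variant_id}: candidate with empty carrier set"
            )


@dataclass(frozen=True)
class GeneSetEnrichment:
    set_name: str
    overlap: int  # k
    set_size: int  # K
    candidates: int  # n
    universe: int  # N
    p_upper: float


# ---------------------------------------------------------------------------
# loading

DEFAULT_ANNOT_COLUMNS = {
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "transcript": "transcript",
    "func": "func",
    "nt_change": "nt_change",
    "aa_change": "aa_change",
    "cadd_phred": "cadd_phred",
    "sift": "sift",
    "polyphen": "polyphen",
    "dbsnp": "dbsnp",
}
FREQ_PREFIX = "freq_"


def _norm_func(token: str) -> str:
    try:
        return _FUNC_ALIASES[token.strip().lower()]
    except KeyError:
        raise VariantTableError(f"unknown functional class {token!r}") from None


def _absent(token: str) -> bool:
    return token.strip().lower() in _ABSENT_MARKERS


def _load_annotations(path: str | Path,
                      columns: Mapping[str, str]) -> list[AnnotatedVariant]:
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        rows = list(reader)
        header = reader.fieldnames or []
    freq_cols = [c for c in header if c.startswith(FREQ_PREFIX)]
    variants = []
    for i, row in enumerate(rows, start=2):
        def cell(key: str, default: str = "") -> str:
            col = columns.get(key)
            return row.get(col, default) if col else default

        try:
            pos = int(cell("pos"))
        except ValueError:
            raise VariantTableError(
                f"row {i}: non-integer position {cell('pos')!r}"
            ) from None
        freqs = {}
        for c in freq_cols:
            if not _absent(row[c]):
                try:
                    freqs[c[len(FREQ_PREFIX):]] = float(row[c])
                except ValueError:
                    raise VariantTableError(
                        f"row {i}: bad frequency {row[c]!r} in {c}"
                    ) from None
        cadd = None if _absent(cell("cadd_phred")) else float(cell("cadd_phred"))
        variants.append(AnnotatedVariant(
            chrom=cell("chrom"),
            pos=pos,
            ref=cell("ref"),
            alt=cell("alt"),
            gene=cell("gene"),
            func_class=_norm_func(cell("func")),
            transcript=cell("transcript"),
            nt_change=cell("nt_change"),
            aa_change=cell("aa_change"),
            pop_freqs=freqs,
            cadd_phred=cadd,
            sift=None if _absent(cell("sift")) else cell("sift"),
            polyphen=None if _absent(cell("polyphen")) else cell("polyphen"),
            dbsnp=None if _absent(cell("dbsnp")) else cell("dbsnp"),
        ))
    return variants


def _load_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids, rows = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise VariantTableError(
                f"{v.CHROM}:{v.POS}: multi-allelic record; split upstream"
            )
        variant_ids.append(f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}")
        row = []
        for g in v.genotypes:
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                row.append(MISSING_CALL)
            else:
                row.append(int(sum(1 for a in alleles if a > 0)))
        rows.append(row)
    vcf.close()
    return GenotypeMatrix(variant_ids, samples,
                          np.asarray(rows, dtype=np.int8).reshape(
                              len(variant_ids), len(samples)))


def _load_tsv_genotypes(path: str | Path) -> GenotypeMatrix:
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        samples = header[1:]
        variant_ids, rows = [], []
        for i, row in enumerate(reader, start=2):
            variant_ids.append(row[0])
            parsed = []
            for s, token in zip(samples, row[1:]):
                if _absent(token):
                    parsed.append(MISSING_CALL)
                elif token in ("0", "1", "2"):
                    parsed.append(int(token))
                else:
                    raise VariantTableError(
                        f"row {i}, sample {s}: malformed genotype {token!r}"
                    )
            rows.append(parsed)
    return GenotypeMatrix(variant_ids, samples,
                          np.asarray(rows, dtype=np.int8).reshape(
                              len(variant_ids), len(samples)))


def load_variant_table(
    annot_path: str | Path,
    geno_path: str | Path,
    columns: Mapping[str, str] | None = None,
    exclude_samples: Sequence[str] = (),
) -> tuple[list[AnnotatedVariant], GenotypeMatrix]:
    """Load an annotation TSV and genotypes (VCF or 0/1/2 matrix TSV).

    The two files are joined on ``chrom:pos:ref:alt``; a variant present in
    only one of them is an error.  *exclude_samples* drops samples flagged by
    upstream sample-level QC.
    """
    variants = _load_annotations(annot_path, columns or DEFAULT_ANNOT_COLUMNS)
    geno_path = Path(geno_path)
    if geno_path.suffix in (".vcf", ".gz", ".bcf"):
        gm = _load_vcf_genotypes(geno_path)
    else:
        gm = _load_tsv_genotypes(geno_path)
    if exclude_samples:
        keep = [i for i, s in enumerate(gm.samples)
                if s not in set(exclude_samples)]
        gm = GenotypeMatrix(gm.variant_ids,
                            [gm.samples[i] for i in keep],
                            gm.calls[:, keep])
    annot_ids = [v.variant_id for v in variants]
    only_annot = set(annot_ids) - set(gm.variant_ids)
    only_geno = set(gm.variant_ids) - set(annot_ids)
    if only_annot or only_geno:
        raise VariantTableError(
            "annotation/genotype mismatch; annotation-only: "
            f"{sorted(only_annot)[:5]}, genotype-only: {sorted(only_geno)[:5]}"
        )
    gm = gm.subset(annot_ids)  # align row order with the annotation table
    return variants, gm


def load_pedigree(path: str | Path) -> Pedigree:
    """3-column TSV: sample, family, affected (1/0 or yes/no)."""
    entries = []
    with open(path, "r", encoding="utf-8", newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            entries.append(PedigreeEntry(
                sample=row["sample"],
                family=row["family"],
                affected=row["affected"].strip().lower() in ("1", "yes", "true"),
            ))
    return Pedigree(entries)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# cascade filters

def qc_filter(
    variants: Sequence[AnnotatedVariant],
    gm: GenotypeMatrix,
    min_call_rate: float = 0.95,
) -> tuple[list[AnnotatedVariant], GenotypeMatrix, CascadeStage]:
    """Drop monomorphic (MAC = 0) and low call-rate variants."""
    kept, removed = [], []
    for v in variants:
        vid = v.variant_id
        if gm.mac(vid) == 0 or gm.call_rate(vid) < min_call_rate:
            removed.append(vid)
        else:
            kept.append(v)
    stage = CascadeStage("qc", len(kept), tuple(removed[:5]))
    return kept, gm.subset([v.variant_id for v in kept]), stage


def functional_class_filter(
    variants: Sequence[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], CascadeStage]:
    """Keep splicing/exonic-altering classes; drop synonymous and other."""
    kept = [v for v in variants if v.func_class in KEPT_FUNC_CLASSES]
    removed = [v.variant_id for v in variants
               if v.func_class not in KEPT_FUNC_CLASSES]
    return kept, CascadeStage("functional_class", len(kept), tuple(removed[:5]))


def rarity_filter(
    variants: Sequence[AnnotatedVariant],
    maf_cutoff: float = 0.2,
) -> tuple[list[AnnotatedVariant], CascadeStage]:
    """Drop common variants: maximum population frequency >= cutoff.

    A variant with no populated frequency column is treated as novel and kept.
    """
    kept = [v for v in variants
            if v.maf_max is None or v.maf_max < maf_cutoff]
    removed = [v.variant_id for v in variants
               if v.maf_max is not None and v.maf_max >= maf_cutoff]
    return kept, CascadeStage("rarity", len(kept), tuple(removed[:5]))


def deleteriousness_filter(
    variants: Sequence[AnnotatedVariant],
    cadd_cutoff: float = 20.0,
    allow_missing_cadd_for_indels: bool = True,
) -> tuple[list[AnnotatedVariant], CascadeStage]:
    """Keep CADD phred >= cutoff; unscored variants pass only if indels."""
    def passes(v: AnnotatedVariant) -> bool:
        if v.cadd_phred is None:
            return allow_missing_cadd_for_indels and v.func_class in INDEL_CLASSES
        return v.cadd_phred >= cadd_cutoff

    kept = [v for v in variants if passes(v)]
    removed = [v.variant_id for v in variants if not passes(v)]
    return kept, CascadeStage("deleteriousness", len(kept), tuple(removed[:5]))


# ---------------------------------------------------------------------------
# sharing / segregation

def shared_carrier_analysis(
    variants: Sequence[AnnotatedVariant],
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    mode: str = "between_families",
    family: str | None = None,
    subset: Sequence[str] | None = None,
) -> list[SharedVariant]:
    """Carrier sets and sharing labels under one of the two sharing analyses.

    ``between_families`` keeps variants with at least one carrier in every
    family; ``within_family`` keeps variants carried by every member of the
    given *subset* of one family (default: all of that family's samples).
    """
    if mode not in ("between_families", "within_family"):
        raise VariantTableError(f"unknown sharing mode {mode!r}")
    unknown = [s for s in gm.samples if s not in pedigree]
    if unknown:
        raise VariantTableError(f"samples missing from pedigree: {unknown}")
    families = pedigree.families
    out = []
    if mode == "between_families":
        for v in variants:
            carriers = gm.carriers(v.variant_id)
            carrier_families = {pedigree.family_of(s) for s in carriers}
            if all(f in carrier_families for f in families):
                out.append(SharedVariant(v, frozenset(carriers), BOTH_FAMILIES))
    else:
        if family is None:
            raise VariantTableError("within_family mode requires a family")
        members = list(subset) if subset is not None else pedigree.members(family)
        if not members:
            raise VariantTableError(f"family {family!r} has no members")
        for v in variants:
            carriers = gm.carriers(v.variant_id)
            if all(m in carriers for m in members):
                carrier_families = {pedigree.family_of(s) for s in carriers
                                    if s in pedigree}
                label = (BOTH_FAMILIES if len(carrier_families) > 1
                         else FAMILY_SPECIFIC)
                out.append(SharedVariant(v, frozenset(carriers), label))
    return out


def phenotype_segregation(
    variants: Sequence[AnnotatedVariant],
    gm: GenotypeMatrix,
    trait: Mapping[str, int],
) -> list[SegregationResult]:
    """Concordance between carrier status and a dichotomized trait.

    Concordance is the fraction of genotyped samples whose carrier status
    (dosage >= 1) equals their trait value; 1.0 flags perfect cosegregation,
    0.0 flags a perfectly inverse pattern.
    """
    missing = [s for s in gm.samples if s not in trait]
    if missing:
        raise VariantTableError(f"trait undefined for samples: {missing}")
    out = []
    for v in variants:
        carriers = gm.carriers(v.variant_id)
        agree = sum(
            int((s in carriers) == bool(trait[s])) for s in gm.samples
        )
        conc = agree / len(gm.samples)
        out.append(SegregationResult(
            variant=v,
            carriers=frozenset(carriers),
            concordance=conc,
            perfect=conc == 1.0,
            inverse=conc == 0.0,
        ))
    return sorted(out, key=lambda r: (-r.concordance, r.variant.variant_id))


def pathway_enrichment(
    candidate_genes: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    universe_size: int,
    universe: set[str] | None = None,
) -> list[GeneSetEnrichment]:
    """Upper-tail hypergeometric enrichment per gene set.

    p = P(X >= k) with X ~ Hypergeom(N=universe_size, K=set size,
    n=candidate-list size).
    """
    genes = set(candidate_genes)
    n = len(genes)
    out = []
    for name, members in gene_sets.items():
        if universe is not None:
            stray = members - universe
            if stray:
                warnings.warn(
                    f"gene set {name!r}: {len(stray)} gene(s) absent from "
                    f"the universe", stacklevel=2,
                )
        big_k = len(members)
        if universe_size < max(big_k, n):
            raise VariantTableError(
                "universe smaller than a gene set or the candidate list"
            )
        k = len(genes & members)
        p = float(sps.hypergeom.sf(k - 1, universe_size, big_k, n))
        out.append(GeneSetEnrichment(
            set_name=name, overlap=k, set_size=big_k, candidates=n,
            universe=universe_size, p_upper=min(p, 1.0),
        ))
    return sorted(out, key=lambda e: (e.p_upper, e.set_name))


# ---------------------------------------------------------------------------
# orchestration

def prioritize(
    variants: Sequence[AnnotatedVariant],
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    traits: Mapping[str, Mapping[str, int]] | None = None,
    maf_cutoff: float = 0.2,
    cadd_cutoff: float = 20.0,
    min_call_rate: float = 0.95,
    within_family_subsets: Mapping[str, Sequence[str]] | None = None,
    gene_sets: Mapping[str, set[str]] | None = None,
    universe_size: int | None = None,
) -> tuple[list[CandidateVariant], CascadeReport, list[GeneSetEnrichment]]:
    """Run the full cascade and emit candidates with provenance.

    Sharing keeps the union of the between-family analysis and the
    within-family analysis run for every family (subsets overridable via
    *within_family_subsets*).
    """
    report = CascadeReport()
    report.add("input", len(variants))
    v_qc, gm_qc, stage = qc_filter(variants, gm, min_call_rate)
    report.add(stage.name, stage.n_after, stage.removed_examples)
    v_func, stage = functional_class_filter(v_qc)
    report.add(stage.name, stage.n_after, stage.removed_examples)
    v_rare, stage = rarity_filter(v_func, maf_cutoff)
    report.add(stage.name, stage.n_after, stage.removed_examples)
    v_del, stage = deleteriousness_filter(v_rare, cadd_cutoff)
    report.add(stage.name, stage.n_after, stage.removed_examples)
    gm_del = gm_qc.subset([v.variant_id for v in v_del])

    shared: dict[str, SharedVariant] = {}
    for sv in shared_carrier_analysis(v_del, gm_del, pedigree,
                                      mode="between_families"):
        shared[sv.variant.variant_id] = sv
    for fam in pedigree.families:
        subset = (within_family_subsets or {}).get(fam)
        for sv in shared_carrier_analysis(v_del, gm_del, pedigree,
                                          mode="within_family", family=fam,
                                          subset=subset):
            shared.setdefault(sv.variant.variant_id, sv)
    v_shared = [v for v in v_del if v.variant_id in shared]
    report.add("sharing", len(v_shared),
               (v.variant_id for v in v_del if v.variant_id not in shared))

    conc_by_trait: dict[str, dict[str, float]] = {v.variant_id: {}
                                                  for v in v_shared}
    if traits:
        gm_shared = gm_del.subset([v.variant_id for v in v_shared])
        for trait_name, trait in traits.items():
            for seg in phenotype_segregation(v_shared, gm_shared, trait):
                conc_by_trait[seg.variant.variant_id][trait_name] = (
                    seg.concordance
                )

    candidates = []
    for v in v_shared:
        sv = shared[v.variant_id]
        conc = conc_by_trait[v.variant_id]
        best = max(conc.values()) if conc else 0.0
        tags = tuple(
            name for name, members in (gene_sets or {}).items()
            if v.gene in members
        )
        candidates.append(CandidateVariant(
            variant=v, carriers=sv.carriers, sharing=sv.label,
            concordance=best, concordance_by_trait=conc, pathways=tags,
        ))

    enrichment: list[GeneSetEnrichment] = []
    if gene_sets and universe_size:
        enrichment = pathway_enrichment(
            {c.variant.gene for c in candidates}, gene_sets, universe_size
        )
    return candidates, report, enrichment


def compound_het_genes(
    candidates: Sequence[CandidateVariant],
) -> dict[str, dict[str, list[str]]]:
    """Gene -> sample -> candidate variant ids, for samples carrying >= 2
    distinct candidate variants of that gene."""
    per_gene: dict[str, dict[str, list[str]]] = {}
    for c in candidates:
        for s in c.carriers:
            per_gene.setdefault(c.variant.gene, {}).setdefault(s, []).append(
                c.variant.variant_id
            )
    return {
        gene: {s: sorted(vids) for s, vids in samples.items() if len(vids) >= 2}
        for gene, samples in per_gene.items()
        if any(len(vids) >= 2 for vids in samples.values())
    }


# ---------------------------------------------------------------------------
# genotype-count summary (candidate polymorphism check)

@dataclass(frozen=True)
class GenotypeCounts:
    rsid: str
    genotypes: Mapping[str, int]
    alleles: Mapping[str, int]


def count_genotypes(rows: Sequence, rsid: str) -> GenotypeCounts:
    """Exact genotype and allele counts for one rsID over genotype rows."""
    if not rows:
        raise VariantTableError("count_genotypes: empty row list")
    genotypes: dict[str, int] = {}
    alleles: dict[str, int] = {}
    for row in rows:
        try:
            gt = row.genotypes[rsid]
        except KeyError:
            raise VariantTableError(
                f"{row.patient_id}: unknown rsid {rsid!r}"
            ) from None
        genotypes[gt] = genotypes.get(gt, 0) + 1
        for a in gt:
            alleles[a] = alleles.get(a, 0) + 1
    return GenotypeCounts(rsid=rsid, genotypes=genotypes, alleles=alleles)


# ---------------------------------------------------------------------------
# packaged fixture

def _ref_alt_from_nt(nt_change: str) -> tuple[str, str]:
    # c.G850A -> (G, A); c.525+2T>G -> (T, G); c.99_100insCTG -> (N, NCTG)
    token = nt_change.removeprefix("c.")
    if "ins" in token:
        return "N", "N" + token.split("ins", 1)[1]
    if ">" in token:
        lhs, alt = token.split(">", 1)
        return lhs[-1], alt.strip()
    body = token.lstrip("0123456789+-_")
    if len(body) >= 2:
        return body[0], body[-1]
    raise VariantTableError(f"cannot parse nucleotide change {nt_change!r}")


def load_bundled_table5() -> list[AnnotatedVariant]:
    """The 16 published rare deleterious variants.

    Genomic coordinates are not published for these rows; placeholder
    coordinates (chromosome ``un``, ordinal positions) are assigned so the
    records satisfy the variant-key contract.
    """
    ref_path = resources.files("lopdkit.data").joinpath("table5_variants.tsv")
    with resources.as_file(ref_path) as p, open(p, encoding="utf-8") as handle:
        rows = list(csv.DictReader(handle, delimiter="\t"))
    variants = []
    for i, row in enumerate(rows, start=1):
        ref, alt = _ref_alt_from_nt(row["nt_change"])
        freqs = {}
        if not _absent(row["maf_max"]):
            freqs["max_reported"] = float(row["maf_max"])
        variants.append(AnnotatedVariant(
            chrom="un",
            pos=i,
            ref=ref,
            alt=alt,
            gene=row["gene"],
            func_class=_norm_func(row["func"]),
            transcript=row["accession"],
            nt_change=row["nt_change"],
            aa_change="" if _absent(row["aa_change"]) else row["aa_change"],
            pop_freqs=freqs,
            cadd_phred=(None if _absent(row["cadd_phred"])
                        else float(row["cadd_phred"])),
            sift=None if _absent(row["sift"]) else row["sift"],
            polyphen=None if _absent(row["polyphen"]) else row["polyphen"],
            dbsnp=None if _absent(row["dbsnp"]) else row["dbsnp"],
        ))
    return variants
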