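# lopdkit

Clinical severity scoring and family-based rare-variant modifier
prioritization for small late-onset Pompe disease (LOPD) sibling cohorts.

The package implements two connected analyses:

1. **Severity index (SI).** A 14-item ordinal grading rubric (age at onset,
   muscle strength, six-minute walk, motor disability, spirometry, body mass,
   vitamin D, bone density, fractures, vascular and cardiac findings, immune
   response to enzyme replacement) summed into a per-patient SI, mapped to
   five severity classes and dichotomized at SI > 20 into lower (`VM_M`) and
   higher (`M_S`) severity groups. The published 11-sibling clinical table,
   grade matrix and genotype table ship as packaged fixtures.
2. **Variant prioritization cascade.** Genotype QC (minor-allele count, call
   rate) → functional-class selection → rarity (max population MAF < 0.2) →
   deleteriousness (CADD phred ≥ 20, with an exception for unscored indels) →
   carrier sharing between/within families → cosegregation with dichotomized
   traits → hypergeometric gene-set enrichment.

Small-sample statistics (exact Mann–Whitney U with mid-rank ties, chi-square,
Pearson correlation, optional Benjamini–Hochberg annotation) and a seeded
synthetic-data generator (latent-severity cohorts, background + planted
modifier variants with recorded ground truth) make every stage testable
without access to the original sequencing data.

## Layout

| module | contents |
| --- | --- |
| `lopdkit.clinical_records` | domain types, TSV ingestion/validation, packaged table fixtures |
| `lopdkit.severity_index` | grading scheme (YAML-serialized), per-item grading, SI, classes, dichotomy |
| `lopdkit.cohort_stats` | descriptives, exact Mann–Whitney, chi-square, Pearson, group report |
| `lopdkit.variant_prioritization` | variant/genotype loading, cascade filters, sharing, segregation, enrichment |
| `lopdkit.synthetic_data` | seeded cohort + variant simulator with planted-truth bookkeeping |
| `lopdkit.workflow` / `lopdkit.cli` | configured end-to-end runs and the `lopdkit` command |

## CLI

```sh
lopdkit simulate --seed 7 --out sim/                 # synthetic bundle (5 files)
lopdkit score --clinical clinical.tsv --out grades.tsv [--overrides o.tsv]
lopdkit stats --clinical clinical.tsv --grades grades.tsv \
    --vars 6MWT,FVC,DFVC,VDD,BMD_FN,GSGC --out table3.tsv
lopdkit prioritize --config run.yaml --out candidates.tsv --report cascade.tsv
lopdkit run --config run.yaml                        # full pipeline
```

`run.yaml` mirrors `lopdkit.workflow.RunConfig`: paths (`clinical`,
`annotations`, `genotypes`, `pedigree`, optional `overrides`, `gene_sets`,
`truth`), thresholds (`si_threshold`, `maf_cutoff`, `cadd_cutoff`,
`min_call_rate`) and `out_dir`. Outputs (grade matrix, association report,
candidate table, cascade report, `summary.json` with a config hash) are
byte-reproducible for an unchanged config.

## Data formats

UTF-8 TSV everywhere: clinical tables use the published column labels (alias
map for spelling variants; `n.p.`/`na` missing markers are typed by reason),
annotations use a flat dialect with `freq_<population>` columns, genotypes
come as VCF (`GT` only, pre-split records) or a 0/1/2 matrix TSV, pedigrees
as `sample/family/affected`, gene sets as GMT.
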