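# Default 14-item severity grading scheme.
#
# Bin edges are written as strings and parsed as exact decimals; a measurement
# is rounded to the item's `precision` (half-up) before bin lookup.  `lo`/`hi`
# are closed bounds; null means unbounded on that side.  Boundary placement
# between adjacent published bins follows the convention pinned by the
# regression fixtures (e.g. AAO 50 -> grade 1, DFVC 20 -> grade 2, FVC 80 -> 0).
si_max: 47
classes:
  - {label: very_mild, lo: 1, hi: 10}
  - {label: mild, lo: 11, hi: 20}
  - {label: moderate, lo: 21, hi: 29}
  - {label: severe, lo: 30, hi: 39}
  - {label: very_severe, lo: 40, hi: 47}
items:
  - id: AAO
    kind: numeric
    field: aao
    precision: 0
    direction: lower_worse
    missing_policy: unavailable_zero
    max_grade: 6
    bins:
      - {grade: 1, lo: "50", hi: null}
      - {grade: 2, lo: "40", hi: "49"}
      - {grade: 3, lo: "30", hi: "39"}
      - {grade: 4, lo: "15", hi: "29"}
      - {grade: 5, lo: "10", hi: "14"}
      - {grade: 6, lo: "1", hi: "9"}
  - id: MMT
    kind: numeric
    field: mmt_mrc
    precision: 0
    direction: lower_worse
    missing_policy: unavailable_zero
    max_grade: 4
    bins:
      - {grade: 0, lo: "100", hi: null}
      - {grade: 1, lo: "90", hi: "99"}
      - {grade: 2, lo: "80", hi: "89"}
      - {grade: 3, lo: "70", hi: "79"}
      - {grade: 4, lo: null, hi: "69"}
  - id: SIXMWT
    kind: numeric
    field: six_mwt
    precision: 0
    direction: lower_worse
    missing_policy: unavailable_zero
    max_grade: 6
    sex_stratified: true
    bins_female:
      - {grade: 0, lo: "423", hi: null}
      - {grade: 1, lo: "362", hi: "422"}
      - {grade: 2, lo: "301", hi: "361"}
      - {grade: 3, lo: "240", hi: "300"}
      - {grade: 4, lo: "179", hi: "239"}
      - {grade: 5, lo: "118", hi: "178"}
      - {grade: 6, lo: null, hi: "117"}
    bins_male:
      - {grade: 0, lo: "536", hi: null}
      - {grade: 1, lo: "476", hi: "535"}
      - {grade: 2, lo: "395", hi: "475"}
      - {grade: 3, lo: "315", hi: "394"}
      - {grade: 4, lo: "234", hi: "314"}
      - {grade: 5, lo: "150", hi: "233"}
      - {grade: 6, lo: null, hi: "149"}
  - id: GSCG
    kind: numeric
    field: gscg
    precision: 0
    direction: higher_worse
    missing_policy: unavailable_zero
    max_grade: 4
    bins:
      - {grade: 0, lo: "4", hi: "4"}
      - {grade: 1, lo: "5", hi: "8"}
      - {grade: 2, lo: "9", hi: "15"}
      - {grade: 3, lo: "16", hi: "21"}
      - {grade: 4, lo: "22", hi: "27"}
  - id: FVC
    kind: numeric
    field: fvc_upright
    precision: 0
    direction: lower_worse
    missing_policy: worst_if_not_performed
    max_grade: 4
    bins:
      - {grade: 0, lo: "80", hi: null}
      - {grade: 1, lo: "70", hi: "79"}
      - {grade: 2, lo: "60", hi: "69"}
      - {grade: 3, lo: "50", hi: "59"}
      - {grade: 4, lo: null, hi: "49"}
  - id: DFVC
    kind: numeric
    field: delta_fvc
    precision: 0
    direction: higher_worse
    missing_policy: worst_if_not_performed
    max_grade: 4
    bins:
      - {grade: 0, lo: null, hi: "9"}
      - {grade: 1, lo: "10", hi: "14"}
      - {grade: 2, lo: "15", hi: "20"}
      - {grade: 3, lo: "21", hi: "30"}
      - {grade: 4, lo: "31", hi: null}
  - id: BMI
    kind: numeric
    field: bmi
    precision: 1
    direction: higher_worse
    missing_policy: unavailable_zero
    max_grade: 4
    bins:
      - {grade: 0, lo: null, hi: "24.9"}
      - {grade: 1, lo: "25.0", hi: "29.9"}
      - {grade: 2, lo: "30.0", hi: "35.9"}
      - {grade: 3, lo: "36.0", hi: "40.0"}
      - {grade: 4, lo: "40.1", hi: null}
  - id: VDD
    kind: numeric
    field: vdd
    precision: 1
    direction: lower_worse
    missing_policy: unavailable_zero
    max_grade: 2
    bins:
      - {grade: 0, lo: "30.0", hi: null}
      - {grade: 1, lo: "20.0", hi: "29.9"}
      - {grade: 2, lo: null, hi: "19.9"}
  - id: BMD
    kind: bmd
    field: bmd_tscores
    missing_policy: unavailable_zero
    max_grade: 2
    osteoporosis_tscore: "-2.5"
    osteopenia_tscore: "-1.0"
    osteoporosis_min_districts: 2
  - id: BF
    kind: boolean
    field: bf
    missing_policy: unavailable_zero
    max_grade: 1
  - id: BAD
    kind: boolean
    field: bad
    missing_policy: unavailable_zero
    max_grade: 1
  - id: MVP
    kind: boolean
    field: mvp
    missing_policy: unavailable_zero
    max_grade: 1
  - id: IGG
    kind: positive_titre
    field: igg_rhgaa
    missing_policy: unavailable_zero
    max_grade: 1
  - id: ERTAE
    kind: boolean
    field: ert_ae
    missing_policy: unavailable_zero
    max_grade: 1
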