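# Built-in predictor registry: 39 missense/conservation/consequence-agnostic/
# disease-specific tools with their published decision thresholds and score
# directions.  Comparators are strict: a variant is called pathogenic when its
# score is strictly greater (strict_greater) or strictly less (strict_less)
# than the reference threshold; a score exactly at the threshold is benign.
# Tools without a published threshold and with a score range of [0, 1] use a
# 0.5 decision boundary.  cVEP emits categorical labels which are mapped to
# fixed numeric surrogates and is excluded from multi-threshold analyses
# (ROC curves, threshold calibration).
version: "table1-v1"
genome_build: GRCh37
tools:
  SIFT:
    field: SIFT
    comparator: strict_less
    reference_threshold: 0.01
    scope: protein
    range: [0, 1]
  MutPred:
    field: MutPred
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
    range: [0, 1]
  Polyphen2_HDIV:
    field: Polyphen2_HDIV
    comparator: strict_greater
    reference_threshold: 0.978
    scope: protein
    range: [0, 1]
  Polyphen2_HVAR:
    field: Polyphen2_HVAR
    comparator: strict_greater
    reference_threshold: 0.978
    scope: protein
    range: [0, 1]
  MutationAssessor:
    field: MutationAssessor
    comparator: strict_greater
    reference_threshold: 1.935
    scope: protein
  Condel:
    field: Condel
    comparator: strict_greater
    reference_threshold: 0.98
    scope: protein
  VEST4:
    field: VEST4
    comparator: strict_greater
    reference_threshold: 0.764
    scope: protein
    range: [0, 1]
  MutationTaster2:
    field: MutationTaster2
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
    range: [0, 1]
  FATHMM:
    field: FATHMM
    comparator: strict_less
    reference_threshold: -4.14
    scope: protein
  PROVEAN:
    field: PROVEAN
    comparator: strict_less
    reference_threshold: -2.5
    scope: protein
  MetaSVM:
    field: MetaSVM
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
  MetaLR:
    field: MetaLR
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
    range: [0, 1]
  M-CAP:
    field: M_CAP
    comparator: strict_greater
    reference_threshold: 0.025
    scope: protein
    range: [0, 1]
  REVEL:
    field: REVEL
    comparator: strict_greater
    reference_threshold: 0.644
    scope: protein
    range: [0, 1]
  MPC:
    field: MPC
    comparator: strict_greater
    reference_threshold: 1.36
    scope: protein
  MTR:
    field: MTR
    comparator: strict_less
    reference_threshold: 0.5
    scope: protein
  PrimateAI:
    field: PrimateAI
    comparator: strict_greater
    reference_threshold: 0.79
    scope: protein
    range: [0, 1]
  ClinPred:
    field: ClinPred
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
    range: [0, 1]
  MISTIC:
    field: MISTIC
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
    range: [0, 1]
  cVEP:
    field: cVEP
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
    range: [0, 1]
    excluded_from_multithreshold: true
    categorical_map:
      Benign: 0.0
      Likely_benign: 0.25
      Likely_pathogenic: 0.75
      Pathogenic: 1.0
  MVP:
    field: MVP
    comparator: strict_greater
    reference_threshold: 0.7
    scope: protein
    range: [0, 1]
  VARITY:
    field: VARITY
    comparator: strict_greater
    reference_threshold: 0.75
    scope: protein
    range: [0, 1]
  MutFormer:
    field: MutFormer
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
    range: [0, 1]
  EVE:
    field: EVE
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
    range: [0, 1]
  MutScore:
    field: MutScore
    comparator: strict_greater
    reference_threshold: 0.5
    scope: protein
    range: [0, 1]
  phastCons:
    field: phastCons
    comparator: strict_greater
    reference_threshold: 0.99
    scope: conservation
    range: [0, 1]
  phyloP:
    field: phyloP
    comparator: strict_greater
    reference_threshold: 7.367
    scope: conservation
  SiPhy:
    field: SiPhy
    comparator: strict_greater
    reference_threshold: 12.7
    scope: conservation
  GERP:
    field: GERP
    comparator: strict_greater
    reference_threshold: 4.4
    scope: conservation
  CDTS:
    field: CDTS
    comparator: strict_less
    reference_threshold: 10
    scope: conservation
  GWAVA:
    field: GWAVA
    comparator: strict_greater
    reference_threshold: 0.4
    scope: consequence_agnostic
    range: [0, 1]
  FATHMM-MKL:
    field: FATHMM_MKL
    comparator: strict_greater
    reference_threshold: 0.5
    scope: consequence_agnostic
    range: [0, 1]
  DANN:
    field: DANN
    comparator: strict_greater
    reference_threshold: 0.9
    scope: consequence_agnostic
    range: [0, 1]
  Eigen:
    field: Eigen
    comparator: strict_greater
    reference_threshold: 1
    scope: consequence_agnostic
  ReMM:
    field: ReMM
    comparator: strict_greater
    reference_threshold: 0.984
    scope: consequence_agnostic
    range: [0, 1]
  CAPICE:
    field: CAPICE
    comparator: strict_greater
    reference_threshold: 0.02
    scope: consequence_agnostic
    range: [0, 1]
  CADD:
    field: CADD
    comparator: strict_greater
    reference_threshold: 25.3
    scope: consequence_agnostic
  CardioVAI:
    field: CardioVAI
    comparator: strict_greater
    reference_threshold: 2
    scope: disease_specific
  CardioBoost:
    field: CardioBoost
    comparator: strict_greater
    reference_threshold: 0.9
    scope: disease_specific
    range: [0, 1]
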