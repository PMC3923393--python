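# Default CDK classification taxonomy: eight subfamilies anchored on the
# human CDK complement, with within-subfamily clades where the subfamily
# holds more than one human paralog group. Accession style is
# {organism}-{protein}; swap in database accessions to match your inputs.
family: CDK
outgroups: [Hsa-GSK3alpha, Hsa-MAK, Hsa-HCDKL1]
subfamilies:
  - label: CDK1
    clades:
      - {label: CDK1, references: [Hsa-CDK1]}
      - {label: CDK2/3, references: [Hsa-CDK2, Hsa-CDK3]}
  - label: CDK4/6
    clades:
      - {label: CDK4/6, references: [Hsa-CDK4, Hsa-CDK6]}
  - label: CDK5
    clades:
      - {label: CDK5, references: [Hsa-CDK5]}
      - {label: CDK16/17/18, references: [Hsa-CDK16, Hsa-CDK17, Hsa-CDK18]}
      - {label: CDK14/15, references: [Hsa-CDK14, Hsa-CDK15]}
  - label: CDK7
    clades:
      - {label: CDK7, references: [Hsa-CDK7]}
  - label: CDK8/19
    clades:
      - {label: CDK8/19, references: [Hsa-CDK8, Hsa-CDK19]}
  - label: CDK9
    clades:
      - {label: CDK9, references: [Hsa-CDK9]}
      - {label: CDK12/13, references: [Hsa-CDK12, Hsa-CDK13]}
  - label: CDK10/11
    clades:
      - {label: CDK10, references: [Hsa-CDK10]}
      - {label: CDK11, references: [Hsa-CDK11A, Hsa-CDK11B]}
  - label: CDK20
    clades:
      - {label: CDK20, references: [Hsa-CDK20]}
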