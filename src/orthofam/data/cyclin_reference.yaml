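# Default cyclin classification taxonomy: sixteen metazoan subfamilies plus
# three fungus-specific ones (CLB, CLN, PCL), each tagged with its group
# (cyclin B-like / Y-like / C-like). Anchors are the human cyclin
# complement and the S. cerevisiae fungal cyclins.
family: cyclin
outgroups: [Hsa-CABLES1, Hsa-CABLES2]
subfamilies:
  - label: cyclin B
    group: cyclin B-like
    clades:
      - {label: cyclin B, references: [Hsa-CCNB1, Hsa-CCNB2, Hsa-CCNB3]}
  - label: cyclin A
    group: cyclin B-like
    clades:
      - {label: cyclin A, references: [Hsa-CCNA1, Hsa-CCNA2]}
  - label: cyclin D
    group: cyclin B-like
    clades:
      - {label: cyclin D, references: [Hsa-CCND1, Hsa-CCND2, Hsa-CCND3]}
  - label: cyclin E
    group: cyclin B-like
    clades:
      - {label: cyclin E, references: [Hsa-CCNE1, Hsa-CCNE2]}
  - label: cyclin J
    group: cyclin B-like
    clades:
      - {label: cyclin J, references: [Hsa-CCNJ]}
  - label: cyclin F
    group: cyclin B-like
    clades:
      - {label: cyclin F, references: [Hsa-CCNF]}
  - label: cyclin G
    group: cyclin B-like
    clades:
      - {label: cyclin G, references: [Hsa-CCNG1, Hsa-CCNG2]}
  - label: cyclin I
    group: cyclin B-like
    clades:
      - {label: cyclin I, references: [Hsa-CCNI]}
  - label: cyclin O
    group: cyclin B-like
    clades:
      - {label: cyclin O, references: [Hsa-CCNO]}
  - label: CLB
    group: cyclin B-like
    clades:
      - {label: CLB, references: [Sce-CLB1, Sce-CLB2, Sce-CLB5]}
  - label: CLN
    group: cyclin B-like
    clades:
      - {label: CLN, references: [Sce-CLN1, Sce-CLN2, Sce-CLN3]}
  - label: cyclin Y
    group: cyclin Y-like
    clades:
      - {label: cyclin Y, references: [Hsa-CCNY]}
  - label: PCL
    group: cyclin Y-like
    clades:
      - {label: PCL, references: [Sce-PCL1, Sce-PCL2]}
  - label: cyclin C
    group: cyclin C-like
    clades:
      - {label: cyclin C, references: [Hsa-CCNC]}
  - label: cyclin H
    group: cyclin C-like
    clades:
      - {label: cyclin H, references: [Hsa-CCNH]}
  - label: cyclin L
    group: cyclin C-like
    clades:
      - {label: cyclin L, references: [Hsa-CCNL1, Hsa-CCNL2]}
  - label: cyclin K
    group: cyclin C-like
    clades:
      - {label: cyclin K, references: [Hsa-CCNK]}
  - label: cyclin T
    group: cyclin C-like
    clades:
      - {label: cyclin T, references: [Hsa-CCNT1, Hsa-CCNT2]}
  - label: Fam58
    group: cyclin C-like
    clades:
      - {label: Fam58, references: [Hsa-FAM58A]}
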