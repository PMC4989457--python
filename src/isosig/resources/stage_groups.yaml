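# Early/late stage-label groupings per tumor type and stage class.
# version 1 — defaults for 12 TCGA tumor types: earliest vs latest
# available stage per type, with adjacent stages merged where a single
# stage has too few samples.  Absent entries have insufficient samples
# or no annotation.  Users may supply their own file with the same
# layout.
version: 1
tumor_types:
  BRCA:
    T: {early: [T1], late: [T3, T4]}
    N: {early: [N0], late: [N2, N3]}
    M: {early: [M0], late: [M1]}
    S: {early: [S1], late: [S4]}
  COAD:
    T: {early: [T1, T2], late: [T4]}
    N: {early: [N0], late: [N2]}
    M: {early: [M0], late: [M1]}
    S: {early: [S1], late: [S4]}
  HNSC:
    T: {early: [T1], late: [T4]}
    N: {early: [N0], late: [N2, N3]}
    S: {early: [S1, S2], late: [S4]}
  KICH:
    T: {early: [T1], late: [T3, T4]}
    S: {early: [S1], late: [S3, S4]}
  KIRC:
    T: {early: [T1], late: [T3, T4]}
    N: {early: [N0], late: [N1]}
    M: {early: [M0], late: [M1]}
    S: {early: [S1], late: [S4]}
  KIRP:
    T: {early: [T1], late: [T3, T4]}
    N: {early: [N0], late: [N1, N2]}
    S: {early: [S1], late: [S3, S4]}
  LUSC:
    T: {early: [T1], late: [T3, T4]}
    N: {early: [N0], late: [N2, N3]}
    S: {early: [S1], late: [S3, S4]}
  LUAD:
    T: {early: [T1], late: [T3, T4]}
    N: {early: [N0], late: [N2, N3]}
    M: {early: [M0], late: [M1]}
    S: {early: [S1], late: [S3, S4]}
  OV:
    S: {early: [S2], late: [S4]}
  PRAD:
    T: {early: [T2], late: [T3, T4]}
    N: {early: [N0], late: [N1]}
  SKCM:
    M: {early: [M0], late: [M1]}
  THCA:
    T: {early: [T1], late: [T3, T4]}
    N: {early: [N0], late: [N1]}
    S: {early: [S1], late: [S4]}
# Breast subgroups by estrogen-receptor status (marker-gene quantile split).
subtypes:
  BRCA_ER_neg:
    T: {early: [T1], late: [T3, T4]}
    N: {early: [N0], late: [N2, N3]}
    S: {early: [S1], late: [S3, S4]}
  BRCA_ER_pos:
    T: {early: [T1], late: [T3, T4]}
    N: {early: [N0], late: [N2, N3]}
    S: {early: [S1], late: [S3, S4]}
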