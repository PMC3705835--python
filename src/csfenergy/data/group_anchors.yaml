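# Per-syndrome CEB quantile anchors used to calibrate the synthetic cohort
# generator: [minimum, 2.5th percentile, 1st quartile, median, 3rd quartile,
# 97.5th percentile, maximum], with the group size n of the reference cohort
# study (total 8183).  Tumorous records are generated separately for TO and
# TP; cohort statistics pool them into the combined "TO + TP" group.
#
# The glucose/cellularity blocks below are generator plumbing, NOT published
# values: per-group plausible ranges chosen only to satisfy the syndrome
# definitions (pleocytosis > 4/uL, composition tolerances, control reference
# ranges).  They are fully configurable.
version: 1
groups:
  CONTROL:
    n: 235
    anchors: [27.45, 28.46, 30.36, 31.31, 32.05, 33.41, 34.30]
  GO:
    n: 64
    anchors: [7.00, 10.06, 26.24, 29.55, 31.12, 33.26, 35.03]
  GP:
    n: 766
    anchors: [-2996.50, -1158.70, -40.99, 4.68, 20.81, 31.75, 33.55]
  LO:
    n: 1200
    anchors: [-1249.00, 24.06, 30.14, 31.12, 31.97, 33.35, 35.11]
  LP:
    n: 1610
    anchors: [-3980.50, -3.29, 26.39, 29.77, 31.24, 33.26, 37.36]
  MO:
    n: 2699
    anchors: [-457.69, 11.44, 28.70, 30.45, 31.68, 33.42, 37.95]
  MP:
    n: 1457
    anchors: [-1360.00, -52.05, 16.82, 25.96, 29.56, 32.66, 36.50]
  TO:
    n: 31
    anchors: [-280.40, -223.50, 27.28, 31.13, 31.72, 32.49, 32.50]
  TP:
    n: 121
    anchors: [-835.00, -671.73, -6.73, 19.72, 27.94, 32.49, 33.40]
plumbing:
  # group-conditional CSF glucose ranges (mmol/L); burst-range records
  # (CEB <= 10) draw from the depleted range instead
  glucose_default: [1.8, 4.0]
  glucose_control: [2.5, 4.5]
  glucose_burst: [0.15, 1.5]
  # CSF/serum glucose quotient bands
  q_glu_control: [0.55, 0.65]
  q_glu_inflamed: [0.45, 0.65]
  q_glu_burst: [0.15, 0.45]
  # erythrocyte-admixture substructure of GP: share of the CEB > 10 subgroup
  # carrying an artificial blood admixture (erythrocytes > 100/uL)
  gp_admixture_fraction: 0.338
  admixture_erythrocytes_range: [101.0, 5000.0]
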