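# Subtype-correlation risk-of-recurrence (ROR-S) coefficients as published
# by Parker et al., J Clin Oncol 2009: risk = sum_k coef_k * Pearson
# correlation of the sample with intrinsic-subtype centroid k. The centroid
# table itself is an input (it is not redistributed here); coefficient keys
# must match the centroid column names.
coefficients:
  Basal: 0.05
  Her2: 0.12
  LumA: -0.34
  LumB: 0.23
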