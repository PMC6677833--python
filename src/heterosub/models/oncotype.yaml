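# 21-gene recurrence-score (RS) model: 16 scored genes in 4 weighted groups
# plus 3 singleton genes, referenced to the mean of 5 housekeeping genes.
# Group weights and RS coefficients as published by Paik et al., N Engl J
# Med 2004 (21-gene assay). Gene symbols are current HGNC names
# (ERBB2 = HER2, ESR1 = ER, BIRC5 = Survivin, AURKA = STK15, CTSV = CTSL2).
# Floors (her2 group 8.0, proliferation group 6.5) apply to the RT-PCR
# reference-normalized scale only; they are inactive unless
# apply_group_thresholds is enabled on the model.
housekeeping: [ACTB, GAPDH, GUSB, RPLP0, TFRC]
groups:
  her2:
    genes: {GRB7: 0.9, ERBB2: 0.1}
    divisor: 1.0
    floor: 8.0
  estrogen:
    genes: {ESR1: 0.8, PGR: 1.2, BCL2: 1.0, SCUBE2: 1.0}
    divisor: 4.0
  proliferation:
    genes: {BIRC5: 1.0, MKI67: 1.0, MYBL2: 1.0, CCNB1: 1.0, AURKA: 1.0}
    divisor: 5.0
    floor: 6.5
  invasion:
    genes: {CTSV: 1.0, MMP11: 1.0}
    divisor: 2.0
rs_coefficients:
  groups: {her2: 0.47, estrogen: -0.34, proliferation: 1.04, invasion: 0.10}
  genes: {CD68: 0.05, GSTM1: -0.08, BAG1: -0.07}
# Affymetrix U133A probe pinned for CD68 when collapsing probe-level arrays.
pinned_probes: {CD68: "203507_at"}
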