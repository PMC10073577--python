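# ICD-10 prefixes defining the maternal condition covariates, matched
# against diagnoses between three months before pregnancy onset and
# delivery (window configurable in code).  Defaults are broad chapter
# prefixes; replace with a validated list for real analyses.
hypertension: [I10, I11, I12, I13, I14, I15]
diabetes: [E10, E11, E12, E13, E14, O24]
obesity: [E66]
epilepsy: [G40]
phenylketonuria: [E70.0]
caesarean: [O82]
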