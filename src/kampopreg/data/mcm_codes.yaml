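# Major congenital malformation (MCM) code list, grouped by the ten
# organ-system labels used in reporting.  Entries are ICD-10 prefixes
# within Q00-Q89; a diagnosis counts as an MCM when it matches an
# included prefix and does not match any excluded_minor prefix.
# Chromosomal abnormalities (Q90-Q99) are handled at the cohort stage,
# not here.  The excluded_minor list is a EUROCAT-style minor-anomaly
# subset; both lists are configuration, not a clinical assertion.
included:
  nervous: [Q00, Q01, Q02, Q03, Q04, Q05, Q06, Q07]
  eye_ear_face_neck: [Q10, Q11, Q12, Q13, Q14, Q15, Q16, Q18]
  circulatory: [Q20, Q21, Q22, Q23, Q24, Q25, Q26, Q27, Q28]
  respiratory: [Q30, Q31, Q32, Q33, Q34]
  cleft_lip_palate: [Q35, Q36, Q37]
  digestive: [Q38, Q39, Q40, Q41, Q42, Q43, Q44, Q45]
  genital: [Q50, Q51, Q52, Q54, Q55, Q56]
  urinary: [Q60, Q61, Q62, Q63, Q64]
  musculoskeletal: [Q65, Q70, Q71, Q72, Q73, Q74, Q75, Q76, Q77, Q78, Q79]
  other: [Q80, Q81, Q85, Q86, Q87, Q89]
excluded_minor:
  - Q10.3   # other malformations of eyelid
  - Q13.5   # blue sclera
  - Q17     # minor ear anomalies
  - Q18.1   # preauricular sinus and cyst
  - Q25.0   # patent ductus arteriosus (minor in preterm infants)
  - Q27.0   # congenital absence/hypoplasia of umbilical artery
  - Q38.1   # ankyloglossia
  - Q40.1   # congenital hiatus hernia
  - Q53     # undescended testicle
  - Q62.5   # duplication of ureter
  - Q65.2   # congenital subluxation of hip
  - Q65.3
  - Q65.4
  - Q65.5
  - Q65.6
  - Q66     # positional foot deformities
  - Q67     # musculoskeletal deformities of head/face/spine/chest
  - Q68     # other musculoskeletal deformities
  - Q69     # polydactyly-adjacent minor variants per local convention
  - Q82.5   # congenital non-neoplastic naevus
  - Q83.2   # absent nipple
  - Q84     # other integument malformations
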