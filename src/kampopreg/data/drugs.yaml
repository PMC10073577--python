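# Drug dictionary for laxative classification.
#
# MgO and senna glycosides are identified by WHO-ATC codes; Kampo
# formulations have no WHO-ATC laxative codes and are matched by product
# name/code instead.  The rhubarb-rhizome (KRR) list holds the 17
# formulations evaluated; daikenchuto is a rhubarb-free Kampo comparator
# tracked for prescription-frequency reporting only.  Edit freely — the
# pipeline treats this file as configuration.
mgo_codes:
  - A02AA02
sg_codes:
  - A06AB06
krr_products:
  - mashiningan
  - daiokanzoto
  - otsujito
  - bofutsushosan
  - tokakujokito
  - keishikashakuyakudaioto
  - junchoto
  - crude_daio
  - tsudosan
  - choijokito
  - jidabokuippo
  - daisaikoto
  - daiobotampito
  - sanoshashinto
  - inchinkoto
  - jizusoippo
  - daijokito
daikenchuto_codes:
  - daikenchuto
# Suspected teratogens (first-trimester use is a confounder covariate and
# the exclusion rule of sensitivity analysis 1).  Placeholder ATC codes;
# replace with the study's own list when available.
teratogen_codes:
  - N03AG01   # valproate
  - D10BA01   # isotretinoin
  - L04AX03   # methotrexate
  - B01AA03   # warfarin
  - L04AX02   # thalidomide
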