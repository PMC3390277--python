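# YES medium preset for in silico simulations.
#
# Glucose uptake is capped at the measured rate (4.19 mmol/gDCW/h by
# default, set by the caller); the five supplements and every nutrient of
# the yeast-extract list that has an exchange reaction in the model are left
# unconstrained (uptake bound -1000). The yeast-extract composition is not
# fully enumerable and this list is a documented, editable approximation:
# the 20 proteinogenic amino acids, nucleobases, common vitamins, and iron.
name: YES
glucose: glc
supplements: [ade, his, leu, ura, lys]
yeast_extract:
  # amino acids
  - ala
  - arg
  - asn
  - asp
  - cys
  - gln
  - glu
  - gly
  - ile
  - met
  - phe
  - pro
  - ser
  - thr
  - trp
  - tyr
  - val
  # nucleobases / nucleosides
  - gua
  - xan
  - hxan
  - csn
  - thym
  # vitamins and cofactor precursors
  - thm
  - ribflv
  - nac
  - pnto
  - pydx
  - btn
  - fol
  - inost
minerals:
  - fe2
  - fe3
  - nh4
  - pi
  - so4
  - k
  - na1
  - mg2
  - ca2
  - o2
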