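# Meso-substitution patterns over the six hexaphyrin sites R1..R6
# (1-based, clockwise).  Groups are ordered; every assignment names one
# substituent per group, in group order.
#
# A2B2C2 ties diagonally facing sites (R1=R4, R2=R5, R3=R6).
# A3B3 uses the alternating partition consistent with the dipyrromethene +
# aldehyde condensation route; it is kept here, not in code, so it can be
# corrected without code changes if a different partition is intended.
# A2BC2D is reconstructed from explicit site mentions (CH3 on R1/R3, single
# site R2, pair R4/R6, single site R5).
patterns:
  FULL:
    groups: [[R1, R2, R3, R4, R5, R6]]
  A2B2C2:
    groups: [[R1, R4], [R2, R5], [R3, R6]]
  A3B3:
    groups: [[R1, R3, R5], [R2, R4, R6]]
  A2BC2D:
    groups: [[R1, R3], [R2], [R4, R6], [R5]]
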