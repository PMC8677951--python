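# Meso-substituent fragment library for hexaphyrin inverse design.
# electronic_class: EWG (electron-withdrawing), EDG (electron-donating), neutral
# character: dominant electronic mechanism (mesomeric vs inductive)
# in_default_library: the seven-fragment optimization library; PhF5 appears
# only in fixture tables, never in searches.
substituents:
  - {label: NO2,  electronic_class: EWG,     character: mesomeric, in_default_library: true}
  - {label: CN,   electronic_class: EWG,     character: mesomeric, in_default_library: true}
  - {label: F,    electronic_class: EWG,     character: inductive, in_default_library: true}
  - {label: H,    electronic_class: neutral, character: none,      in_default_library: true}
  - {label: CH3,  electronic_class: EDG,     character: inductive, in_default_library: true}
  - {label: OH,   electronic_class: EDG,     character: mesomeric, in_default_library: true}
  - {label: NH2,  electronic_class: EDG,     character: mesomeric, in_default_library: true}
  - {label: PhF5, electronic_class: EWG,     character: inductive, in_default_library: false}
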