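substituent,ratio_26R_28R,ratio_28M_28R,diff_26R_28R,diff_28M_28R,provenance
H,2.35e6,1.47e6,2.35e3,1.47e3,table2
F,8.62e6,2.09e6,8.62e3,2.09e3,table2
CN,1.40e0,1.31e0,4.65e2,3.68e2,table2
NO2,1.44e0,2.23e0,4.44e2,1.26e3,table2
PhF5,1.71e0,9.41e-1,1.32e3,-1.09e2,table2
CH3,2.96e7,1.16e6,2.96e4,1.16e3,table2
NH2,1.25e1,8.19e-1,3.10e4,-4.90e2,table2
OH,2.57e7,2.89e6,2.57e4,2.89e3,table2
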