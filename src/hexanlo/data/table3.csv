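key,state,pattern,substituent,site_pair,phi_p,pi_index,lambda_exalt,nics_zz1,av1245,av_min,delta_eta,delta_hl,beta_hrs_static,beta_hrs_0653,beta_hrs_1165,symmetry,provenance
26R(F_H_H),26R,A2B2C2,F,R1/R4,,,,,,,,,5060,,,C1,table3
26R(H_F_H),26R,A2B2C2,F,R2/R5,,,,,,,,,2950,,,C1,table3
26R(H_H_F),26R,A2B2C2,F,R3/R6,,,,,,,,,4630,,,C1,table3
28R(F_H_H),28R,A2B2C2,F,R1/R4,,,,,,,,,0,,,Ci,table3
28R(H_F_H),28R,A2B2C2,F,R2/R5,,,,,,,,,0,,,Ci,table3
28R(H_H_F),28R,A2B2C2,F,R3/R6,,,,,,,,,0,,,Ci,table3
28M(F_H_H),28M,A2B2C2,F,R1/R4,,,,,,,,,354,,,C1,table3
28M(H_F_H),28M,A2B2C2,F,R2/R5,,,,,,,,,1700,,,C1,table3
28M(H_H_F),28M,A2B2C2,F,R3/R6,,,,,,,,,1170,,,C1,table3
26R(CN_H_H),26R,A2B2C2,CN,R1/R4,,,,,,,,,1200,,,C1,table3
26R(H_CN_H),26R,A2B2C2,CN,R2/R5,,,,,,,,,6380,,,C1,table3
26R(H_H_CN),26R,A2B2C2,CN,R3/R6,,,,,,,,,2450,,,C1,table3
28R(CN_H_H),28R,A2B2C2,CN,R1/R4,,,,,,,,,0,,,Ci,table3
28R(H_CN_H),28R,A2B2C2,CN,R2/R5,,,,,,,,,0,,,Ci,table3
28R(H_H_CN),28R,A2B2C2,CN,R3/R6,,,,,,,,,0,,,Ci,table3
28M(CN_H_H),28M,A2B2C2,CN,R1/R4,,,,,,,,,1960,,,C1,table3
28M(H_CN_H),28M,A2B2C2,CN,R2/R5,,,,,,,,,1530,,,C1,table3
28M(H_H_CN),28M,A2B2C2,CN,R3/R6,,,,,,,,,554,,,C1,table3
26R(NO2_H_H),26R,A2B2C2,NO2,R1/R4,,,,,,,,,1140,,,C1,table3
26R(H_NO2_H),26R,A2B2C2,NO2,R2/R5,,,,,,,,,4140,,,C1,table3
26R(H_H_NO2),26R,A2B2C2,NO2,R3/R6,,,,,,,,,1520,,,C1,table3
28R(NO2_H_H),28R,A2B2C2,NO2,R1/R4,,,,,,,,,1340,,,C2,table3
28R(H_NO2_H),28R,A2B2C2,NO2,R2/R5,,,,,,,,,0,,,Ci,table3
28R(H_H_NO2),28R,A2B2C2,NO2,R3/R6,,,,,,,,,923,,,C2,table3
28M(NO2_H_H),28M,A2B2C2,NO2,R1/R4,,,,,,,,,2900,,,C1,table3
28M(H_NO2_H),28M,A2B2C2,NO2,R2/R5,,,,,,,,,2550,,,C1,table3
28M(H_H_NO2),28M,A2B2C2,NO2,R3/R6,,,,,,,,,2010,,,C1,table3
26R(CH3_H_H),26R,A2B2C2,CH3,R1/R4,,,,,,,,,3210,,,C1,table3
26R(H_CH3_H),26R,A2B2C2,CH3,R2/R5,,,,,,,,,3870,,,C1,table3
26R(H_H_CH3),26R,A2B2C2,CH3,R3/R6,,,,,,,,,3460,,,C1,table3
28R(CH3_H_H),28R,A2B2C2,CH3,R1/R4,,,,,,,,,0,,,Ci,table3
28R(H_CH3_H),28R,A2B2C2,CH3,R2/R5,,,,,,,,,0,,,Ci,table3
28R(H_H_CH3),28R,A2B2C2,CH3,R3/R6,,,,,,,,,0,,,Ci,table3
28M(CH3_H_H),28M,A2B2C2,CH3,R1/R4,,,,,,,,,458,,,C1,table3
28M(H_CH3_H),28M,A2B2C2,CH3,R2/R5,,,,,,,,,422,,,C1,table3
28M(H_H_CH3),28M,A2B2C2,CH3,R3/R6,,,,,,,,,900,,,C1,table3
26R(OH_H_H),26R,A2B2C2,OH,R1/R4,,,,,,,,,9990,,,C1,table3
26R(H_OH_H),26R,A2B2C2,OH,R2/R5,,,,,,,,,3610,,,C1,table3
26R(H_H_OH),26R,A2B2C2,OH,R3/R6,,,,,,,,,8920,,,C1,table3
28R(OH_H_H),28R,A2B2C2,OH,R1/R4,,,,,,,,,0,,,Ci,table3
28R(H_OH_H),28R,A2B2C2,OH,R2/R5,,,,,,,,,0,,,Ci,table3
28R(H_H_OH),28R,A2B2C2,OH,R3/R6,,,,,,,,,0,,,Ci,table3
28M(OH_H_H),28M,A2B2C2,OH,R1/R4,,,,,,,,,895,,,C1,table3
28M(H_OH_H),28M,A2B2C2,OH,R2/R5,,,,,,,,,1610,,,C1,table3
28M(H_H_OH),28M,A2B2C2,OH,R3/R6,,,,,,,,,2130,,,C1,table3
26R(NH2_H_H),26R,A2B2C2,NH2,R1/R4,,,,,,,,,15600,,,C1,table3
26R(H_NH2_H),26R,A2B2C2,NH2,R2/R5,,,,,,,,,2740,,,C1,table3
26R(H_H_NH2),26R,A2B2C2,NH2,R3/R6,,,,,,,,,11400,,,C1,table3
28R(NH2_H_H),28R,A2B2C2,NH2,R1/R4,,,,,,,,,0,,,Ci,table3
28R(H_NH2_H),28R,A2B2C2,NH2,R2/R5,,,,,,,,,0,,,Ci,table3
28R(H_H_NH2),28R,A2B2C2,NH2,R3/R6,,,,,,,,,1280,,,C2,table3
28M(NH2_H_H),28M,A2B2C2,NH2,R1/R4,,,,,,,,,963,,,C1,table3
28M(H_NH2_H),28M,A2B2C2,NH2,R2/R5,,,,,,,,,2050,,,C1,table3
28M(H_H_NH2),28M,A2B2C2,NH2,R3/R6,,,,,,,,,1360,,,C1,table3
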