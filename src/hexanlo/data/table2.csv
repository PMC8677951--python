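key,state,pattern,substituent,site_pair,phi_p,pi_index,lambda_exalt,nics_zz1,av1245,av_min,delta_eta,delta_hl,beta_hrs_static,beta_hrs_0653,beta_hrs_1165,symmetry,provenance
26R(H),26R,FULL,H,,11.66,0.88,,,,,,3.66,2350,,,C1,table2
28R(H),28R,FULL,H,,10.87,0.90,,,,,,3.00,0,,,Ci,table2
28M(H),28M,FULL,H,,31.54,-0.45,,,,,,3.82,1470,,,C1,table2
26R(F),26R,FULL,F,,8.83,0.90,,,,,,3.23,8620,,,C1,table2
28R(F),28R,FULL,F,,11.01,0.90,,,,,,3.11,0,,,Ci,table2
28M(F),28M,FULL,F,,32.55,-0.46,,,,,,3.42,2090,,,C1,table2
26R(CN),26R,FULL,CN,,12.69,0.88,,,,,,3.63,1640,,,C1,table2
28R(CN),28R,FULL,CN,,27.98,0.54,,,,,,3.05,1170,,,unknown,table2
28M(CN),28M,FULL,CN,,32.38,-0.46,,,,,,3.63,1540,,,C1,table2
26R(NO2),26R,FULL,NO2,,15.61,0.79,,,,,,3.83,1460,,,C1,table2
28R(NO2),28R,FULL,NO2,,40.58,0.18,,,,,,3.66,1020,,,unknown,table2
28M(NO2),28M,FULL,NO2,,34.20,-0.43,,,,,,3.64,2280,,,C1,table2
26R(PhF5),26R,FULL,PhF5,,16.31,0.80,,,,,,3.64,3180,,,C1,table2
28R(PhF5),28R,FULL,PhF5,,47.95,0.47,,,,,,3.28,1860,,,unknown,table2
28M(PhF5),28M,FULL,PhF5,,32.91,-0.38,,,,,,3.68,1750,,,C1,table2
26R(CH3),26R,FULL,CH3,,18.11,0.66,,,,,,1.57,29600,,,C1,table2
28R(CH3),28R,FULL,CH3,,21.91,0.68,,,,,,3.18,0,,,Ci,table2
28M(CH3),28M,FULL,CH3,,32.59,-0.46,,,,,,3.68,1160,,,C1,table2
26R(NH2),26R,FULL,NH2,,29.26,0.53,,,,,,2.52,33700,,,C1,table2
28R(NH2),28R,FULL,NH2,,30.71,0.43,,,,,,3.33,2700,,,unknown,table2
28M(NH2),28M,FULL,NH2,,33.23,-0.45,,,,,,3.62,2210,,,C1,table2
26R(OH),26R,FULL,OH,,14.28,0.86,,,,,,2.56,25700,,,C1,table2
28R(OH),28R,FULL,OH,,14.26,0.80,,,,,,3.08,0,,,Ci,table2
28M(OH),28M,FULL,OH,,32.52,-0.45,,,,,,3.29,2890,,,C1,table2
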