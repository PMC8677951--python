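key,state,pattern,substituent,site_pair,phi_p,pi_index,lambda_exalt,nics_zz1,av1245,av_min,delta_eta,delta_hl,beta_hrs_static,beta_hrs_0653,beta_hrs_1165,symmetry,provenance
26R(NH2_NO2_NH2),26R,A2B2C2,,,,,,,,,,,59400,,,C1,section4.3.2
26R(NH2_OH_NH2),26R,A2B2C2,,,13.60,0.77,,,,,,,35200,,,C1,section4.3.2
28R(NH2_OH_NH2),28R,A2B2C2,,,,,,,,,,,0,,,Ci,section4.3.2
28R(NH2_NO2_NH2),28R,A2B2C2,,,,,,,,,,,707,,,unknown,section4.3.2
28R(NO2_NH2),28R,A3B3,,,,,,,,,,,10700,,,C1,section4.3.3
28M(NO2_NH2),28M,A3B3,,,,,,,,,,,19500,,,C1,section4.3.3
28M(CH3_NO2_NO2_NO2),28M,A2BC2D,,,,,,,,,,,14300,,,C1,section4.3.3
28M(CH3_H_NO2_NO2),28M,A2BC2D,,,,,,,,,,,6540,,,C1,section4.3.3
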