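key,state,pattern,substituent,site_pair,phi_p,pi_index,lambda_exalt,nics_zz1,av1245,av_min,delta_eta,delta_hl,beta_hrs_static,beta_hrs_0653,beta_hrs_1165,symmetry,provenance
26D(H),26D,FULL,H,,6.41,0.99,-184,-22.4,1.80,0.77,3.77,3.71,1828,3512,4069,C1,table1
26R(H),26R,FULL,H,,11.66,0.88,-155,-15.8,1.68,0.66,1.79,3.66,2347,5432,6570,C1,table1
28R(H),28R,FULL,H,,10.87,0.90,239,41.2,1.33,0.42,-11.54,3.00,0,0,0,Ci,table1
28M(H),28M,FULL,H,,31.54,-0.45,-92,-10.7,1.63,0.79,1.68,3.82,1470,2311,5679,C1,table1
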