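period,N_ref,n_occ_ref,f1,f2,f3,f4,f5,f6,f7,f8,S,p_tr,cv
1985_11,183,31,48,15,4,1,0,0,0,0,68,0.092,0.50
1986_01,165,23,38,23,13,3,1,2,0,0,80,0.122,0.52
1986_03,155,16,35,19,18,15,5,3,1,0,96,0.171,0.55
1986_11,106,10,33,26,9,2,0,0,0,0,70,0.259,0.21
1987_01,74,5,21,14,8,5,3,0,0,0,51,0.451,0.57
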