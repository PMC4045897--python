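period,N_ref,n_occ_ref,f1,f2,f3,f4,f5,f6,f7,f8,S,p_tr,cv
1985_11,194,37,53,19,4,1,0,0,0,0,77,0.078,0.43
1986_01,183,31,50,26,14,4,1,3,0,0,98,0.092,0.59
1986_03,196,23,56,31,24,15,6,3,2,0,137,0.122,0.60
1986_11,135,16,54,31,12,2,0,0,0,0,99,0.171,0.33
1987_01,107,10,43,23,10,5,3,0,0,0,84,0.259,0.62
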