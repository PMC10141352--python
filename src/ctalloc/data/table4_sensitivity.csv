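w_population,w_females,w_old,w_young,w_patients,group_a,group_b,group_c,group_d,group_e,group_f,group_g
0.5,0.1,0.1,0.1,0.1,9,4,36,4,11,16,40
1,0.1,0.1,0.1,0.1,15,3,31,4,10,18,39
0.1,0.5,0.5,0.5,0.1,14,6,30,3,9,19,39
0.1,1,1,1,0.1,15,5,30,6,11,13,43
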